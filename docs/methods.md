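# Methods

This note documents the models, generative conventions, numerical choices
and limitations of the package.  Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Fibrosis Score model

**Training rows are patches.**  Every patch of a biopsy becomes one row of
the design matrix, labeled with that biopsy's *total* mRSS (0–51).  This
patch-level supervision matches the structure of the score: the model
predicts an mRSS value per patch, and the biopsy-level Fibrosis Score is
the exact arithmetic mean of the per-patch predictions.  Scores are not
clipped to [0, 51]; the score's range is arbitrary and only approximates
the mRSS scale.

**Objective and grid.**  The fit minimizes
`(1/2m)·||y − β₀ − Xβ||² + λ·||β||₁` over patch rows (m = number of rows).
λ is searched on a 16-point log-spaced grid from 10⁻⁵ (weak) to 10³
(strong); at the strong end all coefficients vanish and the model predicts
the training-mean mRSS from the intercept alone.  The coordinate-descent
solve is delegated to scikit-learn's `Lasso` (warm-started from strong to
weak penalty along the path); an independently written coordinate-descent
reference in the test suite confirms agreement to 10⁻⁶ on a small problem.

**Penalty selection is patient-grouped and biopsy-level.**  Folds are
formed over subjects — leave-one-subject-out when there are ≤ 15 subjects,
5-fold grouped otherwise — so that no subject's patches appear on both
sides of any split and within-patient correlation cannot inflate the
held-out estimate.  The selection criterion is the held-out *biopsy-level*
mean squared error: fold-test patch predictions are averaged per biopsy
before scoring, because the deliverable is the biopsy score, not the patch
prediction.  Features are standardized with training-fold means/SDs only
(a fair L1 penalty across thousands of heterogeneous features requires a
common scale); the final model is refit on all data at the selected λ.
Held-out biopsy predictions at the selected λ are retained
(`cv_predictions_`) so a genuinely held-out score/mRSS correlation can be
reported without a second nested loop.

**Solver controls.**  Default coordinate-descent tolerance 10⁻⁴ with
20,000 iterations; at the weak-penalty end of the grid on heavily
collinear features the solver may stop at the iteration cap, which affects
only penalties the selection step then rejects.  The oracle-equivalence
test tightens the tolerance to 10⁻¹².

## Feature backends

The pipeline's contract with a backend is minimal: a deterministic map
from an RGB patch to a fixed-width finite vector, constant width within a
run.  The default **texture backend** computes ~30 multiscale statistics —
per-channel moments (anchor-shifted so contrast statistics are exactly
zero on a constant field), collagen blue-excess summaries, a
gradient-orientation histogram (8 bins over [0, π), magnitude-weighted),
and difference-of-Gaussian band-pass energies at four scales on the gray
and blue-excess channels — and expands them to the requested width
(default 4,096, the width of a CNN fully-connected layer) by a fixed,
seeded Gaussian random projection.  The projection preserves the
100 × 4,096 matrix geometry so every downstream code path is identical to
the CNN case; it adds no information beyond the base bank, which is
sufficient for the monotone severity texture it needs to read.

The **ONNX backend** reads activations of a named layer of a local ONNX
model (for AlexNet, either fully-connected layer is 4,096 wide; the layer
name is a required configuration value, not a guess).  Patches are resized
to 224×224 and normalized with the ImageNet channel constants; these
preprocessing choices are serialized in the backend config.  The model
file must be provisioned manually — the library performs no network
access and ships no weights.

## Synthetic-data generator

A latent severity s ∈ [0, 1] per subject-visit jointly drives all three
observable layers.  This shared-cause structure is exactly what the
association analyses assume, which is what makes end-to-end recovery tests
meaningful.

**Cohort.**  Baseline severity ~ U(0.30, 0.78), corresponding to the
mRSS 15–40 entry range of an early diffuse-cutaneous SSc trial cohort;
severity drifts −0.001/week on average (≈ −2.7 mRSS points over 52 weeks,
a mild mean improvement) with a per-subject random slope (SD 0.002/week).
Each of the 17 mRSS sites scores `clip(floor(3s + (i+0.5)/17 + εᵢ), 0, 3)`
with per-site noise εᵢ of SD `noise_sd_mrss/√17` (default total jitter
2 points).  The evenly offset thresholds make the zero-noise total equal
`round(51s)` exactly (Σ⌊x + i/n⌋ = ⌊nx⌋), so the severity→mRSS link is
monotone and fine-grained rather than a 17-point staircase.

**Images.**  2048×2048 px at 1 µm/px by default (holding ≥ 100 disjoint
0.16 mm² patches): background margins, a ~100 µm epidermis band, a dermis
interior (~62 % of tissue rows), and a subcutis band, with smooth
per-column wobble.  Dermal fibrosis is emulated by oriented collagen
streaks — short near-horizontal segments blended toward the trichrome
collagen blue — whose count grows linearly with severity (20→420 per mm²
of dermis).  Streak parameters are drawn sequentially from one seeded
stream with a fixed draw count per streak, and the band layout is
severity-independent, so at a fixed seed a lower severity's streaks are an
exact prefix of a higher severity's; the module's texture statistic T
(blue-excess pixel fraction in the dermis) is therefore monotone in
severity by construction.  Per-(subject, week, purpose) random streams are
derived from the master seed, so adding or removing subjects never shifts
another subject's draws.

**Score sheets.**  Truth values are monotone in severity: binary "yes"
probabilities rise linearly between per-parameter endpoints (e.g. 0.05→
0.95 for eccrine entrapment, 0.01→0.40 for calcification); ordinal stain
scores round `3s` plus noise into 0–3; perivascular CD3 counts are
Poisson(4 + 26s) with CD8 binomial at fraction 0.2 + 0.4s; epidermal
thickness falls from ~85 µm to ~50 µm (five site measurements, SD 6 µm,
averaged).  No published distributional detail exists for these
parameters; all of these are module conventions.  A rater reproduces each
truth value with probability `rater_agreement`, else re-draws from the
parameter's severity-*marginalized* distribution (severity ~ U(0, 1)).
The marginal re-draw is deliberate: with it, zero agreement makes the two
raters genuinely independent (expected kappa 0), whereas a
severity-conditional re-draw would leave them correlated through the
shared severity.  The copy-vs-redraw indicator is recorded per parameter
so realized agreement is measurable directly.  A rater's CD8/CD3
percentage is always derived from that rater's own counts, and re-drawn
counts are re-coerced to CD8 ≤ CD3.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: staining batch effects and scanner variation,
realistic tissue morphology (adnexal structures, vessels, follicles),
segmentation error in the compartment mask (masks are exact by
construction), missing or unusable biopsies, and rater drift over time
(agreement is exchangeable across parameters and rounds).  Recovery
results here demonstrate internal consistency of the pipeline, not
clinical performance.

## Patch sampling

Patches are square with side `round(1000·√area/µm-per-px)` (400 px for
0.16 mm² at 1 µm/px).  Eligibility is "window contains ≥ 90 % dermis
pixels" — a fraction threshold is robust at compartment borders, and
`min_dermis_fraction` is configurable.  Positions are drawn uniformly
without positional replacement among eligible top-left corners (distinct
patches may still overlap spatially); if fewer eligible corners than
requested patches exist, sampling continues with replacement and logs a
warning.  Coordinates are 0-based, row-major, origin at the patch's
top-left pixel, and are serialized in the patch manifest together with
the per-patch dermis fraction and seed.  Eligibility fractions are
computed with a summed-area table and are re-checked in tests by an
independent brute-force pixel scan.

## Agreement statistics

Unweighted Cohen's kappa, `κ = (p_o − p_e)/(1 − p_e)` with chance
agreement from the raters' marginals, is applied to the 12 categorical
parameters (weighted kappa for the ordinal scores would be a reasonable
alternative and can be added as a config option; the unweighted form is
the package default).  When both raters use a single identical category,
p_e = 1 and kappa is undefined; the report marks such parameters "not
assessable" rather than guessing.  Interpretation bands (≤ 0 no
agreement, 0.01–0.20 none-to-slight, 0.21–0.40 fair, 0.41–0.60 moderate,
0.61–0.80 substantial, 0.81–1.00 almost perfect) are defined on
two-decimal values, so kappa is rounded to two decimals before banding —
every value then maps to exactly one band.  Quantitative parameters
(thickness, counts, percentage) are excluded from kappa and summarized by
the mean absolute inter-rater difference.  Missing values are dropped
pairwise per parameter.

## Change per week

Per-parameter trends are estimated with a linear mixed model
`value ~ week` with a random intercept and a random slope per participant
under an independent (diagonal) random-effects covariance, fit by maximum
likelihood.  The optimizer is Powell's derivative-free method: on
random-slope variance components the gradient-based optimizers in the
same framework reproducibly stall at a boundary solution with a grossly
inflated slope standard error, while Powell reaches the ML optimum (the
recovery test pins the slope to ±0.01 and requires a significant p-value
at n = 50 subjects).  Binary parameters are coded yes = 1/no = 0, so
their slope reads as a change in prevalence per week.  Degenerate designs
(near-constant values, unidentifiable components) are reported per
parameter as unestimable rather than aborting a batch run.

## Associations

Each histologic parameter is regressed on one continuous exposure — total
mRSS or Fibrosis Score — with a proportional-odds (ordinal logistic)
model; the odds ratio is per 1-unit exposure change with a Wald 95 % CI
and p-value, maximum-likelihood fit (BFGS, gradient tolerance 10⁻⁸).  For
a binary outcome the model reduces exactly to ordinary logistic
regression (verified against the 2×2 cross-product ratio and an
independent Newton solver).  Outcomes with more than 8 distinct values
are quantile-binned into ≤ 8 ordered categories before the fit — one
threshold per level is unstable at small n.  Complete separation returns
a flagged infinite-OR sentinel with a warning, never a crash;
single-level outcomes and constant exposures are skipped with a recorded
reason.  No multiple-testing correction is applied (exploratory
analyses); the output annotates p < 0.05.  ORs are computed on visit-level
observations by default; computing them on within-subject deltas is a
reasonable alternative reading and can be assembled from the same
functions.

For two raters' sheets feeding one regression, a consensus is formed per
biopsy: a binary call is "yes" iff all raters agree, discordant calls
resolve by majority across rounds with ties going to the first rater's
earliest call; ordinal and quantitative values are averaged (ordinal
rounded back to a level).  The rule is explicit and configurable in
spirit — it lives in one function (`consensus_sheet_values`).

The mRSS/Fibrosis-Score relationship is summarized by Spearman's rank
correlation (midrank ties, two-sided p).

## Pipeline and determinism

`run_pipeline` executes all stages from a single validated config
(pydantic, unknown keys rejected — silent typos are the main
reproducibility hazard) and one master seed fanned out to per-stage,
per-subject streams.  CSV artifacts are written with a fixed float format
and sorted rows, JSON with sorted keys; the manifest records each
artifact's SHA-256 and the config hash (the output directory is excluded
from the hash — it is storage, not science).  Wall-clock timings go to a
separate `run.log` outside the determinism contract.  A double run from
the same config is byte-identical, which the tests verify by hashing.

## Problem sizes

The test suite and acceptance script run at desk scale by the package's
own choice of demonstration sizes: full default geometry (2048 px image,
100 × 400 px patches, 4,096 features) is exercised once; recovery runs use
30 subjects with 512 px images, 12 patches of 0.04 mm² and 256-wide
features; calibration uses 1,000 null replicates at n = 200; the
determinism check uses a 4-subject, 2-visit configuration.  All sizes are
parameters, and nothing in the code depends on them.

## Known limitations

- The texture backend is a stand-in realization of the feature contract,
  not a CNN; its 4,096 columns have rank ≤ the base-bank size.
- The proportional-odds quantile-binning of many-valued outcomes discards
  within-bin information.
- The consensus rule is one defensible convention among several; results
  for discordant binary calls depend on it.
- Intra-rater assessment supports exactly two rounds, mirroring the
  two-time-point reassessment design.
- The synthetic generator's monotone severity links make association
  directions known by construction; effect *sizes* in synthetic runs are
  properties of the generator's conventions, not of any real cohort.
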