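"""Dermatopathology scoring schema, rater agreement and longitudinal trends.

The schema holds the 16 parameters two blinded dermatopathologists score on
each systemic-sclerosis skin biopsy: eight presence/absence calls (scored
"yes"/"no"), four ordinal matrix/stain scores made against a standard image
set, mean epidermal thickness (the average of five site measurements, in µm),
and three perivascular lymphocyte quantities from immunostains.

Agreement between and within raters is summarized with unweighted Cohen's
kappa for the categorical parameters, mapped onto the conventional
interpretation bands (none-to-slight / fair / moderate / substantial / almost
perfect); quantitative parameters are summarized by mean absolute difference
instead.  Per-parameter change per week is estimated with a linear
mixed-effects model with a random intercept and an independent random slope
per participant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score

from .errors import FitError, UndefinedKappaError, ValidationError

# --------------------------------------------------------------------------
# Parameter schema
# --------------------------------------------------------------------------

#: Presence/absence parameters, scored "yes" or "no".
BINARY_PARAMETERS: tuple[str, ...] = (
    "epidermal_papilla_loss",
    "eccrine_entrapment",
    "eccrine_coil_loss",
    "telangiectasia",
    "hair_follicle_loss",
    "calcification",
    "subcut_fat_loss_or_widened_septa",
    "thickened_intima",
)

#: Ordinal parameters scored against a standard image set (default range 0-3).
ORDINAL_PARAMETERS: tuple[str, ...] = (
    "matrix_he",
    "matrix_trichrome",
    "cd34_stain",
    "asma_stain",
)

#: Quantitative parameters: micrometer measurement, cell counts, a percentage.
CONTINUOUS_PARAMETERS: tuple[str, ...] = (
    "mean_epidermal_thickness_um",
    "perivascular_cd3_count",
    "perivascular_cd8_count",
    "pct_cd8_among_cd3",
)

ALL_PARAMETERS: tuple[str, ...] = (
    BINARY_PARAMETERS + ORDINAL_PARAMETERS + CONTINUOUS_PARAMETERS
)

#: Parameters eligible for Cohen's kappa (categorical scales).
KAPPA_PARAMETERS: tuple[str, ...] = BINARY_PARAMETERS + ORDINAL_PARAMETERS

#: Inclusive ordinal range of the standard image set.  The set itself is a
#: pathologist-consensus artifact; its printed range is a configuration value.
DEFAULT_ORDINAL_RANGE: tuple[int, int] = (0, 3)

N_PARAMETERS = len(ALL_PARAMETERS)
assert N_PARAMETERS == 16


@dataclass
class ScoreSheet:
    """One rater's values for the 16 parameters on one biopsy at one round.

    ``values`` must contain exactly the 16 schema parameters.  Binary values
    are the strings ``"yes"``/``"no"``; ordinal values are integers inside
    ``ordinal_range``; quantitative values are non-negative numbers with
    ``pct_cd8_among_cd3`` in [0, 100] and the CD8 count never exceeding the
    CD3 count when both are present (missing values are ``None``).
    """

    biopsy_id: str
    rater_id: str
    values: dict[str, object]
    assessment_round: int = 1
    ordinal_range: tuple[int, int] = DEFAULT_ORDINAL_RANGE

    def __post_init__(self) -> None:
        got = set(self.values)
        expected = set(ALL_PARAMETERS)
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            raise ValidationError(
                f"score sheet must contain exactly {N_PARAMETERS} parameters; "
                f"missing={missing} unexpected={extra}"
            )
        if self.assessment_round not in (1, 2):
            raise ValidationError(
                f"assessment_round must be 1 or 2, got {self.assessment_round}"
            )
        for name in BINARY_PARAMETERS:
            v = self.values[name]
            if v is not None and v not in ("yes", "no"):
                raise ValidationError(f"{name} must be 'yes' or 'no', got {v!r}")
        lo, hi = self.ordinal_range
        for name in ORDINAL_PARAMETERS:
            v = self.values[name]
            if v is None:
                continue
            if int(v) != v or not (lo <= int(v) <= hi):
                raise ValidationError(
                    f"{name} must be an integer in [{lo}, {hi}], got {v!r}"
                )
        for name in CONTINUOUS_PARAMETERS:
            v = self.values[name]
            if v is not None and (not np.isfinite(v) or v < 0):
                raise ValidationError(f"{name} must be a non-negative number, got {v!r}")
        pct = self.values["pct_cd8_among_cd3"]
        if pct is not None and not (0 <= pct <= 100):
            raise ValidationError(f"pct_cd8_among_cd3 must lie in [0, 100], got {pct}")
        cd3 = self.values["perivascular_cd3_count"]
        cd8 = self.values["perivascular_cd8_count"]
        if cd3 is not None and cd8 is not None and cd8 > cd3:
            raise ValidationError(
                f"perivascular_cd8_count ({cd8}) exceeds perivascular_cd3_count ({cd3})"
            )

    def __getitem__(self, parameter: str) -> object:
        return self.values[parameter]


def sheets_to_frame(
    sheets: Iterable[ScoreSheet],
    subject_of: Mapping[str, str] | None = None,
    week_of: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Long-format export: one row per sheet x parameter."""
    rows = []
    for s in sheets:
        for p in ALL_PARAMETERS:
            rows.append(
                {
                    "biopsy_id": s.biopsy_id,
                    "subject_id": (subject_of or {}).get(s.biopsy_id, ""),
                    "week": (week_of or {}).get(s.biopsy_id, ""),
                    "rater_id": s.rater_id,
                    "assessment_round": s.assessment_round,
                    "parameter": p,
                    "value": s.values[p],
                }
            )
    return pd.DataFrame(rows)


def frame_to_sheets(frame: pd.DataFrame) -> list[ScoreSheet]:
    """Inverse of :func:`sheets_to_frame` (ignores subject/week columns)."""
    sheets = []
    keys = ["biopsy_id", "rater_id", "assessment_round"]
    for (bid, rid, rnd), grp in frame.groupby(keys, sort=True):
        values: dict[str, object] = {}
        for _, row in grp.iterrows():
            v = row["value"]
            if pd.isna(v):
                v = None
            elif row["parameter"] in ORDINAL_PARAMETERS:
                v = int(v)
            elif row["parameter"] in CONTINUOUS_PARAMETERS:
                v = float(v)
            values[row["parameter"]] = v
        sheets.append(
            ScoreSheet(biopsy_id=str(bid), rater_id=str(rid), values=values,
                       assessment_round=int(rnd))
        )
    return sheets


# --------------------------------------------------------------------------
# Epidermal thickness
# --------------------------------------------------------------------------

def mean_epidermal_thickness(measurements: Sequence[float]) -> float:
    """Average of the five per-site epidermal thickness measurements (µm)."""
    if len(measurements) != 5:
        raise ValidationError(
            f"epidermal thickness requires exactly 5 site measurements, "
            f"got {len(measurements)}"
        )
    arr = np.asarray(measurements, dtype=float)
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValidationError("thickness measurements must be finite and non-negative")
    return float(arr.mean())


# --------------------------------------------------------------------------
# Cohen's kappa and interpretation bands
# --------------------------------------------------------------------------

#: (upper bound on the two-decimal kappa, label); kappa <= 0 is "no agreement".
KAPPA_BANDS: tuple[tuple[float, str], ...] = (
    (0.00, "no agreement"),
    (0.20, "none-to-slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
)


def kappa_band(kappa: float) -> str:
    """Map a kappa value onto its interpretation band.

    Bands are defined on two-decimal values (0.01-0.20, 0.21-0.40, ...), so
    the value is rounded to two decimals first; every kappa in [-1, 1] then
    falls in exactly one band.
    """
    k = round(float(kappa), 2)
    for upper, label in KAPPA_BANDS:
        if k <= upper:
            return label
    return KAPPA_BANDS[-1][1]


@dataclass(frozen=True)
class KappaResult:
    parameter: str
    kappa: float
    category: str
    n_items: int


def cohens_kappa(
    ratings_a: Sequence[object],
    ratings_b: Sequence[object],
    parameter: str = "",
) -> KappaResult:
    """Unweighted Cohen's kappa between two raters' categorical scores.

    kappa = (p_o - p_e) / (1 - p_e), with chance agreement p_e computed from
    the two raters' marginal category frequencies.  Raises
    :class:`UndefinedKappaError` when p_e = 1 (both raters used a single,
    identical category), where the statistic has a 0/0 form.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("rating vectors must be 1-D and of equal length")
    if a.size < 2:
        raise ValidationError("kappa requires at least 2 rated items")
    labels = sorted(set(a.tolist()) | set(b.tolist()), key=str)
    n = a.size
    p_e = sum(
        (np.sum(a == lab) / n) * (np.sum(b == lab) / n) for lab in labels
    )
    if p_e >= 1.0 - 1e-15:
        raise UndefinedKappaError(
            "kappa undefined: expected agreement is 1 (a single shared category)"
        )
    kappa = float(cohen_kappa_score(a, b, labels=labels))
    return KappaResult(parameter=parameter, kappa=kappa,
                       category=kappa_band(kappa), n_items=int(n))


# --------------------------------------------------------------------------
# Agreement report
# --------------------------------------------------------------------------

@dataclass
class AgreementReport:
    """Inter-rater kappas, intra-rater kappas, and quantitative-parameter MADs."""

    inter_rater: pd.DataFrame
    intra_rater: pd.DataFrame
    continuous_mad: pd.DataFrame

    def to_text(self) -> str:
        parts = ["Inter-rater agreement (Cohen's kappa)", "-" * 40]
        for _, r in self.inter_rater.iterrows():
            parts.append(
                f"{r.parameter:34s} kappa={r.kappa if pd.notna(r.kappa) else 'NA':>6} "
                f"({r.category}, n={r.n})"
            )
        if len(self.intra_rater):
            parts += ["", "Intra-rater agreement", "-" * 40]
            for _, r in self.intra_rater.iterrows():
                parts.append(
                    f"{r.rater_id}: {r.parameter:30s} "
                    f"kappa={r.kappa if pd.notna(r.kappa) else 'NA'} ({r.category})"
                )
        parts += ["", "Quantitative parameters (mean absolute difference)", "-" * 40]
        for _, r in self.continuous_mad.iterrows():
            parts.append(f"{r.parameter:34s} MAD={r.mean_abs_diff:.3f} (n={r.n})")
        return "\n".join(parts)


def _paired_values(sheets_by_key, key_pairs, parameter):
    """Collect aligned value pairs for one parameter, dropping missing pairwise."""
    xs, ys = [], []
    for ka, kb in key_pairs:
        va = sheets_by_key[ka].values[parameter]
        vb = sheets_by_key[kb].values[parameter]
        if va is None or vb is None:
            continue
        xs.append(va)
        ys.append(vb)
    return xs, ys


def _kappa_row(xs, ys, parameter):
    if len(xs) < 2:
        return {"parameter": parameter, "kappa": np.nan,
                "category": "not assessable", "n": len(xs)}
    try:
        res = cohens_kappa(xs, ys, parameter)
        return {"parameter": parameter, "kappa": res.kappa,
                "category": res.category, "n": res.n_items}
    except UndefinedKappaError:
        return {"parameter": parameter, "kappa": np.nan,
                "category": "not assessable", "n": len(xs)}


def agreement_report(sheets: Sequence[ScoreSheet]) -> AgreementReport:
    """Agreement tables over a collection of score sheets.

    Inter-rater rows pair the two raters on each (biopsy, round); intra-rater
    rows pair each rater's round 1 with round 2 on the same biopsy.  Binary
    and ordinal parameters get unweighted kappa; quantitative parameters are
    summarized by the mean absolute inter-rater difference.
    """
    by_key = {(s.biopsy_id, s.rater_id, s.assessment_round): s for s in sheets}
    raters = sorted({s.rater_id for s in sheets})
    if len(raters) < 2:
        raise ValidationError("agreement report requires two raters")
    ra, rb = raters[:2]
    biopsies = sorted({s.biopsy_id for s in sheets})
    rounds = sorted({s.assessment_round for s in sheets})

    inter_pairs = [
        ((b, ra, r), (b, rb, r))
        for b in biopsies for r in rounds
        if (b, ra, r) in by_key and (b, rb, r) in by_key
    ]
    inter_rows = []
    for p in KAPPA_PARAMETERS:
        xs, ys = _paired_values(by_key, inter_pairs, p)
        inter_rows.append(_kappa_row(xs, ys, p))
    inter = pd.DataFrame(inter_rows)

    intra_rows = []
    if set(rounds) >= {1, 2}:
        for rater in (ra, rb):
            pairs = [
                ((b, rater, 1), (b, rater, 2))
                for b in biopsies
                if (b, rater, 1) in by_key and (b, rater, 2) in by_key
            ]
            if not pairs:
                continue
            for p in KAPPA_PARAMETERS:
                xs, ys = _paired_values(by_key, pairs, p)
                row = _kappa_row(xs, ys, p)
                row["rater_id"] = rater
                intra_rows.append(row)
    intra = pd.DataFrame(
        intra_rows, columns=["rater_id", "parameter", "kappa", "category", "n"]
    )

    mad_rows = []
    for p in CONTINUOUS_PARAMETERS:
        xs, ys = _paired_values(by_key, inter_pairs, p)
        mad = (
            float(np.mean(np.abs(np.asarray(xs, float) - np.asarray(ys, float))))
            if xs else np.nan
        )
        mad_rows.append({"parameter": p, "mean_abs_diff": mad, "n": len(xs)})
    mad = pd.DataFrame(mad_rows)

    return AgreementReport(inter_rater=inter, intra_rater=intra, continuous_mad=mad)


# --------------------------------------------------------------------------
# Change per week (linear mixed model)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrendResult:
    slope_per_week: float
    std_err: float
    p: float
    n_subjects: int
    n_obs: int


def change_per_week(long_scores: pd.DataFrame, value_col: str = "value") -> TrendResult:
    """Fixed-effect slope of value on week from a linear mixed model.

    Model: value ~ week with a random intercept and a random slope per
    participant under an independent (diagonal) random-effects covariance,
    fit by maximum likelihood.  Requires columns ``subject_id`` and ``week``.
    """
    import statsmodels.formula.api as smf

    df = long_scores.dropna(subset=[value_col, "week", "subject_id"]).copy()
    df["week"] = df["week"].astype(float)
    n_weeks = df["week"].nunique()
    subj_with_repeats = (df.groupby("subject_id")["week"].nunique() >= 2).sum()
    if n_weeks < 2 or subj_with_repeats < 2:
        raise FitError(
            "change_per_week needs >= 2 distinct weeks for >= 2 subjects; "
            f"got {n_weeks} weeks, {int(subj_with_repeats)} subjects with repeats"
        )
    df = df.rename(columns={value_col: "_value"})
    # diagonal covariance: intercept as re_formula, slope as an independent
    # variance component
    model = smf.mixedlm(
        "_value ~ week", df, groups=df["subject_id"],
        re_formula="1", vc_formula={"week": "0 + week"},
    )
    # derivative-free optimizer: gradient methods stall on the variance
    # components of the random-slope term
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=False, method="powell")
    return TrendResult(
        slope_per_week=float(fit.fe_params["week"]),
        std_err=float(fit.bse["week"]),
        p=float(fit.pvalues["week"]),
        n_subjects=int(df["subject_id"].nunique()),
        n_obs=int(len(df)),
    )


def trend_report(long_frame: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter change/week over a long score-sheet frame.

    Binary values are coded yes=1/no=0 so the slope is a change in prevalence.
    """
    rows = []
    for p in ALL_PARAMETERS:
        sub = long_frame[long_frame["parameter"] == p].copy()
        if p in BINARY_PARAMETERS:
            sub["value"] = sub["value"].map({"yes": 1.0, "no": 0.0})
        sub["value"] = pd.to_numeric(sub["value"], errors="coerce")
        try:
            res = change_per_week(sub)
            rows.append({"parameter": p, "slope_per_week": res.slope_per_week,
                         "se": res.std_err, "p": res.p, "n": res.n_obs,
                         "note": ""})
        except (FitError, np.linalg.LinAlgError, ValueError) as exc:
            # degenerate designs (near-constant values, unidentified variance
            # components) are reported, not fatal
            rows.append({"parameter": p, "slope_per_week": np.nan,
                         "se": np.nan, "p": np.nan, "n": len(sub),
                         "note": str(exc) or type(exc).__name__})
    return pd.DataFrame(rows)
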