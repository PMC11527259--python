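"""Paired-rater score sheets generated from a subject's latent severity.

Each biopsy has one generative "truth" sheet: every binary parameter's "yes"
probability rises linearly with severity, ordinal matrix/stain scores follow
a noisy rounding of ``3*severity``, perivascular counts are Poisson/binomial
with severity-dependent rates, and epidermal thickness falls with severity
(dermal expansion flattens the epidermis).  A rater reproduces each truth
value with probability ``rater_agreement``; otherwise the value is re-drawn
from the parameter's severity-marginalized distribution (severity ~ U(0, 1)),
so that at ``rater_agreement = 0`` the two raters are genuinely independent
and their expected kappa is 0.  The copy-vs-redraw indicator is recorded so
realized agreement is directly measurable.

The marginal distributions here are module conventions chosen for monotone
severity links and realistic magnitudes; no published distributional detail
exists for these parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ValidationError
from ..histology import (
    BINARY_PARAMETERS,
    ORDINAL_PARAMETERS,
    DEFAULT_ORDINAL_RANGE,
    ScoreSheet,
)
from .cohort import SyntheticSubject

#: binary parameters: "yes" probability at severity 0 and severity 1
BINARY_PROBS: dict[str, tuple[float, float]] = {
    "epidermal_papilla_loss": (0.05, 0.95),
    "eccrine_entrapment": (0.05, 0.95),
    "eccrine_coil_loss": (0.02, 0.80),
    "telangiectasia": (0.10, 0.85),
    "hair_follicle_loss": (0.05, 0.90),
    "calcification": (0.01, 0.40),
    "subcut_fat_loss_or_widened_septa": (0.05, 0.95),
    "thickened_intima": (0.05, 0.90),
}

_ORDINAL_NOISE_SD = 0.35
_THICKNESS_MEAN_AT_0 = 85.0  # um
_THICKNESS_DROP = 35.0  # um decrease from severity 0 to 1
_THICKNESS_SITE_SD = 6.0
_CD3_RATE_AT_0 = 4.0
_CD3_RATE_SLOPE = 26.0
_CD8_FRAC_AT_0 = 0.20
_CD8_FRAC_SLOPE = 0.40


def _binary_prob(name: str, severity: float) -> float:
    p0, p1 = BINARY_PROBS[name]
    return p0 + (p1 - p0) * severity


def _draw_truth(severity: float, rng: np.random.Generator) -> dict[str, object]:
    values: dict[str, object] = {}
    for name in BINARY_PARAMETERS:
        values[name] = "yes" if rng.random() < _binary_prob(name, severity) else "no"
    lo, hi = DEFAULT_ORDINAL_RANGE
    for name in ORDINAL_PARAMETERS:
        latent = hi * severity + rng.normal(0.0, _ORDINAL_NOISE_SD)
        values[name] = int(np.clip(np.round(latent), lo, hi))
    sites = rng.normal(
        _THICKNESS_MEAN_AT_0 - _THICKNESS_DROP * severity, _THICKNESS_SITE_SD, size=5
    )
    values["mean_epidermal_thickness_um"] = float(np.maximum(sites, 1.0).mean())
    cd3 = int(rng.poisson(_CD3_RATE_AT_0 + _CD3_RATE_SLOPE * severity))
    cd8 = int(rng.binomial(cd3, _CD8_FRAC_AT_0 + _CD8_FRAC_SLOPE * severity)) if cd3 else 0
    values["perivascular_cd3_count"] = cd3
    values["perivascular_cd8_count"] = cd8
    values["pct_cd8_among_cd3"] = float(100.0 * cd8 / cd3) if cd3 else 0.0
    return values


def _draw_marginal_value(name: str, rng: np.random.Generator) -> object:
    """One value from the parameter's distribution with severity ~ U(0, 1)."""
    sev = rng.uniform()
    if name in BINARY_PARAMETERS:
        return "yes" if rng.random() < _binary_prob(name, sev) else "no"
    lo, hi = DEFAULT_ORDINAL_RANGE
    if name in ORDINAL_PARAMETERS:
        latent = hi * sev + rng.normal(0.0, _ORDINAL_NOISE_SD)
        return int(np.clip(np.round(latent), lo, hi))
    if name == "mean_epidermal_thickness_um":
        sites = rng.normal(
            _THICKNESS_MEAN_AT_0 - _THICKNESS_DROP * sev, _THICKNESS_SITE_SD, size=5
        )
        return float(np.maximum(sites, 1.0).mean())
    cd3 = int(rng.poisson(_CD3_RATE_AT_0 + _CD3_RATE_SLOPE * sev))
    if name == "perivascular_cd3_count":
        return cd3
    cd8 = int(rng.binomial(cd3, _CD8_FRAC_AT_0 + _CD8_FRAC_SLOPE * sev)) if cd3 else 0
    if name == "perivascular_cd8_count":
        return cd8
    return float(100.0 * cd8 / cd3) if cd3 else 0.0


def _coherent(values: dict[str, object]) -> dict[str, object]:
    """Re-establish cross-field constraints after independent re-draws."""
    cd3, cd8 = values["perivascular_cd3_count"], values["perivascular_cd8_count"]
    if cd8 > cd3:
        values["perivascular_cd8_count"] = cd3
        cd8 = cd3
    values["pct_cd8_among_cd3"] = float(100.0 * cd8 / cd3) if cd3 else 0.0
    return values


@dataclass
class SheetDiagnostics:
    """Per-rater copy indicators: True where the rater reproduced the truth."""

    truth: dict[str, object]
    copied: dict[str, dict[str, bool]]  # rater_id -> parameter -> bool

    def copy_fraction(self) -> float:
        flags = [f for per in self.copied.values() for f in per.values()]
        return float(np.mean(flags))


def _rate_sheet(
    truth: dict[str, object],
    agreement: float,
    rng: np.random.Generator,
) -> tuple[dict[str, object], dict[str, bool]]:
    values: dict[str, object] = {}
    copied: dict[str, bool] = {}
    parameters = list(BINARY_PARAMETERS) + list(ORDINAL_PARAMETERS) + [
        "mean_epidermal_thickness_um",
        "perivascular_cd3_count",
        "perivascular_cd8_count",
    ]
    for name in parameters:
        if rng.random() < agreement:
            values[name] = truth[name]
            copied[name] = True
        else:
            values[name] = _draw_marginal_value(name, rng)
            copied[name] = False
    # the percentage is derived from the rater's own counts
    values = _coherent(values)
    copied["pct_cd8_among_cd3"] = (
        copied["perivascular_cd3_count"] and copied["perivascular_cd8_count"]
    )
    return values, copied


def simulate_assessments(
    subject: SyntheticSubject,
    week: int,
    rater_agreement: float,
    seed: int,
    rounds: int = 1,
    rater_ids: tuple[str, str] = ("rater_A", "rater_B"),
    return_diagnostics: bool = False,
):
    """Score sheets from two raters for one biopsy, optionally repeated rounds.

    The truth sheet depends only on (subject severity, seed); each
    rater x round applies the copy-or-redraw process independently.
    """
    if week not in subject.visit_weeks:
        raise LookupError(
            f"week {week} is not a visit week of {subject.subject_id} "
            f"(visits: {list(subject.visit_weeks)})"
        )
    if not (0.0 <= rater_agreement <= 1.0):
        raise ValidationError(
            f"rater_agreement must lie in [0, 1], got {rater_agreement}"
        )
    if rounds not in (1, 2):
        raise ValidationError(f"rounds must be 1 or 2, got {rounds}")
    severity = subject.severity[week]
    biopsy_id = f"{subject.subject_id}-w{week:03d}"
    truth_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
    truth = _draw_truth(severity, truth_rng)

    sheets: list[ScoreSheet] = []
    copied: dict[str, dict[str, bool]] = {}
    for rnd in range(1, rounds + 1):
        for r_idx, rater_id in enumerate(rater_ids):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(seed), 1 + r_idx, rnd])
            )
            values, flags = _rate_sheet(truth, rater_agreement, rng)
            sheets.append(
                ScoreSheet(
                    biopsy_id=biopsy_id,
                    rater_id=rater_id,
                    values=values,
                    assessment_round=rnd,
                )
            )
            copied[f"{rater_id}/round{rnd}"] = flags
    if return_diagnostics:
        return sheets, SheetDiagnostics(truth=truth, copied=copied)
    return sheets


def simulate_score_sheets(
    subject: SyntheticSubject,
    week: int,
    rater_agreement: float,
    seed: int,
    return_diagnostics: bool = False,
):
    """Single-round pair of sheets (rater A, rater B) for one biopsy."""
    out = simulate_assessments(
        subject, week, rater_agreement, seed, rounds=1,
        return_diagnostics=return_diagnostics,
    )
    if return_diagnostics:
        sheets, diag = out
        return (sheets[0], sheets[1]), diag
    return (out[0], out[1])
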