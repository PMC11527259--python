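"""Simulated trial participants: severity trajectories and per-visit mRSS.

The modified Rodnan skin score (mRSS) rates skin thickness 0-3 at 17 body
sites, total 0-51.  Here each subject carries a latent fibrosis severity in
[0, 1] per visit; site scores are produced by thresholding ``3*severity``
plus per-site noise into {0..3}.  The 17 thresholds are offset on an even
sub-grid so that, at zero noise, the total equals ``round(51*severity)`` up
to boundary rounding — a monotone, fine-grained link between severity and
total mRSS.

Default cohort parameters mirror an early-diffuse-SSc trial population:
baseline severity spread corresponding to mRSS ~15-40, a slight mean
improvement over 52 weeks, and per-subject random slopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import ValidationError

N_SITES = 17
MAX_SITE_SCORE = 3
MAX_TOTAL = N_SITES * MAX_SITE_SCORE  # 51

# purpose codes for per-(subject, week, purpose) random streams
_PURPOSE_TRAJECTORY = 1
_PURPOSE_MRSS = 2
_PURPOSE_BIOPSY = 3
_PURPOSE_SHEETS = 4


def stream(seed: int, *keys: int) -> np.random.Generator:
    """Independent generator for (master seed, key...) — inserting or removing
    a subject never shifts another subject's draws."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, keys)]))


@dataclass
class CohortSpec:
    """Generative settings for a simulated cohort."""

    n_subjects: int
    visit_weeks: tuple[int, ...] = (0, 24, 52)
    severity_drift_per_week: float = -0.001
    subject_slope_sd: float = 0.002
    baseline_severity_range: tuple[float, float] = (0.30, 0.78)
    rater_agreement: float = 0.8
    noise_sd_mrss: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if len(self.visit_weeks) < 1:
            raise ValidationError("visit_weeks must be non-empty")
        if not (0.0 <= self.rater_agreement <= 1.0):
            raise ValidationError(
                f"rater_agreement must lie in [0, 1], got {self.rater_agreement}"
            )
        if self.noise_sd_mrss < 0:
            raise ValidationError(
                f"noise_sd_mrss must be non-negative, got {self.noise_sd_mrss}"
            )
        lo, hi = self.baseline_severity_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValidationError(
                f"baseline_severity_range must satisfy 0 <= lo <= hi <= 1, "
                f"got {self.baseline_severity_range}"
            )
        if self.subject_slope_sd < 0:
            raise ValidationError(
                f"subject_slope_sd must be non-negative, got {self.subject_slope_sd}"
            )


@dataclass
class SyntheticSubject:
    """A simulated participant: severity trajectory, visit mRSS, biopsy seeds."""

    subject_id: str
    visit_weeks: tuple[int, ...]
    severity: dict[int, float] = field(default_factory=dict)
    mrss_sites: dict[int, np.ndarray] = field(default_factory=dict)
    biopsy_seeds: dict[int, int] = field(default_factory=dict)

    def mrss_total(self, week: int) -> int:
        """Total mRSS (0-51) at a visit week."""
        return int(self.mrss_sites[week].sum())

    def validate(self) -> None:
        for week in self.visit_weeks:
            s = self.severity[week]
            if not (0.0 <= s <= 1.0):
                raise ValidationError(f"severity[{week}]={s} outside [0, 1]")
            sites = self.mrss_sites[week]
            if sites.shape != (N_SITES,):
                raise ValidationError(f"mrss_sites[{week}] must have {N_SITES} entries")
            if sites.min() < 0 or sites.max() > MAX_SITE_SCORE:
                raise ValidationError(f"site scores at week {week} outside 0..3")


# even sub-grid of threshold offsets so the 17 sites quantize severity at
# 1/51 resolution: sum_i floor(3s + (i+0.5)/17) tracks round(51 s)
_SITE_OFFSETS = (np.arange(N_SITES) + 0.5) / N_SITES


def draw_site_scores(
    severity: float, noise_sd_mrss: float, rng: np.random.Generator
) -> np.ndarray:
    """17 site scores in {0..3} whose expected total tracks round(51*severity)."""
    if not (0.0 <= severity <= 1.0):
        raise ValidationError(f"severity must lie in [0, 1], got {severity}")
    site_noise = (
        rng.normal(0.0, noise_sd_mrss / np.sqrt(N_SITES), size=N_SITES)
        if noise_sd_mrss > 0
        else np.zeros(N_SITES)
    )
    latent = MAX_SITE_SCORE * severity + _SITE_OFFSETS + site_noise
    return np.clip(np.floor(latent), 0, MAX_SITE_SCORE).astype(int)


def simulate_cohort(spec: CohortSpec) -> list[SyntheticSubject]:
    """Draw a cohort of subjects; deterministic for a fixed spec.seed."""
    subjects = []
    lo, hi = spec.baseline_severity_range
    for i in range(spec.n_subjects):
        traj_rng = stream(spec.seed, i, 0, _PURPOSE_TRAJECTORY)
        s0 = traj_rng.uniform(lo, hi)
        slope = spec.severity_drift_per_week + traj_rng.normal(0, spec.subject_slope_sd)
        subject = SyntheticSubject(
            subject_id=f"S{i:03d}", visit_weeks=tuple(spec.visit_weeks)
        )
        for week in spec.visit_weeks:
            sev = float(np.clip(s0 + slope * week, 0.0, 1.0))
            subject.severity[week] = sev
            mrss_rng = stream(spec.seed, i, week, _PURPOSE_MRSS)
            subject.mrss_sites[week] = draw_site_scores(
                sev, spec.noise_sd_mrss, mrss_rng
            )
            subject.biopsy_seeds[week] = int(
                stream(spec.seed, i, week, _PURPOSE_BIOPSY).integers(2**31)
            )
        subject.validate()
        subjects.append(subject)
    return subjects


def sheet_seed(spec_seed: int, subject_index: int, week: int) -> int:
    """Deterministic per-(subject, week) seed for score-sheet simulation."""
    return int(stream(spec_seed, subject_index, week, _PURPOSE_SHEETS).integers(2**31))


def cohort_to_frame(subjects: list[SyntheticSubject]) -> pd.DataFrame:
    """Per-visit clinical table: subject, week, latent severity, total mRSS,
    and the 17 site scores."""
    rows = []
    for subj in subjects:
        for week in subj.visit_weeks:
            row = {
                "subject_id": subj.subject_id,
                "week": week,
                "severity": subj.severity[week],
                "mrss_total": subj.mrss_total(week),
                "biopsy_seed": subj.biopsy_seeds[week],
            }
            for k, v in enumerate(subj.mrss_sites[week]):
                row[f"site_{k:02d}"] = int(v)
            rows.append(row)
    return pd.DataFrame(rows)
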