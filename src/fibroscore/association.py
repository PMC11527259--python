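"""Ordinal-logistic associations and rank correlation.

Each histologic parameter (ordinal response) is regressed on one continuous
exposure — the total mRSS or the Fibrosis Score — with a proportional-odds
model; the reported odds ratio is per 1-unit exposure change, with a Wald
95% CI and p-value.  For a binary outcome the proportional-odds model is
exactly ordinary logistic regression.  The mRSS/Fibrosis-Score relationship
is summarized by Spearman's rank correlation.  No multiple-testing
correction is applied (exploratory analyses); the 0.05 threshold is
annotated, not enforced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ValidationError
from .histology import (
    ALL_PARAMETERS,
    BINARY_PARAMETERS,
    CONTINUOUS_PARAMETERS,
    ORDINAL_PARAMETERS,
    ScoreSheet,
)
from .model import FibrosisScore

#: outcomes with more distinct values than this are quantile-binned before
#: the proportional-odds fit (threshold count grows with level count and
#: small samples make many-threshold fits unstable)
MAX_ORDINAL_LEVELS = 8

#: |coefficient| above this is treated as complete separation
_SEPARATION_COEF = 15.0

SIGNIFICANCE_THRESHOLD = 0.05


@dataclass(frozen=True)
class OrResult:
    parameter: str
    exposure: str
    odds_ratio: float
    ci95: tuple[float, float]
    p: float
    n: int
    separated: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n: int


def ordinal_logistic_or(
    outcome: Sequence,
    exposure: Sequence[float],
    parameter: str = "",
    exposure_name: str = "",
    tol: float = 1e-8,
) -> OrResult:
    """Proportional-odds OR per 1-unit change of a continuous exposure.

    Complete separation is flagged (infinite-OR sentinel with a warning),
    not raised.  A single-level outcome is a validation error; callers that
    sweep parameters should skip those with a reason.
    """
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    y = np.asarray(outcome)
    x = np.asarray(exposure, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValidationError("outcome and exposure must be 1-D and equal length")
    levels = np.unique(y)
    if levels.size < 2:
        raise ValidationError(
            f"outcome '{parameter}' has a single observed level; no OR is defined"
        )
    if np.unique(x).size < 2:
        raise ValidationError(
            f"exposure '{exposure_name}' is constant; no OR is defined"
        )
    codes = np.searchsorted(levels, y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = OrderedModel(codes, x[:, None], distr="logit")
        res = model.fit(method="bfgs", maxiter=500, disp=0, gtol=tol)
    coef = float(res.params[0])
    bse = float(res.bse[0])
    converged = bool(res.mle_retvals.get("converged", True))
    if not np.isfinite(coef) or not np.isfinite(bse) or abs(coef) > _SEPARATION_COEF:
        warnings.warn(
            f"complete separation suspected for '{parameter}' vs "
            f"'{exposure_name}'; returning an infinite-OR sentinel",
            stacklevel=2,
        )
        sign = np.sign(coef) if np.isfinite(coef) else 1.0
        orr = np.inf if sign >= 0 else 0.0
        return OrResult(parameter, exposure_name, orr, (0.0, np.inf),
                        np.nan, int(y.size), separated=True)
    if not converged:
        warnings.warn(
            f"proportional-odds fit did not fully converge for '{parameter}'",
            stacklevel=2,
        )
    lo, hi = np.exp(coef - 1.959964 * bse), np.exp(coef + 1.959964 * bse)
    return OrResult(
        parameter=parameter,
        exposure=exposure_name,
        odds_ratio=float(np.exp(coef)),
        ci95=(float(lo), float(hi)),
        p=float(res.pvalues[0]),
        n=int(y.size),
    )


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with midrank ties and a two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValidationError("need equal-length 1-D vectors with n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValidationError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p=float(p), n=int(x.size))


# --------------------------------------------------------------------------
# Consensus and report
# --------------------------------------------------------------------------

def consensus_sheet_values(sheets: Sequence[ScoreSheet]) -> dict[str, object]:
    """Collapse one biopsy's sheets (2 raters x up to 2 rounds) to consensus.

    Binary: "yes" iff all raters agree "yes"; discordant values resolve by
    majority across rounds, ties to rater A's round-1 call.  Ordinal and
    quantitative parameters: mean of available values (ordinal rounded back
    to an integer level).
    """
    raters = sorted({s.rater_id for s in sheets})
    values: dict[str, object] = {}
    sheets_sorted = sorted(sheets, key=lambda s: (s.assessment_round, s.rater_id))
    for p in ALL_PARAMETERS:
        vals = [s.values[p] for s in sheets_sorted if s.values[p] is not None]
        if not vals:
            values[p] = None
            continue
        if p in BINARY_PARAMETERS:
            if all(v == vals[0] for v in vals):
                values[p] = vals[0]
            else:
                yes, no = vals.count("yes"), vals.count("no")
                if yes != no:
                    values[p] = "yes" if yes > no else "no"
                else:  # tie: defer to first rater's earliest call
                    first = next(
                        s for s in sheets_sorted
                        if s.rater_id == raters[0] and s.values[p] is not None
                    )
                    values[p] = first.values[p]
        elif p in ORDINAL_PARAMETERS:
            values[p] = int(round(float(np.mean(vals))))
        else:
            values[p] = float(np.mean(vals))
    return values


def _outcome_vector(series: pd.Series, parameter: str) -> np.ndarray:
    if parameter in BINARY_PARAMETERS:
        return series.map({"no": 0, "yes": 1}).to_numpy()
    vals = pd.to_numeric(series, errors="coerce").to_numpy(dtype=float)
    levels = np.unique(vals[~np.isnan(vals)])
    if parameter in CONTINUOUS_PARAMETERS and levels.size > MAX_ORDINAL_LEVELS:
        # quantile-bin quantitative outcomes into ordered categories
        ranks = stats.rankdata(vals, method="average") / len(vals)
        return np.ceil(ranks * MAX_ORDINAL_LEVELS).astype(int)
    return vals


@dataclass
class AssociationReport:
    or_table: pd.DataFrame
    correlation: CorrelationResult
    skipped: list[tuple[str, str, str]]  # (parameter, exposure, reason)


def association_report(
    sheets: Sequence[ScoreSheet],
    mrss_totals: Mapping[str, float],
    scores: Sequence[FibrosisScore] | Mapping[str, float],
) -> AssociationReport:
    """ORs for every eligible parameter x {mRSS, FibrosisScore}, plus the
    Spearman correlation between the two exposures.

    Sheets are collapsed to rater consensus per biopsy and joined on
    biopsy_id; join failures list the orphan biopsies.  No multiplicity
    correction is applied; the table annotates p < 0.05.
    """
    score_map = (
        {s.biopsy_id: s.score for s in scores}
        if not isinstance(scores, Mapping)
        else dict(scores)
    )
    by_biopsy: dict[str, list[ScoreSheet]] = {}
    for s in sheets:
        by_biopsy.setdefault(s.biopsy_id, []).append(s)
    orphans = sorted(
        set(by_biopsy) - set(mrss_totals)
    ) + sorted(set(by_biopsy) - set(score_map))
    if orphans:
        raise DataError(f"biopsies missing exposure values: {sorted(set(orphans))}")

    biopsies = sorted(by_biopsy)
    consensus = pd.DataFrame(
        [consensus_sheet_values(by_biopsy[b]) for b in biopsies],
        index=biopsies,
    )
    exposures = {
        "mRSS": np.array([mrss_totals[b] for b in biopsies], dtype=float),
        "FibrosisScore": np.array([score_map[b] for b in biopsies], dtype=float),
    }

    rows, skipped = [], []
    for parameter in ALL_PARAMETERS:
        outcome = _outcome_vector(consensus[parameter], parameter)
        ok = ~pd.isna(outcome)
        for exp_name, exp_vals in exposures.items():
            y, x = outcome[ok], exp_vals[ok]
            if np.unique(y).size < 2:
                skipped.append((parameter, exp_name, "single observed level"))
                continue
            try:
                res = ordinal_logistic_or(y, x, parameter, exp_name)
            except ValidationError as exc:
                skipped.append((parameter, exp_name, str(exc)))
                continue
            rows.append(
                {
                    "parameter": parameter,
                    "exposure": exp_name,
                    "or": res.odds_ratio,
                    "ci_lo": res.ci95[0],
                    "ci_hi": res.ci95[1],
                    "p": res.p,
                    "n": res.n,
                    "significant": bool(res.p < SIGNIFICANCE_THRESHOLD)
                    if np.isfinite(res.p)
                    else False,
                    "separated": res.separated,
                }
            )
    or_table = pd.DataFrame(
        rows,
        columns=["parameter", "exposure", "or", "ci_lo", "ci_hi", "p", "n",
                 "significant", "separated"],
    )
    or_table.attrs["multiplicity_correction"] = "none (exploratory)"
    or_table.attrs["significance_threshold"] = SIGNIFICANCE_THRESHOLD

    try:
        corr = spearman_correlation(exposures["mRSS"], exposures["FibrosisScore"])
    except ValidationError as exc:
        # e.g. a fully shrunk (intercept-only) model scores every biopsy
        # identically; the report still emits, with the correlation undefined
        warnings.warn(f"mRSS/FibrosisScore correlation undefined: {exc}", stacklevel=2)
        corr = CorrelationResult(rho=float("nan"), p=float("nan"),
                                 n=len(exposures["mRSS"]))
    return AssociationReport(or_table=or_table, correlation=corr, skipped=skipped)
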