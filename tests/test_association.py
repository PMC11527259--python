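"""Proportional-odds ORs, Spearman correlation, consensus and report."""

import warnings

import numpy as np
import pandas as pd
import pytest

import fibroscore as fs
from fibroscore.association import (
    association_report,
    consensus_sheet_values,
    ordinal_logistic_or,
    spearman_correlation,
)
from fibroscore.errors import ValidationError
from fibroscore.histology import BINARY_PARAMETERS, ScoreSheet
from fibroscore.synthetic.cohort import SyntheticSubject
from fibroscore.synthetic.sheets import simulate_score_sheets
from oracles import logistic_newton, simulate_proportional_odds, spearman_no_ties


# ------------------------------------------------------------------ Spearman

def test_spearman_monotone_extremes():
    x = np.arange(10, dtype=float)
    assert spearman_correlation(x, np.exp(x)).rho == pytest.approx(1.0)
    assert spearman_correlation(x, -(x**3)).rho == pytest.approx(-1.0)


def test_spearman_hand_computed_permutation():
    """x=[1..5], y=[2,1,4,3,5]: sum d^2 = 4 -> rho = 1 - 24/120 = 0.8;
    the classic displaced pairs give the closed form exactly."""
    x = [1, 2, 3, 4, 5]
    y = [2, 1, 4, 3, 5]
    res = spearman_correlation(x, y)
    assert res.rho == pytest.approx(spearman_no_ties(np.array(x), np.array(y)))
    assert res.rho == pytest.approx(0.8)


def test_spearman_matches_closed_form_on_random_permutations():
    rng = np.random.default_rng(0)
    for n in (4, 7, 15, 30):
        x = np.arange(n, dtype=float)
        y = rng.permutation(n).astype(float)
        assert spearman_correlation(x, y).rho == pytest.approx(
            spearman_no_ties(x, y), abs=1e-12
        )


def test_spearman_constant_vector_rejected():
    with pytest.raises(ValidationError, match="constant"):
        spearman_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ------------------------------------------------------------ ordinal logistic

def test_binary_outcome_reproduces_cross_product_odds_ratio():
    """2x2 table [[30,10],[10,30]] with exposure 0/1: OR = ad/bc = 9.0, which
    both the proportional-odds fit and an independent Newton logistic give."""
    y = np.array([0] * 30 + [1] * 10 + [0] * 10 + [1] * 30)
    x = np.array([0.0] * 40 + [1.0] * 40)
    res = ordinal_logistic_or(y, x, "toy", "exposure")
    assert res.odds_ratio == pytest.approx(9.0, abs=1e-3)
    assert res.ci95[0] < 9.0 < res.ci95[1]
    assert np.exp(logistic_newton(x, y)) == pytest.approx(9.0, abs=1e-6)


def test_binary_path_matches_newton_oracle_on_2x3_design():
    rng = np.random.default_rng(5)
    x = np.repeat([0.0, 1.0, 2.0], 40)
    p = 1 / (1 + np.exp(-(-1.0 + 0.8 * x)))
    y = (rng.uniform(size=x.size) < p).astype(int)
    res = ordinal_logistic_or(y, x, "toy", "exposure")
    oracle = np.exp(logistic_newton(x, y))
    assert res.odds_ratio == pytest.approx(oracle, abs=1e-4)


def test_null_exposure_gives_odds_ratio_near_one():
    """Permuted labels at n=1000: OR must sit in [0.9, 1.1]."""
    rng = np.random.default_rng(11)
    y = rng.integers(0, 4, size=1000)
    x = rng.normal(size=1000)
    res = ordinal_logistic_or(y, x, "null", "exposure")
    assert 0.9 <= res.odds_ratio <= 1.1


def test_proportional_odds_recovery_covers_truth():
    """Simulated proportional-odds data with true per-unit OR 2.0 at n=2000:
    the estimate's 95% CI covers the truth."""
    rng = np.random.default_rng(21)
    y, x = simulate_proportional_odds(2000, np.log(2.0), np.array([-1.0, 0.5, 2.0]), rng)
    res = ordinal_logistic_or(y, x, "sim", "exposure")
    assert res.ci95[0] <= 2.0 <= res.ci95[1]
    assert res.odds_ratio == pytest.approx(2.0, rel=0.15)


def test_complete_separation_yields_sentinel_not_crash():
    y = np.array([0] * 20 + [1] * 20)
    x = np.concatenate([np.linspace(-3, -1, 20), np.linspace(1, 3, 20)])
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = ordinal_logistic_or(y, x, "sep", "exposure")
    assert res.separated
    assert np.isinf(res.odds_ratio) or res.odds_ratio == 0.0
    assert any("separation" in str(w.message) for w in caught)


def test_single_level_outcome_rejected_with_reason():
    with pytest.raises(ValidationError, match="single observed level"):
        ordinal_logistic_or(np.ones(10), np.arange(10.0), "flat", "exposure")


# ---------------------------------------------------------------- consensus

def _sheet(bid, rater, rnd=1, **overrides):
    values = {p: "no" for p in BINARY_PARAMETERS}
    values.update({"matrix_he": 1, "matrix_trichrome": 1, "cd34_stain": 1,
                   "asma_stain": 1, "mean_epidermal_thickness_um": 70.0,
                   "perivascular_cd3_count": 10, "perivascular_cd8_count": 4,
                   "pct_cd8_among_cd3": 40.0})
    values.update(overrides)
    return ScoreSheet(bid, rater, values, assessment_round=rnd)


def test_consensus_yes_requires_both_raters():
    sheets = [
        _sheet("b", "rater_A", telangiectasia="yes"),
        _sheet("b", "rater_B", telangiectasia="yes"),
    ]
    assert consensus_sheet_values(sheets)["telangiectasia"] == "yes"
    sheets = [
        _sheet("b", "rater_A", telangiectasia="yes"),
        _sheet("b", "rater_B", telangiectasia="no"),
    ]
    # discordant 1-1 tie resolves to rater A's call
    assert consensus_sheet_values(sheets)["telangiectasia"] == "yes"


def test_consensus_majority_across_rounds():
    sheets = [
        _sheet("b", "rater_A", 1, calcification="no"),
        _sheet("b", "rater_B", 1, calcification="yes"),
        _sheet("b", "rater_A", 2, calcification="no"),
        _sheet("b", "rater_B", 2, calcification="no"),
    ]
    assert consensus_sheet_values(sheets)["calcification"] == "no"


def test_consensus_averages_ordinal_and_continuous():
    sheets = [
        _sheet("b", "rater_A", matrix_trichrome=1, mean_epidermal_thickness_um=60.0),
        _sheet("b", "rater_B", matrix_trichrome=2, mean_epidermal_thickness_um=80.0),
    ]
    values = consensus_sheet_values(sheets)
    assert values["matrix_trichrome"] == 2  # mean 1.5 rounds to even -> 2
    assert values["mean_epidermal_thickness_um"] == 70.0


# ------------------------------------------------------------------- report

def _severity_cohort_sheets(n=120, seed=0):
    rng = np.random.default_rng(seed)
    sheets, mrss, scores = [], {}, {}
    for k in range(n):
        sev = float(rng.uniform())
        subj = SyntheticSubject(
            f"P{k:03d}", (0,), {0: sev}, {0: np.zeros(17, int)}, {0: 1}
        )
        a, b = simulate_score_sheets(subj, 0, 0.9, seed=5_000 + k)
        sheets += [a, b]
        bid = a.biopsy_id
        mrss[bid] = 51 * sev + rng.normal(0, 2)
        scores[bid] = 51 * sev + rng.normal(0, 4)
    return sheets, mrss, scores


def test_report_direction_follows_generative_link():
    """Severity drives exposures and parameters jointly, so severity-linked
    binary parameters must show OR > 1 against both exposures."""
    sheets, mrss, scores = _severity_cohort_sheets(n=200)
    report = association_report(sheets, mrss, scores)
    table = report.or_table
    finite = table[np.isfinite(table["or"])]
    binary = finite[finite["parameter"].isin(BINARY_PARAMETERS)]
    assert len(binary) >= 10
    assert (binary["or"] > 1).mean() > 0.9
    assert report.correlation.rho > 0.8


def test_report_is_deterministic():
    sheets, mrss, scores = _severity_cohort_sheets(n=60)
    r1 = association_report(sheets, mrss, scores)
    r2 = association_report(sheets, mrss, scores)
    pd.testing.assert_frame_equal(r1.or_table, r2.or_table)
    assert r1.correlation == r2.correlation


def test_constant_parameters_are_skipped_with_reasons():
    sheets = [
        _sheet(f"b{k}", r) for k in range(10) for r in ("rater_A", "rater_B")
    ]
    mrss = {f"b{k}": float(k) for k in range(10)}
    scores = {f"b{k}": float(k) for k in range(10)}
    report = association_report(sheets, mrss, scores)
    # every binary/ordinal parameter is constant -> skipped
    skipped_params = {p for p, _, _ in report.skipped}
    assert set(BINARY_PARAMETERS) <= skipped_params
    assert not (report.or_table["parameter"].isin(BINARY_PARAMETERS)).any()


def test_orphan_biopsies_raise_data_error():
    from fibroscore.errors import DataError

    sheets = [_sheet("known", "rater_A"), _sheet("known", "rater_B"),
              _sheet("orphan", "rater_A"), _sheet("orphan", "rater_B")]
    with pytest.raises(DataError, match="orphan"):
        association_report(sheets, {"known": 10.0}, {"known": 9.0})
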