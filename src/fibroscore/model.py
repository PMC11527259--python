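"""Penalized linear Fibrosis Score model.

The model regresses the total modified Rodnan skin score (mRSS, 0-51) on the
per-patch quantitative image features: every patch of a biopsy is a training
row labeled with that biopsy's total mRSS, the fit is L1-penalized least
squares (lasso) over a log-spaced penalty grid (default 16 values from 1e-5
to 1e3), and the biopsy-level Fibrosis Score is the arithmetic mean of the
per-patch predictions.  The penalty is selected by patient-grouped
cross-validation — folds never split a subject, so within-patient
correlation cannot leak — scored on the held-out *biopsy-level* squared
error (patch predictions are averaged per biopsy before scoring, because the
deliverable is the biopsy score).  Features are standardized with
training-fold statistics only.  At the strong-penalty end of the grid all
coefficients vanish and the model predicts the training-mean mRSS.

Scores are not clipped to [0, 51]; the score's range is arbitrary and only
approximates the mRSS range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import Lasso
from sklearn.model_selection import GroupKFold, LeaveOneGroupOut
from sklearn.utils.validation import check_is_fitted

from .errors import DataError, DimensionError, FitError, ValidationError
from .features import QifMatrix


@dataclass
class LambdaGrid:
    """Log-spaced penalty grid; values[0] = lo, values[-1] = hi."""

    values: np.ndarray
    n: int
    lo: float
    hi: float


def make_lambda_grid(n: int = 16, lo: float = 1e-5, hi: float = 1e3) -> LambdaGrid:
    """values[k] = 10**(log10 lo + k*(log10 hi - log10 lo)/(n-1))."""
    if n < 2:
        raise ValidationError(f"lambda grid needs n >= 2, got n={n}")
    if not (0 < lo < hi):
        raise ValidationError(f"lambda grid needs 0 < lo < hi, got lo={lo}, hi={hi}")
    values = np.logspace(np.log10(lo), np.log10(hi), n)
    return LambdaGrid(values=values, n=n, lo=lo, hi=hi)


@dataclass(frozen=True)
class FibrosisScore:
    """Biopsy-level score: exact arithmetic mean of per-patch predictions."""

    biopsy_id: str
    score: float
    n_patches_used: int


class FibrosisScorer(RegressorMixin, BaseEstimator):
    """Lasso mRSS regression on patch features with patch-mean aggregation.

    Parameters
    ----------
    lambdas : array-like or None
        Penalty grid; ``None`` means the default 16-value grid from 1e-5 to
        1e3.  The penalty multiplies the L1 norm in the objective
        ``(1/2m)||y - Xb||^2 + lambda*||b||_1`` (m = number of patch rows).
    cv : "auto", int, or None
        Grouped CV for penalty selection: "auto" uses leave-one-subject-out
        when there are <= 15 subjects, else 5-fold grouped; an int requests
        that many grouped folds; ``None`` behaves like "auto".
    standardize : bool
        Standardize features with training-fold means/SDs (recommended: the
        L1 penalty is only fair across features on a common scale).
    tol, max_iter : solver controls passed to the coordinate-descent lasso.

    Attributes
    ----------
    intercept_, coef_ : fitted linear model on the standardized scale.
    lambda_ : selected penalty.
    cv_results_ : per-lambda mean held-out biopsy-level squared error.
    cv_predictions_ : held-out biopsy-level predictions at the selected
        penalty (each biopsy scored by a model that never saw its subject).
    scale_mean_, scale_std_ : per-feature standardization constants.
    """

    _loso_max_subjects = 15

    def __init__(
        self,
        lambdas: Sequence[float] | None = None,
        cv: str | int | None = "auto",
        standardize: bool = True,
        tol: float = 1e-4,
        max_iter: int = 20_000,
        random_state: int = 0,
    ):
        self.lambdas = lambdas
        self.cv = cv
        self.standardize = standardize
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _grid(self) -> np.ndarray:
        if self.lambdas is None:
            return make_lambda_grid().values
        values = np.asarray(self.lambdas, dtype=float)
        if values.ndim != 1 or values.size < 1 or np.any(values <= 0):
            raise ValidationError("lambdas must be a 1-D array of positive values")
        return values

    def _splitter(self, n_subjects: int):
        cv = "auto" if self.cv is None else self.cv
        if cv == "auto":
            if n_subjects <= self._loso_max_subjects:
                return LeaveOneGroupOut()
            return GroupKFold(n_splits=5)
        if isinstance(cv, int):
            if cv < 2 or cv > n_subjects:
                raise ValidationError(
                    f"cv={cv} incompatible with {n_subjects} subjects"
                )
            return GroupKFold(n_splits=cv)
        raise ValidationError(f"unrecognized cv spec: {cv!r}")

    @staticmethod
    def _scaling(X: np.ndarray, enabled: bool) -> tuple[np.ndarray, np.ndarray]:
        if not enabled:
            return np.zeros(X.shape[1]), np.ones(X.shape[1])
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std[std == 0] = 1.0  # constant features carry no signal either way
        return mean, std

    def _path(self, X: np.ndarray, y: np.ndarray, grid: np.ndarray) -> list[Lasso]:
        """Lasso fits along the grid, warm-starting from strong to weak."""
        fits = []
        order = np.argsort(grid)[::-1]
        model = Lasso(
            alpha=float(grid[order[0]]), warm_start=True,
            tol=self.tol, max_iter=self.max_iter,
        )
        by_lambda: dict[int, Lasso] = {}
        for k in order:
            model.set_params(alpha=float(grid[k]))
            model.fit(X, y)
            frozen = Lasso(alpha=float(grid[k]))
            frozen.coef_ = model.coef_.copy()
            frozen.intercept_ = float(model.intercept_)
            by_lambda[k] = frozen
        for k in range(len(grid)):
            fits.append(by_lambda[k])
        return fits

    # -- sklearn API -------------------------------------------------------

    def fit(
        self,
        X,
        y,
        groups: Sequence | None = None,
        biopsy_ids: Sequence | None = None,
    ):
        """Fit on stacked patch rows.

        X : (n_rows, n_features) patch feature rows.
        y : per-row labels (each patch carries its biopsy's total mRSS).
        groups : per-row subject ids (required; folds never split a subject).
        biopsy_ids : per-row biopsy ids (required; selection error is scored
            at the biopsy level after patch-mean aggregation).
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or y.shape != (X.shape[0],):
            raise ValidationError("X must be (n_rows, n_features) with matching y")
        if groups is None or biopsy_ids is None:
            raise ValidationError("groups and biopsy_ids are required")
        groups = np.asarray(groups)
        biopsy_ids = np.asarray(biopsy_ids)
        if groups.shape != (X.shape[0],) or biopsy_ids.shape != (X.shape[0],):
            raise ValidationError("groups and biopsy_ids must align with rows of X")
        subj_of_biopsy: dict = {}
        for b, g in zip(biopsy_ids, groups):
            if b in subj_of_biopsy and subj_of_biopsy[b] != g:
                raise DataError(
                    f"biopsy {b!r} mapped to two subjects: "
                    f"{subj_of_biopsy[b]!r} and {g!r}"
                )
            subj_of_biopsy[b] = g
        n_subjects = len(np.unique(groups))
        if n_subjects < 3:
            raise ValidationError(
                f"need >= 3 subjects for grouped cross-validation, got {n_subjects}"
            )
        if np.allclose(y, y[0]):
            raise FitError("degenerate fit: outcome is constant across all rows")

        grid = self._grid()
        splitter = self._splitter(n_subjects)

        sq_errors: dict[int, list[float]] = {k: [] for k in range(len(grid))}
        heldout_rows: list[dict] = []
        for train_idx, test_idx in splitter.split(X, y, groups):
            assert not set(groups[train_idx]) & set(groups[test_idx])
            mean, std = self._scaling(X[train_idx], self.standardize)
            Xtr = (X[train_idx] - mean) / std
            Xte = (X[test_idx] - mean) / std
            fits = self._path(Xtr, y[train_idx], grid)
            test_biopsies = biopsy_ids[test_idx]
            for k, f in enumerate(fits):
                pred = Xte @ f.coef_ + f.intercept_
                frame = pd.DataFrame(
                    {"biopsy": test_biopsies, "pred": pred, "y": y[test_idx]}
                )
                per_biopsy = frame.groupby("biopsy").mean()
                sq_errors[k].extend(
                    ((per_biopsy["pred"] - per_biopsy["y"]) ** 2).tolist()
                )
                for biopsy, row in per_biopsy.iterrows():
                    heldout_rows.append(
                        {"lambda_index": k, "biopsy_id": biopsy,
                         "heldout_score": row["pred"], "y": row["y"]}
                    )

        cv_mse = np.array([np.mean(sq_errors[k]) for k in range(len(grid))])
        best = int(np.argmin(cv_mse))
        self.lambda_ = float(grid[best])
        self.cv_results_ = pd.DataFrame(
            {"lambda": grid, "heldout_biopsy_mse": cv_mse}
        )
        heldout = pd.DataFrame(heldout_rows)
        self.cv_predictions_ = (
            heldout[heldout["lambda_index"] == best]
            .drop(columns="lambda_index")
            .sort_values("biopsy_id")
            .reset_index(drop=True)
        )

        self.scale_mean_, self.scale_std_ = self._scaling(X, self.standardize)
        Xs = (X - self.scale_mean_) / self.scale_std_
        final = Lasso(alpha=self.lambda_, tol=self.tol, max_iter=self.max_iter)
        final.fit(Xs, y)
        self.coef_ = final.coef_.copy()
        self.intercept_ = float(final.intercept_)
        self.n_features_in_ = X.shape[1]
        self.training_meta_ = {
            "n_subjects": int(n_subjects),
            "n_biopsies": int(len(subj_of_biopsy)),
            "n_rows": int(X.shape[0]),
            "random_state": self.random_state,
        }
        return self

    def predict(self, X) -> np.ndarray:
        """Per-patch predicted mRSS values."""
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise DimensionError(
                f"expected {self.n_features_in_} features, got shape {X.shape}"
            )
        Xs = (X - self.scale_mean_) / self.scale_std_
        return Xs @ self.coef_ + self.intercept_

    def score_biopsy(self, qif: QifMatrix) -> FibrosisScore:
        """Fibrosis Score: mean per-patch prediction; never clipped."""
        preds = self.predict(qif.values)
        return FibrosisScore(
            biopsy_id=qif.biopsy_id,
            score=float(preds.mean()),
            n_patches_used=int(preds.size),
        )

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        check_is_fitted(self, "coef_")
        nz = np.nonzero(self.coef_)[0]
        payload = {
            "intercept": self.intercept_,
            "lambda_star": self.lambda_,
            "n_features": int(self.n_features_in_),
            "coefficients": {int(i): float(self.coef_[i]) for i in nz},
            "scale_mean": self.scale_mean_.tolist(),
            "scale_std": self.scale_std_.tolist(),
            "cv_table": self.cv_results_.to_dict(orient="list"),
            "training_meta": self.training_meta_,
        }
        text = json.dumps(payload, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FibrosisScorer":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        model = cls()
        model.n_features_in_ = payload["n_features"]
        model.intercept_ = payload["intercept"]
        model.lambda_ = payload["lambda_star"]
        coef = np.zeros(model.n_features_in_)
        for i, v in payload["coefficients"].items():
            coef[int(i)] = v
        model.coef_ = coef
        model.scale_mean_ = np.asarray(payload["scale_mean"], dtype=float)
        model.scale_std_ = np.asarray(payload["scale_std"], dtype=float)
        model.cv_results_ = pd.DataFrame(payload["cv_table"])
        model.training_meta_ = payload["training_meta"]
        return model


# --------------------------------------------------------------------------
# Functional wrappers over the estimator
# --------------------------------------------------------------------------

def stack_qifs(
    qifs: Sequence[QifMatrix],
    mrss_totals: Mapping[str, float],
    subject_of: Mapping[str, str],
):
    """Stack per-biopsy QIF matrices into (X, y, groups, biopsy_ids) rows."""
    widths = {q.n_features for q in qifs}
    if len(widths) > 1:
        raise DimensionError(f"inconsistent feature widths across biopsies: {widths}")
    missing = [q.biopsy_id for q in qifs if q.biopsy_id not in mrss_totals]
    if missing:
        raise DataError(f"biopsies lacking an mRSS total: {missing}")
    missing = [q.biopsy_id for q in qifs if q.biopsy_id not in subject_of]
    if missing:
        raise DataError(f"biopsies lacking a subject mapping: {missing}")
    X = np.vstack([q.values for q in qifs])
    y = np.concatenate([np.full(q.n_patches, mrss_totals[q.biopsy_id]) for q in qifs])
    groups = np.concatenate(
        [np.full(q.n_patches, subject_of[q.biopsy_id], dtype=object) for q in qifs]
    )
    biopsy_ids = np.concatenate(
        [np.full(q.n_patches, q.biopsy_id, dtype=object) for q in qifs]
    )
    return X, y, groups, biopsy_ids


def fit_fibrosis_model(
    qifs: Sequence[QifMatrix],
    mrss_totals: Mapping[str, float],
    subject_of: Mapping[str, str],
    grid: LambdaGrid | None = None,
    cv: str | int | None = "auto",
    seed: int = 0,
) -> FibrosisScorer:
    """Fit the Fibrosis Score model from per-biopsy QIF matrices."""
    X, y, groups, biopsy_ids = stack_qifs(qifs, mrss_totals, subject_of)
    model = FibrosisScorer(
        lambdas=None if grid is None else grid.values, cv=cv, random_state=seed
    )
    return model.fit(X, y, groups=groups, biopsy_ids=biopsy_ids)


def predict_fibrosis_score(model: FibrosisScorer, qif: QifMatrix) -> FibrosisScore:
    return model.score_biopsy(qif)
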