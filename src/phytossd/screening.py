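"""Cook's-distance screening of extreme-outlier dose records.

Before fitting the crude SSD, reported doses are regressed on covariates that
proxy study quality — the number of specimens treated (``n``) and the highest
tested dose with observed treatment failure (``F``) — and observations with
outsized influence on that linear model are removed. Influence is measured by
Cook's distance; two threshold rules are supported: four times the mean
distance (default) and 4/n.

A covariate that is missing for *every* screenable record is dropped from the
design matrix (a literature table often omits ``F`` entirely), so the model
degrades gracefully from ``dose ~ n + F`` to ``dose ~ n``. Records missing a
retained covariate are not screenable and pass through as kept, with a
warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from sklearn.base import BaseEstimator, OutlierMixin

from .records import DoseRecord

__all__ = ["ScreeningResult", "CooksDistanceScreener", "screen_outliers"]

THRESHOLD_RULES = ("four_times_mean", "four_over_n")


@dataclass
class ScreeningResult:
    """Outcome of one screening pass; kept + removed partition the input."""

    kept: list[DoseRecord]
    removed: list[tuple[DoseRecord, float]]  # (record, cooks_distance)
    threshold: float
    threshold_rule: str
    cooks_distances: dict[int, float] = field(default_factory=dict)  # input index -> D_i
    model_params: dict[str, float] = field(default_factory=dict)
    covariates: tuple[str, ...] = ()
    skipped: bool = False


class CooksDistanceScreener(OutlierMixin, BaseEstimator):
    """Flag high-influence observations of a linear model via Cook's distance.

    scikit-learn-style outlier detector: ``fit_predict(X, y)`` returns +1 for
    inliers and -1 for observations whose Cook's distance exceeds the
    threshold. Rows of ``X`` containing NaN are not screenable and are always
    inliers.

    Parameters
    ----------
    threshold_rule : {"four_times_mean", "four_over_n"}
        ``four_times_mean`` removes observations with D_i > 4 * mean(D);
        ``four_over_n`` removes D_i > 4/n, n the number of fitted rows.
    min_complete : int
        Minimum number of complete rows needed to fit; below it screening is
        skipped (everything kept) with a warning.
    """

    def __init__(self, threshold_rule: str = "four_times_mean", min_complete: int = 4):
        self.threshold_rule = threshold_rule
        self.min_complete = min_complete

    def fit(self, X, y):
        if self.threshold_rule not in THRESHOLD_RULES:
            raise ValueError(f"threshold_rule must be one of {THRESHOLD_RULES}")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and np.asarray(y).size != 1:
            X = X.T
        y = np.asarray(y, dtype=float)

        # drop covariates missing everywhere; then rows missing any survivor
        col_ok = ~np.all(np.isnan(X), axis=0)
        self.used_columns_ = np.flatnonzero(col_ok)
        Xu = X[:, col_ok]
        complete = ~np.any(np.isnan(Xu), axis=1) & np.isfinite(y)
        self.complete_mask_ = complete
        n_complete = int(complete.sum())

        self.cooks_distance_ = np.full(y.size, np.nan)
        self.skipped_ = False
        if Xu.shape[1] == 0 or n_complete < max(self.min_complete, Xu.shape[1] + 2):
            warnings.warn(
                "too few complete records to fit the screening model; "
                "screening skipped, all records kept",
                stacklevel=2,
            )
            self.skipped_ = True
            self.threshold_ = np.inf
            self.model_params_ = {}
            return self

        design = sm.add_constant(Xu[complete], has_constant="add")
        if np.linalg.matrix_rank(design) < design.shape[1]:
            warnings.warn(
                "screening design matrix is rank deficient (collinear "
                "covariates); using a pseudo-inverse least-squares fit",
                stacklevel=2,
            )
        res = sm.OLS(y[complete], design).fit()
        self.model_params_ = {
            name: float(v)
            for name, v in zip(["intercept"] + [f"x{i}" for i in self.used_columns_],
                               res.params)
        }
        # an exact (to rounding) fit has no meaningful influence structure
        exact_fit = res.mse_resid <= 1e-20 * float(np.mean(y[complete] ** 2))
        if res.df_resid <= 0 or exact_fit:
            d = np.zeros(n_complete)
        else:
            d = res.get_influence().cooks_distance[0]
        self.cooks_distance_[complete] = d
        if self.threshold_rule == "four_times_mean":
            mean_d = float(np.mean(d))
            self.threshold_ = 4.0 * mean_d if mean_d > 0 else np.inf
        else:
            self.threshold_ = 4.0 / n_complete
        return self

    def predict(self, X=None) -> np.ndarray:
        """+1 inlier / -1 outlier for the rows seen by :meth:`fit`."""
        d = self.cooks_distance_
        out = np.ones(d.size, dtype=int)
        with np.errstate(invalid="ignore"):
            out[np.nan_to_num(d, nan=-np.inf) > self.threshold_] = -1
        return out

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).predict()


def screen_outliers(
    records: Sequence[DoseRecord],
    threshold_rule: str = "four_times_mean",
) -> ScreeningResult:
    """One screening pass of dose records against ``dose ~ n + F``.

    Covariates that no record reports are dropped from the model; records
    missing a retained covariate are kept unscreened with a warning.
    """
    records = list(records)
    if not records:
        raise ValueError("records must be non-empty")
    X = np.array(
        [
            [
                np.nan if r.n_treated is None else float(r.n_treated),
                np.nan if r.highest_fail_dose_gy is None else r.highest_fail_dose_gy,
            ]
            for r in records
        ]
    )
    y = np.array([r.dose_gy for r in records])
    screener = CooksDistanceScreener(threshold_rule=threshold_rule)
    flags = screener.fit_predict(X, y)

    if not screener.skipped_ and not screener.complete_mask_.all():
        n_skipped = int((~screener.complete_mask_).sum())
        warnings.warn(
            f"{n_skipped} record(s) missing screening covariates were kept "
            "without screening",
            stacklevel=2,
        )

    kept = [r for r, f in zip(records, flags) if f == 1]
    removed = [
        (r, float(screener.cooks_distance_[i]))
        for i, (r, f) in enumerate(zip(records, flags))
        if f == -1
    ]
    covariate_names = tuple(
        name for i, name in enumerate(("n_treated", "highest_fail_dose_gy"))
        if i in getattr(screener, "used_columns_", [])
    )
    return ScreeningResult(
        kept=kept,
        removed=removed,
        threshold=float(screener.threshold_),
        threshold_rule=threshold_rule,
        cooks_distances={
            i: float(d)
            for i, d in enumerate(screener.cooks_distance_)
            if np.isfinite(d)
        },
        model_params=screener.model_params_,
        covariates=covariate_names,
        skipped=screener.skipped_,
    )
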