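"""Feature-level filtering, QC diagnostics and Pareto scaling of peak tables.

Background removal drops every feature detected (above an explicit intensity
threshold) in at least one blank (solvent) run or pure-additive run, so
features belonging to the supplied hormones and growth regulators themselves
never enter the models. QC dispersion is reported as a per-feature coefficient
of variation over pooled-sample injections (diagnostic only by default).
Pareto scaling -- mean-centering then division by the square root of the
sample standard deviation -- is the normalisation applied before modelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "FilterReport",
    "remove_background_features",
    "qc_cv",
    "pareto_scale",
    "ParetoScaler",
]


@dataclass
class FilterReport:
    features_in: int
    removed_blank: int
    removed_additive: int
    features_out: int
    qc_cv_percent: pd.Series | None = None

    def __post_init__(self) -> None:
        assert self.features_out == (
            self.features_in - self.removed_blank - self.removed_additive
        )


def _check_samples(block: pd.DataFrame, ids: list[str], what: str) -> None:
    missing = [s for s in ids if s not in block.index]
    if missing:
        raise KeyError(f"unknown {what} sample id(s): {missing}")


def remove_background_features(
    block: pd.DataFrame,
    blank_sample_ids: list[str] | None = None,
    additive_sample_ids: list[str] | None = None,
    detection_threshold: float = 30.0,
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop features detected in blank or pure-additive runs.

    A feature is removed iff its intensity exceeds ``detection_threshold`` in
    at least one of the named samples; a feature detected in both kinds of
    run is counted once, under blank. The default threshold of 30 (three
    times the simulator's noise floor) is arbitrary-intensity-unit config and
    should be set to match the instrument/noise floor at hand. With no blank
    or additive samples supplied this is the identity filter.
    """
    blank_sample_ids = list(blank_sample_ids or [])
    additive_sample_ids = list(additive_sample_ids or [])
    _check_samples(block, blank_sample_ids, "blank")
    _check_samples(block, additive_sample_ids, "additive")
    in_blank = (
        (block.loc[blank_sample_ids] > detection_threshold).any(axis=0)
        if blank_sample_ids else pd.Series(False, index=block.columns)
    )
    in_additive = (
        (block.loc[additive_sample_ids] > detection_threshold).any(axis=0)
        if additive_sample_ids else pd.Series(False, index=block.columns)
    )
    removed_blank = int(in_blank.sum())
    removed_additive = int((in_additive & ~in_blank).sum())
    keep = ~(in_blank | in_additive)
    filtered = block.loc[:, keep]
    report = FilterReport(
        features_in=block.shape[1],
        removed_blank=removed_blank,
        removed_additive=removed_additive,
        features_out=filtered.shape[1],
    )
    return filtered, report


def qc_cv(block: pd.DataFrame, qc_sample_ids: list[str],
          threshold: float = 40.0) -> pd.DataFrame:
    """Per-feature coefficient of variation (%) over pooled QC injections.

    CV = 100 * sd / mean on raw intensities (CV is meaningless after
    centering). Returns a frame with columns ``cv_percent`` and ``pass``
    (CV below ``threshold``, default 40%); the flag is diagnostic -- the
    pipeline reports it but does not filter on it by default.
    """
    if len(qc_sample_ids) < 2:
        raise ValueError("need at least 2 QC samples to compute a CV")
    _check_samples(block, list(qc_sample_ids), "QC")
    qc = block.loc[qc_sample_ids]
    mean = qc.mean(axis=0)
    sd = qc.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = 100.0 * sd / mean
    return pd.DataFrame({"cv_percent": cv, "pass": cv < threshold})


def pareto_scale(X: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Column-wise Pareto scaling: (x - mean) / sqrt(sd), sd with ddof=1."""
    return ParetoScaler().fit_transform(X)


class ParetoScaler(TransformerMixin, BaseEstimator):
    """Pareto scaling as a scikit-learn transformer.

    Each column is mean-centered and divided by the square root of its sample
    standard deviation (ddof=1), the usual compromise for LC-MS intensities
    between no scaling (dominated by intense ions) and unit variance
    (inflates noise). A zero-variance column is an error naming the feature:
    background features must be filtered out first. Fitting on a training
    fold and transforming held-out samples with the stored parameters is the
    leakage-free usage; cross-validation in this package always does so.
    """

    def fit(self, X, y=None):
        X_arr = np.asarray(X, dtype=float)
        if X_arr.ndim != 2:
            raise ValueError("expected a 2D samples x features matrix")
        self.mean_ = X_arr.mean(axis=0)
        sd = X_arr.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            names = (
                list(np.asarray(X.columns)[zero][:5])
                if isinstance(X, pd.DataFrame) else zero[:5].tolist()
            )
            raise ValueError(
                f"zero-variance feature(s) cannot be Pareto scaled: {names}"
                f"{' ...' if zero.size > 5 else ''} (filter first)"
            )
        self.scale_ = np.sqrt(sd)
        self.n_features_in_ = X_arr.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "scale_")
        X_arr = np.asarray(X, dtype=float)
        out = (X_arr - self.mean_) / self.scale_
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out

    def inverse_transform(self, X):
        check_is_fitted(self, "scale_")
        return np.asarray(X, dtype=float) * self.scale_ + self.mean_
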