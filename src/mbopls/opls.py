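"""Kernel OPLS-DA on a consensus kernel, scikit-learn style.

The model splits the fused kernel's variation into one Y-predictive
component and ``n_orthogonal`` Y-orthogonal components,

    X_i = t_p p_p,i^T + T_o P_o,i^T + E_i        Y = t_p q_p^T + F,

where t_p is the predictive score vector, T_o the orthogonal scores, q_p the
Y-loading, and p_p,i / P_o,i the per-block loadings recovered by
back-projection (linear kernels). Training works entirely in the dual: the
predictive score is the kernel image of the centered response, each
orthogonal component is the dominant Y-orthogonal structured direction
(K - t_p t_p^T) t_p, and the kernel is deflated on both sides before the
final predictive component is extracted, which makes t_p orthogonal to every
orthogonal score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .kernels import ConsensusKernel, _weights_from_rv, linear_kernel, rv_coefficient
from sklearn.preprocessing import KernelCenterer

__all__ = ["KoplsFit", "fit_kopls", "predict_kopls", "ConsensusOPLSDA"]

_RANK_TOL = 1e-12


@dataclass
class _Stage:
    """State of one orthogonal-component extraction round."""

    K: np.ndarray          # kernel deflated a times (both sides)
    tp: np.ndarray         # predictive score at this round (weights unit-norm)
    r: float               # sqrt(yc' K yc): predictive weight normaliser
    tpn: float             # tp' tp
    to: np.ndarray         # unit-norm orthogonal score
    s: float               # norm of the unnormalised orthogonal score


@dataclass
class KoplsFit:
    """Fitted kernel-OPLS state (dual representation)."""

    y_mean: float
    yc: np.ndarray
    stages: list[_Stage]
    K_final: np.ndarray
    tp: np.ndarray
    r_final: float
    qp: float
    fitted: np.ndarray

    @property
    def n_orthogonal(self) -> int:
        return len(self.stages)

    @property
    def orthogonal_scores(self) -> np.ndarray:
        if not self.stages:
            return np.empty((len(self.tp), 0))
        return np.column_stack([st.to for st in self.stages])


def _validate_y(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    vals = np.unique(y)
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError("y must be a 0/1 indicator vector")
    if len(vals) < 2:
        raise ValueError("y is constant: degenerate single-class response")
    return y


def fit_kopls(K: np.ndarray | ConsensusKernel, y: np.ndarray,
              n_orthogonal: int = 0) -> KoplsFit:
    """Fit kernel OPLS with one predictive and ``n_orthogonal`` components.

    ``K`` is a centered (consensus) training kernel. Raises if the response
    is constant or if the kernel rank cannot support the requested number of
    orthogonal components.
    """
    if isinstance(K, ConsensusKernel):
        K = K.K
    K = np.asarray(K, dtype=float)
    y = _validate_y(y)
    if K.shape[0] != K.shape[1] or K.shape[0] != len(y):
        raise ValueError("kernel / response dimension mismatch")
    if n_orthogonal < 0:
        raise ValueError("n_orthogonal must be >= 0")
    yc = y - y.mean()
    scale = float(np.trace(K)) or 1.0

    Kd = K
    stages: list[_Stage] = []
    for _ in range(n_orthogonal):
        r2 = float(yc @ Kd @ yc)
        if r2 <= _RANK_TOL * scale:
            raise ValueError(
                f"kernel rank exhausted after {len(stages)} orthogonal "
                "components; n_orthogonal too large"
            )
        r = np.sqrt(r2)
        tp = (Kd @ yc) / r
        tpn = float(tp @ tp)
        to_un = Kd @ tp - tp * tpn
        s = float(np.linalg.norm(to_un))
        if s <= np.sqrt(_RANK_TOL) * scale:
            raise ValueError(
                f"no Y-orthogonal variation left after {len(stages)} "
                "components; n_orthogonal too large"
            )
        to = to_un / s
        stages.append(_Stage(K=Kd, tp=tp, r=r, tpn=tpn, to=to, s=s))
        KP = Kd - np.outer(Kd @ to, to)
        Kd = KP - np.outer(to, to @ KP)

    r2 = float(yc @ Kd @ yc)
    if r2 <= _RANK_TOL * scale:
        raise ValueError("no predictive variation left in the deflated kernel")
    r_final = float(np.sqrt(r2))
    tp = (Kd @ yc) / r_final
    qp = float((yc @ tp) / (tp @ tp))
    fitted = tp * qp + y.mean()
    return KoplsFit(
        y_mean=float(y.mean()), yc=yc, stages=stages, K_final=Kd,
        tp=tp, r_final=r_final, qp=qp, fitted=fitted,
    )


def predict_kopls(fit: KoplsFit, k_rows: np.ndarray) -> np.ndarray:
    """Predict responses for new samples from consensus cross-kernel rows.

    ``k_rows`` (m x n_train) must be built with the training centering,
    block scalings and weights. New samples are deflated by each orthogonal
    component in turn, then projected onto the predictive direction.
    """
    k = np.atleast_2d(np.asarray(k_rows, dtype=float))
    if k.shape[1] != len(fit.yc):
        raise ValueError(
            f"cross-kernel has {k.shape[1]} training columns, expected {len(fit.yc)}"
        )
    for st in fit.stages:
        tp_new = (k @ fit.yc) / st.r
        to_new = (k @ st.tp - tp_new * st.tpn) / st.s
        k = k - np.outer(to_new, st.K @ st.to)
        k = k - np.outer(k @ st.to, st.to)
    tp_new = (k @ fit.yc) / fit.r_final
    return tp_new * fit.qp + fit.y_mean


class ConsensusOPLSDA(BaseEstimator):
    """Consensus OPLS-DA over fused linear block kernels.

    Fits one Y-predictive and ``n_orthogonal`` Y-orthogonal components on the
    weighted sum of block-scaled centered linear kernels. Block weights are
    modified-RV coefficients against the response kernel (``block_weighting=
    "rv"``) or uniform (``"equal"``). ``X`` may be a single samples x
    features matrix or a list of such matrices (one per block) sharing the
    sample order; blocks are expected pre-scaled (e.g. Pareto).

    Attributes (after ``fit``)
    --------------------------
    scores_ : (n,) predictive score vector t_p.
    orthogonal_scores_ : (n, n_orthogonal) orthogonal scores T_o.
    y_loading_ : float, q_p.
    block_weights_ : (n_blocks,) fused-kernel weights lambda_i.
    block_rv_ : raw modified-RV of each block against the response kernel.
    fitted_ : in-sample continuous predictions.
    """

    def __init__(self, n_orthogonal: int = 0, block_weighting: str = "rv"):
        self.n_orthogonal = n_orthogonal
        self.block_weighting = block_weighting

    @staticmethod
    def _as_blocks(X) -> list[np.ndarray]:
        if isinstance(X, (list, tuple)):
            blocks = [np.asarray(b, dtype=float) for b in X]
        else:
            blocks = [np.asarray(X, dtype=float)]
        if any(b.ndim != 2 for b in blocks):
            raise ValueError("each block must be a 2D samples x features matrix")
        if len({b.shape[0] for b in blocks}) != 1:
            raise ValueError("all blocks must share the sample index")
        return blocks

    def fit(self, X, y):
        if self.block_weighting not in ("rv", "equal"):
            raise ValueError("block_weighting must be 'rv' or 'equal'")
        blocks = self._as_blocks(X)
        y = _validate_y(np.asarray(y))
        if blocks[0].shape[0] != len(y):
            raise ValueError("X and y sample counts differ")
        yc = y - y.mean()
        Ky = np.outer(yc, yc)
        self._centerers = []
        self._norms = []
        self._Xtrain = blocks
        scaled = []
        for b in blocks:
            cen = KernelCenterer().fit(linear_kernel(b))
            Kc = cen.transform(linear_kernel(b))
            norm = np.linalg.norm(Kc)
            if norm == 0:
                raise ValueError("a block has an all-zero centered kernel")
            self._centerers.append(cen)
            self._norms.append(norm)
            scaled.append(Kc / norm)
        rvs = np.array([rv_coefficient(K, Ky) for K in scaled])
        if self.block_weighting == "equal" or len(scaled) == 1:
            lam = np.full(len(scaled), 1.0 / len(scaled))
        else:
            lam = _weights_from_rv(rvs)
        K = sum(w * Ki for w, Ki in zip(lam, scaled))
        self._kfit = fit_kopls(K, y, self.n_orthogonal)
        self.block_weights_ = lam
        self.block_rv_ = rvs
        self.scores_ = self._kfit.tp
        self.orthogonal_scores_ = self._kfit.orthogonal_scores
        self.y_loading_ = self._kfit.qp
        self.fitted_ = self._kfit.fitted
        self.n_features_in_ = sum(b.shape[1] for b in blocks)
        return self

    def _cross_kernel(self, X) -> np.ndarray:
        blocks = self._as_blocks(X)
        if len(blocks) != len(self._Xtrain):
            raise ValueError("block count differs from training")
        k = 0.0
        for b, btr, cen, norm, w in zip(
            blocks, self._Xtrain, self._centerers, self._norms,
            self.block_weights_,
        ):
            if b.shape[1] != btr.shape[1]:
                raise ValueError("block feature dimension differs from training")
            k = k + w * cen.transform(b @ btr.T) / norm
        return k

    def predict(self, X) -> np.ndarray:
        """Continuous response estimate for new samples (one row per sample)."""
        if not hasattr(self, "_kfit"):
            raise ValueError("estimator is not fitted")
        return predict_kopls(self._kfit, self._cross_kernel(X))

    def predict_class(self, X) -> np.ndarray:
        """Hard 0/1 assignment at the 0.5 threshold."""
        return (self.predict(X) > 0.5).astype(int)

    def transform(self, X) -> np.ndarray:
        """Predictive then orthogonal score columns for new samples."""
        if not hasattr(self, "_kfit"):
            raise ValueError("estimator is not fitted")
        k = self._cross_kernel(X)
        fit = self._kfit
        cols = []
        for st in fit.stages:
            tp_new = (k @ fit.yc) / st.r
            to_new = (k @ st.tp - tp_new * st.tpn) / st.s
            cols.append(to_new)
            k = k - np.outer(to_new, st.K @ st.to)
            k = k - np.outer(k @ st.to, st.to)
        tp_new = (k @ fit.yc) / fit.r_final
        return np.column_stack([tp_new] + cols)

    def block_loadings(self) -> list[np.ndarray]:
        """Back-projected predictive loadings p_p,i = X_i^T t_p / (t_p^T t_p)."""
        if not hasattr(self, "_kfit"):
            raise ValueError("estimator is not fitted")
        tp = self.scores_
        return [b.T @ tp / (tp @ tp) for b in self._Xtrain]
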