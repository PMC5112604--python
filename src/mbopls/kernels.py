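"""Linear kernels, block scaling and RV-based block weighting.

Each analytical block X_i enters the consensus model through its linear
kernel K_i = X_i X_i^T (samples x samples), double-centered and scaled to
unit Frobenius norm so every block gets an equal starting chance to
contribute. Block weights are modified RV coefficients (kernel diagonals
zeroed, Smilde's RV2) between each scaled kernel and the response kernel
y_c y_c^T, clipped at zero and normalised to sum to one, so the response
orientates the consensus kernel toward predictability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.preprocessing import KernelCenterer

__all__ = [
    "linear_kernel",
    "center_kernel",
    "block_scale",
    "rv_coefficient",
    "consensus_kernel",
    "ConsensusKernel",
]


def linear_kernel(X: np.ndarray) -> np.ndarray:
    """K = X X^T, the inter-sample association matrix of one block."""
    X = np.asarray(X, dtype=float)
    return X @ X.T


def center_kernel(K: np.ndarray) -> np.ndarray:
    """Double-center a training kernel (feature-space column centering)."""
    return KernelCenterer().fit_transform(np.asarray(K, dtype=float))


def block_scale(K: np.ndarray) -> np.ndarray:
    """Scale a kernel to unit Frobenius norm."""
    K = np.asarray(K, dtype=float)
    norm = np.linalg.norm(K)
    if norm == 0:
        raise ValueError("cannot block-scale an all-zero kernel")
    return K / norm


def rv_coefficient(K_a: np.ndarray, K_b: np.ndarray) -> float:
    """Modified RV coefficient between two sample association matrices.

    Both kernels have their diagonals set to zero before the normalised
    Frobenius inner product, removing the sample-size bias of the classic RV.
    Result lies in [-1, 1]; 1 for identical (off-diagonal) association
    structure.
    """
    A = np.asarray(K_a, dtype=float).copy()
    B = np.asarray(K_b, dtype=float).copy()
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ValueError("kernels must be square and of equal size")
    np.fill_diagonal(A, 0.0)
    np.fill_diagonal(B, 0.0)
    na, nb = np.linalg.norm(A), np.linalg.norm(B)
    if na == 0 or nb == 0:
        raise ValueError("RV undefined for a kernel with zero off-diagonal")
    return float(np.sum(A * B) / (na * nb))


@dataclass
class ConsensusKernel:
    """A response-weighted sum of block-scaled centered linear kernels."""

    K: np.ndarray
    block_kernels: list[np.ndarray]  # centered + unit-Frobenius, per block
    weights: np.ndarray              # lambda_i >= 0, sum to 1
    rv: np.ndarray                   # raw modified-RV against the Y kernel


def _weights_from_rv(rvs: np.ndarray) -> np.ndarray:
    lam = np.clip(rvs, 0.0, None)
    total = lam.sum()
    if total <= 0:
        warnings.warn(
            "all block RV coefficients non-positive; falling back to equal "
            "block weights", RuntimeWarning, stacklevel=3,
        )
        return np.full(len(rvs), 1.0 / len(rvs))
    return lam / total


def consensus_kernel(blocks: list[np.ndarray], y: np.ndarray) -> ConsensusKernel:
    """Fuse block kernels with RV weights against the response kernel.

    Blocks must share the sample index (same row order). The response kernel
    is y_c y_c^T with y_c the centered 0/1 indicator.
    """
    if not blocks:
        raise ValueError("need at least one block")
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if any(np.asarray(b).shape[0] != n for b in blocks):
        raise ValueError("all blocks must share the sample index")
    yc = y - y.mean()
    Ky = np.outer(yc, yc)
    scaled = [block_scale(center_kernel(linear_kernel(b))) for b in blocks]
    rvs = np.array([rv_coefficient(K, Ky) for K in scaled])
    lam = _weights_from_rv(rvs)
    K = sum(w * Ki for w, Ki in zip(lam, scaled))
    return ConsensusKernel(K=K, block_kernels=scaled, weights=lam, rv=rvs)
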