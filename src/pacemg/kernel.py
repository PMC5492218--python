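"""RBF kernel, kernel matrices, and the induced feature-space metric.

All classifiers in this package operate in the reproducing-kernel Hilbert
space of the Gaussian (RBF) kernel

    k(x_i, x_j) = exp(-gamma * ||x_i - x_j||^2),

evaluated on the native 7-channel feature vectors (normalized RMS
amplitudes); no additional scaling is applied inside the kernel.  The
kernel induces a proper metric on feature space,

    d(x_i, x_j) = ||phi(x_i) - phi(x_j)|| = sqrt(2 - 2 k(x_i, x_j)),

bounded by sqrt(2), which drives both the k-medoids initialization and
the attractive-zone replacement test of the particle adaptive classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


@dataclass(frozen=True)
class KernelParams:
    """Gaussian kernel width parameter.

    Attributes
    ----------
    gamma : float
        RBF width; must be strictly positive.  Larger values make the
        kernel more local (distances saturate faster toward sqrt(2)).
    """

    gamma: float

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")


def _check_pair(x_i: np.ndarray, x_j: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if x_i.shape != x_j.shape:
        raise ValueError(f"dimension mismatch: {x_i.shape} vs {x_j.shape}")
    return x_i, x_j


def rbf_kernel(x_i: np.ndarray, x_j: np.ndarray, params: KernelParams) -> float:
    """Gaussian kernel similarity in (0, 1]; equals 1 iff the inputs coincide."""
    x_i, x_j = _check_pair(x_i, x_j)
    diff = x_i - x_j
    return float(np.exp(-params.gamma * diff.dot(diff)))


def kernel_vector(x: np.ndarray, samples: np.ndarray, params: KernelParams) -> np.ndarray:
    """k(x, s) for every row s of ``samples`` (the hot path of prediction)."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    x = np.asarray(x, dtype=float).reshape(1, -1)
    if samples.shape[1] != x.shape[1]:
        raise ValueError("dimension mismatch between x and samples")
    sq = cdist(x, samples, "sqeuclidean")[0]
    return np.exp(-params.gamma * sq)


def kernel_matrix(samples: np.ndarray, params: KernelParams) -> np.ndarray:
    """Symmetric PSD Gram matrix with unit diagonal for a set of samples."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] == 0:
        raise ValueError("kernel_matrix requires a nonempty sample list")
    sq = cdist(samples, samples, "sqeuclidean")
    K = np.exp(-params.gamma * sq)
    # enforce exact symmetry / unit diagonal against rounding in cdist
    K = 0.5 * (K + K.T)
    np.fill_diagonal(K, 1.0)
    return K


def kernel_distance(x_i: np.ndarray, x_j: np.ndarray, params: KernelParams) -> float:
    """Feature-space metric sqrt(2 - 2 k(x_i, x_j)); range [0, sqrt(2))."""
    k = rbf_kernel(x_i, x_j, params)
    return float(np.sqrt(max(2.0 - 2.0 * k, 0.0)))


def kernel_distance_from_similarity(k: np.ndarray) -> np.ndarray:
    """Map kernel similarities to feature-space distances, elementwise.

    Reuses kernel products already computed for prediction, so the
    attractive-zone test adds no extra kernel evaluations.
    """
    return np.sqrt(np.maximum(2.0 - 2.0 * np.asarray(k), 0.0))


def distance_matrix(samples: np.ndarray, params: KernelParams) -> np.ndarray:
    """Pairwise feature-space distances (used by k-medoids clustering)."""
    return kernel_distance_from_similarity(kernel_matrix(samples, params))
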