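"""Random Fourier features for the Gaussian kernel.

By Bochner's theorem a shift-invariant positive-definite kernel is the
Fourier transform of a probability measure, so the kernel can be estimated
by Monte-Carlo over frequencies drawn from that measure. For the Gaussian
kernel

    k(x, y) = exp(-||x - y||^2 / (2 sigma^2))

the frequency law is a spherical Gaussian with per-coordinate standard
deviation 1/sigma. The map used here places both cos and sin features for
each sampled frequency and normalizes by 1/sqrt(D) (instead of the classic
cos-only map with sqrt(2/D)), so that every mapped row has unit Euclidean
norm and Z Z^T has an exactly unit diagonal:

    z(x) = D^{-1/2} [cos(delta_j.x + b_j), ..., sin(delta_j.x + b_j), ...]

Each cos^2 + sin^2 pair contributes exactly 1/D to the squared row norm.
The phase offsets b_j are retained even though they cancel identically in
the cos/sin pairing of z(x)^T z(y).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist

__all__ = ["RFFMap", "estimate_sigma", "sample_map", "transform",
           "exact_gaussian_kernel"]


@dataclass(frozen=True)
class RFFMap:
    """A frozen random Fourier map for one feature set.

    Attributes
    ----------
    sigma : float
        Gaussian kernel width, in input-space distance units.
    Delta : ndarray of shape (input_dim, D)
        Frequency matrix; column j is the sampled frequency delta_j.
    offsets : ndarray of shape (D,)
        Phase offsets b_j in [0, 2*pi).
    """

    sigma: float
    Delta: np.ndarray
    offsets: np.ndarray

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.Delta.ndim != 2:
            raise ValueError("Delta must be 2-D (input_dim x D)")
        if self.offsets.shape != (self.Delta.shape[1],):
            raise ValueError("offsets must have one entry per frequency")
        if np.any(self.offsets < 0) or np.any(self.offsets >= 2 * np.pi):
            raise ValueError("offsets must lie in [0, 2*pi)")

    @property
    def D(self) -> int:
        """Number of random Fourier samples (output width is 2*D)."""
        return self.Delta.shape[1]

    @property
    def input_dim(self) -> int:
        return self.Delta.shape[0]


def estimate_sigma(X, S: int | None = None, rng=None) -> float:
    """Bandwidth heuristic: mean pairwise distance over a random row subset.

    Draws ``S`` rows of ``X`` without replacement (default ``min(N, 1000)``)
    and returns the mean Euclidean distance over the S(S-1)/2 distinct
    unordered pairs — the zero diagonal is excluded and no pair is counted
    twice.

    Raises
    ------
    ValueError
        If N < 2, S is out of [2, N], or all sampled rows coincide
        ("degenerate bandwidth").
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows to estimate a bandwidth")
    if S is None:
        S = min(n, 1000)
    if not 2 <= S <= n:
        raise ValueError(f"subset size S={S} must be in [2, {n}]")
    rng = np.random.default_rng(rng)
    rows = X[rng.choice(n, size=S, replace=False)] if S < n else X
    sigma = float(pdist(rows).mean())
    if sigma <= 0.0:
        raise ValueError("degenerate bandwidth: sampled rows are identical")
    return sigma


def sample_map(input_dim: int, D: int, sigma: float, rng=None) -> RFFMap:
    """Draw a random Fourier map for a Gaussian kernel of width ``sigma``.

    Frequencies are i.i.d. N(0, 1/sigma^2) per coordinate (the Gaussian
    kernel's Fourier transform); offsets are i.i.d. uniform on [0, 2*pi).
    """
    if D < 1:
        raise ValueError("D must be a positive integer")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(rng)
    Delta = rng.normal(0.0, 1.0 / sigma, size=(input_dim, D))
    offsets = rng.uniform(0.0, 2.0 * np.pi, size=D)
    # uniform() may return the high endpoint through rounding; fold it back
    offsets = np.mod(offsets, 2.0 * np.pi)
    return RFFMap(sigma=float(sigma), Delta=Delta, offsets=offsets)


def transform(X, rff_map: RFFMap) -> np.ndarray:
    """Apply a frozen map: Z = D^{-1/2} [cos(X Delta + b), sin(X Delta + b)].

    Returns an (N, 2D) matrix whose rows all have unit Euclidean norm.
    Deterministic given the map: all randomness lives in map sampling.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != rff_map.input_dim:
        raise ValueError(
            f"X has {X.shape[1] if X.ndim == 2 else '?'} columns, "
            f"map expects {rff_map.input_dim}"
        )
    A = X @ rff_map.Delta + rff_map.offsets
    scale = 1.0 / np.sqrt(rff_map.D)
    return np.hstack([np.cos(A), np.sin(A)]) * scale


def exact_gaussian_kernel(X, Y, sigma: float) -> np.ndarray:
    """Exact Gaussian kernel matrix exp(-||x - y||^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must have matching column counts")
    sq = cdist(X, Y, metric="sqeuclidean")
    return np.exp(-sq / (2.0 * sigma**2))
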