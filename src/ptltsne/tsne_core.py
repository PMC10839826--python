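"""t-SNE building blocks: Gaussian and Student-t affinities and the KL loss.

High-dimensional proximities use per-point Gaussian kernels whose bandwidths
``sigma_i`` are calibrated so that the conditional neighbor distribution of
every point has a prescribed perplexity ``2^H``.  Low-dimensional proximities
use the heavy-tailed Student-t kernel ``(1 + d^2)^-1``.  The embedding
objective is the Kullback-Leibler divergence ``sum_ij p_ij log(p_ij/q_ij)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: floor applied inside logarithms only
EPS = 1e-12


class DegenerateRowError(ValueError):
    """A point has no usable neighbors (all-infinite or all-identical)."""


@dataclass
class AffinityMatrix:
    """Joint high-dimensional probabilities ``P`` with calibrated bandwidths."""

    P: np.ndarray
    sigmas: np.ndarray
    perplexity: float


@dataclass
class EmbeddingAffinity:
    """Joint low-dimensional Student-t probabilities ``Q``."""

    Q: np.ndarray


def squared_distances(Z: np.ndarray) -> np.ndarray:
    """Symmetric matrix of squared Euclidean distances with exact zero diagonal."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    sq = np.sum(Z**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (Z @ Z.T)
    np.maximum(d2, 0.0, out=d2)
    np.fill_diagonal(d2, 0.0)
    return d2


def conditional_affinities(sq_dists: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    """Row-normalized Gaussian conditionals ``p_{j|i}``.

    Row i is ``exp(-d2_ij / (2 sigma_i^2))`` over ``j != i`` normalized to
    sum 1; the diagonal is zero.  A row of all-zero distances yields uniform
    conditionals (duplicate points are legal).
    """
    d2 = np.asarray(sq_dists, dtype=float)
    n = d2.shape[0]
    sig = np.broadcast_to(np.asarray(sigmas, dtype=float), (n,))
    if np.any(sig <= 0):
        raise ValueError("sigmas must be positive")
    # subtract the row-min over off-diagonal entries for stability
    off = d2 + np.where(np.eye(n, dtype=bool), np.inf, 0.0)
    if np.any(~np.isfinite(off.min(axis=1))):
        raise DegenerateRowError("a row has no finite off-diagonal distance")
    shifted = d2 - off.min(axis=1)[:, None]
    W = np.exp(-shifted / (2.0 * sig[:, None] ** 2))
    np.fill_diagonal(W, 0.0)
    rows = W.sum(axis=1)
    if np.any(rows <= 0):
        raise DegenerateRowError("a row has zero total affinity")
    return W / rows[:, None]


def _row_perplexity(sq_row: np.ndarray, sigma: float) -> float:
    """Perplexity ``2^H`` (H in bits) of one conditional distribution."""
    x = -np.asarray(sq_row, dtype=float) / (2.0 * sigma**2)
    x = x - x.max()
    w = np.exp(x)
    p = w / w.sum()
    h = -np.sum(p * np.log2(np.maximum(p, EPS)))
    return float(2.0**h)


def calibrate_sigma(
    sq_dist_row: np.ndarray,
    target_perplexity: float,
    tol: float = 1e-5,
    max_iter: int = 100,
) -> tuple[float, bool]:
    """Binary search on log(sigma) to hit the target perplexity.

    Returns ``(sigma, converged)``.  The bracket is expanded by factors of 2
    until the target is straddled.  Perplexity is non-decreasing in sigma, so
    bisection is safe.  Equidistant rows are sigma-independent and return
    immediately.
    """
    row = np.asarray(sq_dist_row, dtype=float)
    if target_perplexity <= 1.0:
        raise ValueError("target perplexity must exceed 1")
    if row.ndim != 1 or row.size < 1:
        raise ValueError("need a 1-D row of squared distances to neighbors")
    sigma = 1.0
    perp = _row_perplexity(row, sigma)
    if abs(perp - target_perplexity) <= tol:
        return sigma, True
    lo, hi = sigma, sigma
    # expand bracket
    for _ in range(64):
        if perp < target_perplexity:
            hi *= 2.0
            perp = _row_perplexity(row, hi)
            if perp >= target_perplexity:
                lo = hi / 2.0
                break
        else:
            lo /= 2.0
            perp = _row_perplexity(row, lo)
            if perp <= target_perplexity:
                hi = lo * 2.0
                break
    else:
        # entropy saturated (e.g. equidistant row): any sigma is as good
        return sigma, abs(_row_perplexity(row, sigma) - target_perplexity) <= tol
    best = sigma
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)
        perp = _row_perplexity(row, mid)
        best = mid
        if abs(perp - target_perplexity) <= tol:
            return mid, True
        if perp < target_perplexity:
            lo = mid
        else:
            hi = mid
    return best, False


def calibrate_sigmas(
    sq_dists: np.ndarray, perplexity: float, tol: float = 1e-5, max_iter: int = 100
) -> np.ndarray:
    """Vectorized bandwidth calibration for every row of a distance matrix.

    Bisection on log(sigma) over all rows simultaneously; same monotone
    search as :func:`calibrate_sigma`, row-for-row.
    """
    d2 = np.asarray(sq_dists, dtype=float)
    n = d2.shape[0]
    eye = np.eye(n, dtype=bool)
    off = np.where(eye, np.inf, d2)
    shift = off.min(axis=1, keepdims=True)
    if np.any(~np.isfinite(shift)):
        raise DegenerateRowError("a row has no finite off-diagonal distance")
    dd = d2 - shift
    dd[eye] = 0.0  # excluded below; keeps exp from overflowing at tiny sigma

    def perp(sig: np.ndarray) -> np.ndarray:
        W = np.exp(-dd / (2.0 * sig[:, None] ** 2))
        W[eye] = 0.0
        P = W / W.sum(axis=1, keepdims=True)
        H = -np.sum(np.where(P > 0, P * np.log2(np.maximum(P, EPS)), 0.0), axis=1)
        return 2.0**H

    sig = np.ones(n)
    p = perp(sig)
    active = np.abs(p - perplexity) > tol
    lo = np.ones(n)
    hi = np.ones(n)
    # expand per-row brackets by factors of 2 until the target is straddled
    grow = active & (p < perplexity)
    shrink = active & (p > perplexity)
    for _ in range(64):
        if not (grow.any() or shrink.any()):
            break
        hi[grow] *= 2.0
        lo[shrink] /= 2.0
        probe = np.where(grow, hi, np.where(shrink, lo, sig))
        pp = perp(probe)
        newly_hi = grow & (pp >= perplexity)
        newly_lo = shrink & (pp <= perplexity)
        lo[newly_hi] = hi[newly_hi] / 2.0
        hi[newly_lo] = lo[newly_lo] * 2.0
        grow &= ~newly_hi
        shrink &= ~newly_lo
    # saturated rows (entropy independent of sigma) keep their current value
    active &= ~(grow | shrink)
    for _ in range(max_iter):
        if not active.any():
            break
        mid = np.sqrt(lo * hi)
        sig = np.where(active, mid, sig)
        p = perp(sig)
        conv = np.abs(p - perplexity) <= tol
        low = p < perplexity
        lo = np.where(active & low, mid, lo)
        hi = np.where(active & ~low, mid, hi)
        active &= ~conv
    return sig


def joint_affinities(
    Z: np.ndarray, perplexity: float, sq_dists: np.ndarray | None = None
) -> AffinityMatrix:
    """Symmetrized joint probabilities ``p_ij = (p_{j|i} + p_{i|j}) / (2N)``."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    n = Z.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    eff_perp = min(perplexity, n - 1.0)
    d2 = squared_distances(Z) if sq_dists is None else np.asarray(sq_dists, float)
    if d2.max() == 0.0:
        raise DegenerateRowError("all points identical: affinities undefined")
    sig = calibrate_sigmas(d2, eff_perp)
    cond = conditional_affinities(d2, sig)
    P = (cond + cond.T) / (2.0 * n)
    return AffinityMatrix(P=P, sigmas=sig, perplexity=eff_perp)


def student_t_affinities(S: np.ndarray) -> EmbeddingAffinity:
    """Joint Student-t probabilities ``q_ij`` over all ordered pairs i != j."""
    S = np.atleast_2d(np.asarray(S, dtype=float))
    if S.shape[0] < 2:
        raise ValueError("need at least 2 embedded points")
    d2 = squared_distances(S)
    K = 1.0 / (1.0 + d2)
    np.fill_diagonal(K, 0.0)
    return EmbeddingAffinity(Q=K / K.sum())


def kl_gradient(P: np.ndarray, S: np.ndarray) -> tuple[float, np.ndarray]:
    """KL loss and its analytic gradient with respect to the embedding.

    ``dC/ds_i = 4 sum_j (p_ij - q_ij) (1 + |s_i - s_j|^2)^-1 (s_i - s_j)``.
    """
    P = P.P if isinstance(P, AffinityMatrix) else np.asarray(P, dtype=float)
    S = np.atleast_2d(np.asarray(S, dtype=float))
    d2 = squared_distances(S)
    K = 1.0 / (1.0 + d2)
    np.fill_diagonal(K, 0.0)
    Q = K / K.sum()
    loss = kl_loss(P, Q)
    W = (P - Q) * K
    dS = 4.0 * (W.sum(axis=1)[:, None] * S - W @ S)
    return loss, dS


def direct_embed(
    P: AffinityMatrix | np.ndarray,
    n_dims: int = 2,
    n_iter: int = 600,
    learning_rate: float = 0.3,
    seed: int = 0,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Classical (non-parametric) t-SNE: optimize the embedding directly.

    Adam on the KL objective from a small random (or supplied)
    initialization.  Serves as the reference embedding the parametric
    network is compared against.
    """
    Pm = P.P if isinstance(P, AffinityMatrix) else np.asarray(P, dtype=float)
    n = Pm.shape[0]
    rng = np.random.default_rng(seed)
    S = rng.normal(0.0, 1e-2, size=(n, n_dims)) if init is None else init.copy()
    m = np.zeros_like(S)
    v = np.zeros_like(S)
    b1, b2, eps = 0.9, 0.999, 1e-8
    for t in range(1, n_iter + 1):
        _, g = kl_gradient(Pm, S)
        m = b1 * m + (1 - b1) * g
        v = b2 * v + (1 - b2) * g * g
        S = S - learning_rate * (m / (1 - b1**t)) / (np.sqrt(v / (1 - b2**t)) + eps)
    return S


def kl_loss(
    P: AffinityMatrix | np.ndarray,
    Q: EmbeddingAffinity | np.ndarray,
    eps: float = EPS,
) -> float:
    """``sum_{i != j} p_ij log(p_ij / q_ij)`` with ``0 log 0 = 0``."""
    p = P.P if isinstance(P, AffinityMatrix) else np.asarray(P, dtype=float)
    q = Q.Q if isinstance(Q, EmbeddingAffinity) else np.asarray(Q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("P and Q shapes differ")
    mask = p > 0
    return float(
        np.sum(p[mask] * (np.log(np.maximum(p[mask], eps)) - np.log(np.maximum(q[mask], eps))))
    )
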