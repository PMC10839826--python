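"""Embedding-quality metrics: pairwise RMSD, common-neighbor preservation,
and recovery of the planted slow mode."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_data import SyntheticGroundTruth
from .trajectory_io import Trajectory, optimal_rotation


@dataclass
class NeighborScore:
    """Per-frame counts of common top-k neighbors plus their mean."""

    counts: np.ndarray
    mean: float
    k: int


def rmsd_matrix(traj: Trajectory, cap: int = 2000, force: bool = False) -> np.ndarray:
    """Pairwise minimized RMSD over rigid superposition (nm).

    Quadratic in the number of frames; refuses above ``cap`` frames unless
    ``force`` is set.
    """
    n = traj.n_frames
    if n > cap and not force:
        raise ValueError(
            f"{n} frames exceed the pairwise cap {cap}; pass force=True to override"
        )
    frames = traj.as_atoms()
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            R, pc, qc = optimal_rotation(frames[j], frames[i])
            fitted = (frames[j] - pc) @ R + qc
            val = np.sqrt(np.mean(np.sum((fitted - frames[i]) ** 2, axis=1)))
            out[i, j] = out[j, i] = val
    return out


def _topk(dist_row: np.ndarray, i: int, k: int) -> np.ndarray:
    """Indices of the k nearest neighbors of point i, self excluded,
    ties broken by frame index (stable sort)."""
    order = np.argsort(dist_row, kind="stable")
    order = order[order != i]
    return order[:k]


def neighbor_preservation(
    high_d: np.ndarray, low_d: np.ndarray, k: int = 20
) -> NeighborScore:
    """Common top-k neighbors between high-dimensional distances and the
    Euclidean geometry of a low-dimensional embedding."""
    high_d = np.asarray(high_d, dtype=float)
    low_d = np.atleast_2d(np.asarray(low_d, dtype=float))
    n = high_d.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of frames {n}")
    if low_d.shape[0] != n:
        raise ValueError("embedding frame count mismatch")
    diff = low_d[:, None, :] - low_d[None, :, :]
    low_dist = np.sqrt(np.sum(diff**2, axis=-1))
    counts = np.empty(n, dtype=int)
    for i in range(n):
        hi = set(_topk(high_d[i], i, k).tolist())
        lo = set(_topk(low_dist[i], i, k).tolist())
        counts[i] = len(hi & lo)
    return NeighborScore(counts=counts, mean=float(counts.mean()), k=k)


def _best_threshold_accuracy(values: np.ndarray, labels: np.ndarray) -> float:
    """Best 1-D threshold classification accuracy (either polarity)."""
    order = np.argsort(values, kind="stable")
    y = labels[order]
    n = len(y)
    ones_left = np.concatenate([[0], np.cumsum(y)])
    total_ones = ones_left[-1]
    # threshold after position i: left = predicted 0, right = predicted 1
    correct = (np.arange(n + 1) - ones_left) + (total_ones - ones_left)
    acc = np.maximum(correct, n - correct) / n
    return float(acc.max())


def slow_mode_recovery(
    embedding: np.ndarray, truth: SyntheticGroundTruth
) -> tuple[float, float]:
    """How well the 2-D CVs recover the planted slow coordinate.

    Returns ``(|r|, accuracy)``: the maximum absolute Pearson correlation
    with ``z`` over the two CV axes and their PCA rotation, and the best
    1-D-threshold accuracy for the planted state labels over the same axes.
    A constant embedding scores (0.0, 0.5).
    """
    emb = np.atleast_2d(np.asarray(embedding, dtype=float))
    z = truth.slow_series
    labels = truth.state_labels
    if emb.shape[0] != len(z):
        raise ValueError("embedding frame count mismatch")
    axes = [emb[:, d] for d in range(emb.shape[1])]
    centered = emb - emb.mean(axis=0)
    cov = centered.T @ centered / emb.shape[0]
    if np.linalg.norm(cov) > 0:
        _, vecs = np.linalg.eigh(cov)
        for d in range(vecs.shape[1]):
            axes.append(centered @ vecs[:, d])
    best_r, best_acc = 0.0, 0.5
    for a in axes:
        sd = a.std()
        if sd <= 0 or not np.isfinite(sd):
            continue
        r = abs(float(np.corrcoef(a, z)[0, 1]))
        best_r = max(best_r, r)
        best_acc = max(best_acc, _best_threshold_accuracy(a, labels))
    return best_r, best_acc
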