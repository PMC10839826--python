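"""Trajectory input/output, rigid-body superposition and 0-1 coordinate scaling.

Coordinates are stored as flat ``N x M`` matrices (``M = 3 * n_atoms``, nm).
Molecular formats (multi-model PDB, GRO/PDB topology + XTC/DCD) are read
through :mod:`mdtraj`; plain numeric frame matrices come from CSV/TSV files
with one row per frame.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Unreadable or inconsistent trajectory file."""


class DimensionError(ValueError):
    """Atom-count or coordinate-dimension mismatch."""


class DegenerateFitError(ValueError):
    """Superposition or scaling problem is ill-conditioned."""


@dataclass
class Trajectory:
    """``N x M`` Cartesian coordinates (nm) with optional times and labels.

    Invariants: ``N >= 2``, ``M`` divisible by 3 for molecular data, all
    coordinates finite.
    """

    coords: np.ndarray
    times: np.ndarray | None = None
    atom_labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise DimensionError("coords must be a 2-D (N x M) array")
        if self.coords.shape[0] < 2:
            raise DimensionError("a trajectory needs at least 2 frames")
        if not np.all(np.isfinite(self.coords)):
            raise FormatError("non-finite coordinate encountered")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_dim(self) -> int:
        return self.coords.shape[1]

    @property
    def n_atoms(self) -> int:
        if self.coords.shape[1] % 3:
            raise DimensionError("M is not divisible by 3; no atom structure")
        return self.coords.shape[1] // 3

    def as_atoms(self) -> np.ndarray:
        """View coordinates as ``(N, A, 3)``."""
        return self.coords.reshape(self.n_frames, self.n_atoms, 3)


@dataclass
class ReferenceStructure:
    """A single reference frame (``1 x M``, nm) for superposition."""

    coords: np.ndarray
    atom_labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1)
        if not np.all(np.isfinite(self.coords)):
            raise FormatError("non-finite coordinate in reference structure")

    @property
    def n_dim(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        if self.coords.shape[0] % 3:
            raise DimensionError("M is not divisible by 3")
        return self.coords.shape[0] // 3

    def as_atoms(self) -> np.ndarray:
        return self.coords.reshape(self.n_atoms, 3)


@dataclass
class ScaledCoordinates:
    """Affine record of the global 0-1 mapping: ``X = centered * scale + offset``.

    ``centered`` are superposed coordinates minus the reference; the single
    global ``offset``/``scale`` pair applies to every entry so the map can be
    inverted exactly and re-used for out-of-sample frames.
    """

    X: np.ndarray
    offset: float
    scale: float
    ref: ReferenceStructure = field(repr=False)
    per_coordinate: bool = False
    col_offset: np.ndarray | None = None
    col_scale: np.ndarray | None = None

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Apply the stored affine map to already-superposed coordinates."""
        centered = np.atleast_2d(coords) - self.ref.coords
        if self.per_coordinate:
            return centered * self.col_scale + self.col_offset
        return centered * self.scale + self.offset

    def inverse(self, X: np.ndarray | None = None) -> np.ndarray:
        """Recover superposed coordinates from scaled values."""
        X = self.X if X is None else np.asarray(X, dtype=float)
        if self.per_coordinate:
            centered = (X - self.col_offset) / self.col_scale
        else:
            centered = (X - self.offset) / self.scale
        return centered + self.ref.coords


def _traj_from_mdtraj(t) -> Trajectory:
    import mdtraj  # noqa: F401  (delayed import)

    coords = t.xyz.reshape(t.n_frames, -1).astype(float)  # mdtraj is nm
    labels = [str(a) for a in t.topology.atoms] if t.topology is not None else None
    times = np.asarray(t.time, dtype=float) / 1000.0 if t.time is not None else None
    return Trajectory(coords=coords, times=times, atom_labels=labels)


def read_trajectory(path: str, topology: str | None = None) -> Trajectory:
    """Read a trajectory from PDB/GRO/XTC/DCD (via mdtraj) or CSV/TSV.

    CSV/TSV files hold one frame per row; a non-numeric first row is treated
    as a header. Molecular formats are returned in nm (mdtraj convention).
    """
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    ext = os.path.splitext(path)[1].lower()
    if ext in (".csv", ".tsv", ".txt"):
        sep = "," if ext == ".csv" else r"\s+"
        try:
            df = pd.read_csv(path, sep=sep, header=None)
        except Exception as exc:  # pragma: no cover - pandas error paths
            raise FormatError(f"cannot parse {path}: {exc}") from exc
        if df.iloc[0].apply(lambda v: isinstance(v, str)).any():
            df = df.iloc[1:].reset_index(drop=True)
        try:
            coords = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric record in {path}: {exc}") from exc
        return Trajectory(coords=coords)
    import mdtraj

    try:
        if topology is not None:
            t = mdtraj.load(path, top=topology)
        else:
            t = mdtraj.load(path)
    except Exception as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    return _traj_from_mdtraj(t)


def read_reference(path: str, topology: str | None = None) -> ReferenceStructure:
    """Read a single-frame reference structure (first frame if several)."""
    try:
        traj = read_trajectory(path, topology)
    except (FormatError, DimensionError):
        # single-frame CSV fails the N >= 2 invariant; retry as raw vector
        ext = os.path.splitext(path)[1].lower()
        if ext in (".csv", ".tsv", ".txt"):
            sep = "," if ext == ".csv" else r"\s+"
            arr = pd.read_csv(path, sep=sep, header=None).to_numpy(dtype=float)
            return ReferenceStructure(coords=arr.reshape(-1))
        raise
    return ReferenceStructure(coords=traj.coords[0], atom_labels=traj.atom_labels)


def write_scaled_csv(path: str, scaled: ScaledCoordinates) -> None:
    header = f"# offset={scaled.offset!r} scale={scaled.scale!r}"
    np.savetxt(path, scaled.X, delimiter=",", header=header)


def optimal_rotation(
    frame: np.ndarray, ref: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Kabsch optimal proper rotation of ``frame`` (A x 3) onto ``ref`` (A x 3).

    Returns ``(R, frame_centroid, ref_centroid)`` with the convention that
    the superposed frame is ``(frame - frame_centroid) @ R + ref_centroid``
    and ``det(R) = +1``.
    """
    frame = np.asarray(frame, dtype=float)
    ref = np.asarray(ref, dtype=float)
    n = frame.shape[0]
    if n < 3:
        raise DegenerateFitError("need at least 3 atoms for a rigid fit")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
    pc = w @ frame
    qc = w @ ref
    P = frame - pc
    Q = ref - qc
    # collinearity check on the reference
    if np.linalg.matrix_rank(Q - Q.mean(axis=0), tol=1e-10) < 2:
        raise DegenerateFitError("reference atoms are collinear or coincident")
    H = (P * w[:, None]).T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    return R, pc, qc


def kabsch_superpose(
    traj: Trajectory,
    ref: ReferenceStructure,
    weights: np.ndarray | None = None,
) -> Trajectory:
    """Superpose every frame onto the reference (weighted least-squares fit)."""
    if traj.n_dim != ref.n_dim:
        raise DimensionError(
            f"trajectory M={traj.n_dim} does not match reference M={ref.n_dim}"
        )
    frames = traj.as_atoms()
    refa = ref.as_atoms()
    out = np.empty_like(frames)
    for i, fr in enumerate(frames):
        R, pc, qc = optimal_rotation(fr, refa, weights)
        out[i] = (fr - pc) @ R + qc
    return Trajectory(
        coords=out.reshape(traj.n_frames, -1),
        times=traj.times,
        atom_labels=traj.atom_labels,
    )


def rmsd(frame: np.ndarray, ref: np.ndarray) -> float:
    """Plain (already superposed) RMSD between two flat coordinate vectors."""
    frame = np.asarray(frame, dtype=float).reshape(-1, 3)
    ref = np.asarray(ref, dtype=float).reshape(-1, 3)
    return float(np.sqrt(np.mean(np.sum((frame - ref) ** 2, axis=1))))


def center_scale(
    traj: Trajectory, ref: ReferenceStructure, per_coordinate: bool = False
) -> ScaledCoordinates:
    """Center on the reference and map all entries into [0, 1].

    The default is one global affine map (single offset and positive scale
    over all entries) so relative geometry is preserved isotropically; the
    per-coordinate min-max mode exists only for reproduction studies.
    """
    if traj.n_dim != ref.n_dim:
        raise DimensionError("trajectory/reference dimension mismatch")
    centered = traj.coords - ref.coords
    if per_coordinate:
        lo = centered.min(axis=0)
        hi = centered.max(axis=0)
        rng = hi - lo
        if np.any(rng <= 0):
            raise DegenerateFitError("zero dynamic range in some coordinate")
        col_scale = 1.0 / rng
        col_offset = -lo / rng
        X = centered * col_scale + col_offset
        return ScaledCoordinates(
            X=X,
            offset=0.0,
            scale=1.0,
            ref=ref,
            per_coordinate=True,
            col_offset=col_offset,
            col_scale=col_scale,
        )
    lo = float(centered.min())
    hi = float(centered.max())
    if hi <= lo:
        raise DegenerateFitError("zero dynamic range: all frames equal the reference")
    scale = 1.0 / (hi - lo)
    offset = -lo * scale
    X = centered * scale + offset
    return ScaledCoordinates(X=X, offset=offset, scale=scale, ref=ref)
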