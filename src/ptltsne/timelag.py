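"""Time-lag expansion of scaled coordinates (AMUSE-style).

The pipeline whitens the scaled coordinates (projection on covariance
eigenvectors divided by the roots of the eigenvalues), estimates the
covariance between the series and its copy shifted by ``lag`` frames,
symmetrizes it as ``C_sym = (C + C^T) / 2``, and expands the eigenvectors of
``C_sym`` by the square roots of the eigenvalue magnitudes.  Projecting the
trajectory on these expanded eigenvectors stretches slowly decorrelating
directions (|autocorrelation| near 1) and shrinks fast ones, so a subsequent
t-SNE emphasizes slow motions.  The whole transform collapses to a single
affine map, which keeps collective-variable gradients trivial.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .trajectory_io import ScaledCoordinates, Trajectory


class DegenerateCovarianceError(ValueError):
    """Covariance of the input has no usable variance."""


class InsufficientPairsError(ValueError):
    """Lag leaves fewer than one usable frame pair."""


@dataclass
class WhitenedCoordinates:
    """Whitened series ``Y`` with the map that produced it.

    ``Y = (X - mean) @ whitening_map`` has identity sample covariance on the
    retained components; ``component_variances`` are the covariance
    eigenvalues of the retained components.
    """

    Y: np.ndarray
    whitening_map: np.ndarray
    mean: np.ndarray
    component_variances: np.ndarray


@dataclass
class LaggedCovariance:
    C: np.ndarray
    C_sym: np.ndarray
    lag: int


@dataclass
class TimeLagBasis:
    """One affine map from superposed raw coordinates to time-lag projections.

    Composition: center on reference, global 0-1 affine, subtract column
    means, whitening map, lagged-eigenvector expansion.  ``linear``/``const``
    record the collapsed map z = coords @ linear + const.
    """

    ref_coords: np.ndarray
    offset: float
    scale: float
    mean: np.ndarray
    whitening_map: np.ndarray
    lag_map: np.ndarray
    lag: int
    eigenvalues: np.ndarray
    eigenvalue_signs: np.ndarray

    def __post_init__(self) -> None:
        # collapse to a single affine map from superposed coords to outputs
        W = self.whitening_map @ self.lag_map
        self.linear = self.scale * W
        self.const = (
            (-self.ref_coords * self.scale + self.offset - self.mean) @ W
        )

    @property
    def n_components(self) -> int:
        return self.lag_map.shape[1]

    def save(self, path: str) -> None:
        """Serialize as JSON header + raw little-endian float64 blocks."""
        header = {
            "schema": "ptltsne-basis-1",
            "lag": int(self.lag),
            "offset": float(self.offset),
            "scale": float(self.scale),
            "shapes": {
                "ref_coords": list(self.ref_coords.shape),
                "mean": list(self.mean.shape),
                "whitening_map": list(self.whitening_map.shape),
                "lag_map": list(self.lag_map.shape),
                "eigenvalues": list(self.eigenvalues.shape),
                "eigenvalue_signs": list(self.eigenvalue_signs.shape),
            },
        }
        blocks = b"".join(
            np.ascontiguousarray(getattr(self, k), dtype="<f8").tobytes()
            for k in header["shapes"]
        )
        head = json.dumps(header).encode()
        with open(path, "wb") as fh:
            fh.write(len(head).to_bytes(8, "little"))
            fh.write(head)
            fh.write(blocks)

    @classmethod
    def load(cls, path: str) -> "TimeLagBasis":
        with open(path, "rb") as fh:
            n = int.from_bytes(fh.read(8), "little")
            header = json.loads(fh.read(n).decode())
            if header.get("schema") != "ptltsne-basis-1":
                raise ValueError(f"unknown basis schema in {path}")
            arrays = {}
            for key, shape in header["shapes"].items():
                count = int(np.prod(shape)) if shape else 1
                buf = fh.read(count * 8)
                if len(buf) != count * 8:
                    raise ValueError(f"truncated basis file {path}")
                arrays[key] = np.frombuffer(buf, dtype="<f8").reshape(shape).copy()
        return cls(
            ref_coords=arrays["ref_coords"],
            offset=header["offset"],
            scale=header["scale"],
            mean=arrays["mean"],
            whitening_map=arrays["whitening_map"],
            lag_map=arrays["lag_map"],
            lag=header["lag"],
            eigenvalues=arrays["eigenvalues"],
            eigenvalue_signs=arrays["eigenvalue_signs"],
        )


def whiten(X: ScaledCoordinates | np.ndarray, variance_floor: float = 1e-10) -> WhitenedCoordinates:
    """Whiten scaled coordinates by eigenvector projection.

    Components with covariance eigenvalue ``<= variance_floor * max_eigenvalue``
    are dropped.  Covariance uses the 1/N normalization so that the lag-0
    covariance of the output is the identity under the same estimator.
    """
    arr = X.X if isinstance(X, ScaledCoordinates) else np.asarray(X, dtype=float)
    n = arr.shape[0]
    mean = arr.mean(axis=0)
    Xc = arr - mean
    cov = (Xc.T @ Xc) / n
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if evals[0] <= 0:
        raise DegenerateCovarianceError("constant trajectory: zero covariance")
    keep = evals > variance_floor * evals[0]
    evals = evals[keep]
    evecs = evecs[:, keep]
    wmap = evecs / np.sqrt(evals)
    return WhitenedCoordinates(
        Y=Xc @ wmap, whitening_map=wmap, mean=mean, component_variances=evals
    )


def lagged_covariance(Y: WhitenedCoordinates | np.ndarray, lag: int) -> LaggedCovariance:
    """Time-lagged covariance ``C[a,b] = mean_t Y[t,a] Y[t+lag,b]``.

    Uses the N - lag available pairs and the one global mean already removed
    during whitening (stationarity assumption); ``C_sym`` is the exact
    half-sum with its transpose.
    """
    arr = Y.Y if isinstance(Y, WhitenedCoordinates) else np.asarray(Y, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    n = arr.shape[0]
    lag = int(lag)
    if lag < 0:
        raise ValueError("lag must be non-negative")
    if lag >= n - 1 and lag != 0:
        raise InsufficientPairsError(f"lag {lag} leaves fewer than 2 pairs (N={n})")
    m = n - lag
    C = (arr[:m].T @ arr[lag:]) / m
    C_sym = 0.5 * (C + C.T)
    return LaggedCovariance(C=C, C_sym=C_sym, lag=lag)


def build_basis(
    X: ScaledCoordinates,
    lag: int,
    n_components: int | None = None,
    variance_floor: float = 1e-10,
) -> TimeLagBasis:
    """Build the complete time-lag basis from scaled coordinates.

    Eigenvectors of the symmetrized lagged covariance are sorted by
    eigenvalue magnitude (descending) and each is expanded by
    ``sqrt(|lambda|)``; signs are recorded separately so the map stays real
    even for anticorrelated components.
    """
    white = whiten(X, variance_floor=variance_floor)
    lc = lagged_covariance(white, lag)
    evals, evecs = np.linalg.eigh(lc.C_sym)
    order = np.argsort(np.abs(evals))[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if n_components is not None:
        if n_components > evals.shape[0]:
            raise ValueError(
                f"n_components={n_components} exceeds available {evals.shape[0]}"
            )
        evals = evals[:n_components]
        evecs = evecs[:, :n_components]
    lag_map = evecs * np.sqrt(np.abs(evals))
    return TimeLagBasis(
        ref_coords=X.ref.coords.copy(),
        offset=X.offset,
        scale=X.scale,
        mean=white.mean,
        whitening_map=white.whitening_map,
        lag_map=lag_map,
        lag=lag,
        eigenvalues=evals,
        eigenvalue_signs=np.sign(evals),
    )


def apply_basis(basis: TimeLagBasis, coords: Trajectory | np.ndarray) -> np.ndarray:
    """Affine projection of superposed coordinates onto the basis.

    Accepts a :class:`Trajectory`, an ``N x M`` matrix or a single flat
    frame; batch and single-frame paths evaluate the identical map.
    """
    arr = coords.coords if isinstance(coords, Trajectory) else np.asarray(coords, dtype=float)
    single = arr.ndim == 1
    arr2 = np.atleast_2d(arr)
    if arr2.shape[1] != basis.linear.shape[0]:
        raise ValueError(
            f"frame dimension {arr2.shape[1]} does not match basis input "
            f"{basis.linear.shape[0]}"
        )
    out = arr2 @ basis.linear + basis.const
    return out[0] if single else out
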