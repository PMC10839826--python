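"""Free-energy surfaces from metadynamics output.

In well-tempered metadynamics the converged bias is related to the free
energy by ``F(s) = -(gamma/(gamma-1)) V_bias(s)`` (plain ``-V_bias`` without
tempering).  Marginalization converts a 2-D surface to a probability
profile, integrates one CV out, and converts back.  Time-series reweighting
uses per-frame weights ``exp(beta (V(s_t, t) - c(t)))`` with the
time-dependent bias offset

    c(t) = (1/beta) ln [ int ds exp(beta gamma V(s,t)/(gamma-1))
                        / int ds exp(beta V(s,t)/(gamma-1)) ]

evaluated by grid quadrature each time a hill is deposited.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .toy_sampler import KB, HillsLog, bias_on_grid


@dataclass
class FreeEnergySurface:
    """Gridded free energy (kJ/mol), anchored so that its minimum is 0."""

    axes: list[np.ndarray]
    values: np.ndarray
    temperature: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("free energy must be finite on the grid")

    @property
    def ndim(self) -> int:
        return len(self.axes)

    def anchored(self) -> "FreeEnergySurface":
        return FreeEnergySurface(
            axes=self.axes, values=self.values - self.values.min(),
            temperature=self.temperature,
        )


@dataclass
class ReweightedEstimate:
    weights: np.ndarray
    fes: FreeEnergySurface
    c_of_t: np.ndarray
    c_times: np.ndarray


def make_axis(lo: float, hi: float, n_bins: int) -> np.ndarray:
    """Bin-center axis for an [lo, hi] range."""
    edges = np.linspace(lo, hi, n_bins + 1)
    return 0.5 * (edges[:-1] + edges[1:])


def fes_from_hills(
    hills: HillsLog,
    axes: list[np.ndarray],
    bias_factor: float | None = None,
    temperature: float = 300.0,
    well_tempered: bool = True,
) -> FreeEnergySurface:
    """Scaled negative image of the bias potential, anchored to min 0."""
    if len(hills) == 0:
        warnings.warn("empty hills log: returning a flat zero surface")
        V = bias_on_grid(hills, axes)
        return FreeEnergySurface(axes=axes, values=V, temperature=temperature)
    gamma = hills.bias_factor if bias_factor is None else bias_factor
    V = bias_on_grid(hills, axes)
    if well_tempered:
        if gamma <= 1:
            raise ValueError("well-tempered FES needs bias factor > 1")
        F = -gamma / (gamma - 1.0) * V
    else:
        F = -V
    return FreeEnergySurface(
        axes=axes, values=F - F.min(), temperature=temperature
    )


def marginalize_fes(
    fes: FreeEnergySurface, axis_to_integrate: int, temperature: float | None = None
) -> FreeEnergySurface:
    """Integrate the Boltzmann weight over one CV of a 2-D surface.

    ``p = exp(-F/kT)`` (max-shifted), Riemann sum over the integrated axis,
    ``F1 = -kT ln p1`` re-anchored to 0.
    """
    if fes.ndim != 2:
        raise ValueError("marginalization expects a 2-D surface")
    T = fes.temperature if temperature is None else temperature
    beta = 1.0 / (KB * T)
    logp = -beta * fes.values
    log_marg = logsumexp(logp, axis=axis_to_integrate)
    F1 = -log_marg / beta
    keep = 1 - axis_to_integrate
    return FreeEnergySurface(axes=[fes.axes[keep]], values=F1 - F1.min(), temperature=T)


def fes_from_weighted_samples(
    values: np.ndarray,
    weights: np.ndarray,
    axis: np.ndarray,
    temperature: float,
) -> FreeEnergySurface:
    """Weighted histogram of a 1-D CV converted to free energy."""
    edges = np.concatenate(
        [
            [axis[0] - 0.5 * (axis[1] - axis[0])],
            0.5 * (axis[1:] + axis[:-1]),
            [axis[-1] + 0.5 * (axis[-1] - axis[-2])],
        ]
    )
    hist, _ = np.histogram(values, bins=edges, weights=weights)
    with np.errstate(divide="ignore"):
        F = -KB * temperature * np.log(hist / hist.sum())
    finite = np.isfinite(F)
    if not finite.any():
        raise FloatingPointError("all histogram bins empty")
    F[~finite] = np.nan  # empty bins undefined; callers mask them
    F = F - np.nanmin(F)
    F = np.where(np.isfinite(F), F, np.nanmax(F))
    return FreeEnergySurface(axes=[axis], values=F, temperature=temperature)


def compute_c_of_t(
    hills: HillsLog,
    axes: list[np.ndarray],
    bias_factor: float,
    temperature: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Time-dependent bias offset c(t) after each hill deposition.

    The bias grid is accumulated incrementally (one Gaussian per step), so
    the cost is hills x grid, not hills^2 x grid.
    """
    beta = 1.0 / (KB * temperature)
    gamma = bias_factor
    T_arr, C, W, H = hills.arrays()
    mesh = np.meshgrid(*axes, indexing="ij")
    V = np.zeros(mesh[0].shape)
    c_vals = np.empty(len(hills))
    for k in range(len(hills)):
        e = np.zeros(V.shape)
        for d, ax in enumerate(mesh):
            e += (ax - C[k, d]) ** 2 / (2.0 * W[k, d] ** 2)
        V += H[k] * np.exp(-e)
        num = logsumexp(beta * gamma / (gamma - 1.0) * V)
        den = logsumexp(beta / (gamma - 1.0) * V)
        c_vals[k] = (num - den) / beta
    return T_arr, c_vals


def reweight(
    colvar: dict,
    hills: HillsLog,
    bias_factor: float,
    temperature: float,
    new_cv: np.ndarray,
    new_cv_axis: np.ndarray,
    discard: float = 0.0,
    grid_axes: list[np.ndarray] | None = None,
) -> ReweightedEstimate:
    """Umbrella-sampling reweighting with the time-dependent offset c(t).

    ``colvar`` must carry the per-frame bias energy ``V(s_t, t)`` (as written
    by the sampler) time-aligned with the hills schedule; frames before
    ``discard`` (ps) are dropped.  The weighted histogram of ``new_cv`` is
    returned as a free-energy estimate.
    """
    times = np.asarray(colvar["time"], dtype=float)
    bias = np.asarray(colvar["bias"], dtype=float)
    new_cv = np.asarray(new_cv, dtype=float)
    if len(times) != len(new_cv):
        raise ValueError("new_cv must align with the COLVAR frames")
    if len(hills) and times[-1] < hills.times[0]:
        raise ValueError("hills schedule does not overlap the COLVAR series")
    beta = 1.0 / (KB * temperature)
    if grid_axes is None:
        grid_axes = [new_cv_axis] if hills.n_cvs == 1 else None
    if grid_axes is None:
        raise ValueError("grid_axes required for multi-dimensional CVs")
    if len(hills):
        hill_times, c_vals = compute_c_of_t(hills, grid_axes, bias_factor, temperature)
        idx = np.searchsorted(hill_times, times, side="right") - 1
        c_frames = np.where(idx >= 0, c_vals[np.clip(idx, 0, None)], 0.0)
    else:
        hill_times = np.zeros(0)
        c_vals = np.zeros(0)
        c_frames = np.zeros(len(times))
    logw = beta * (bias - c_frames)
    keep = times >= discard
    if not keep.any():
        raise ValueError("discard removed every frame")
    logw = logw[keep] - logsumexp(logw[keep])
    weights = np.exp(logw)
    fes = fes_from_weighted_samples(new_cv[keep], weights, new_cv_axis, temperature)
    return ReweightedEstimate(
        weights=weights, fes=fes, c_of_t=c_vals, c_times=hill_times
    )


def folded_fraction(
    weights: np.ndarray, indicator: np.ndarray, blocks: int = 10
) -> tuple[float, float]:
    """Weighted fraction of frames with indicator 1, with block-average SEM.

    Frames are split into ``blocks`` contiguous equal-length windows; the
    mean and the standard error of the mean are taken across windows.
    """
    w = np.asarray(weights, dtype=float)
    ind = np.asarray(indicator, dtype=float)
    if blocks < 2:
        raise ValueError("need at least 2 blocks")
    if w.shape != ind.shape:
        raise ValueError("weights and indicator must align")
    parts_w = np.array_split(w, blocks)
    parts_i = np.array_split(ind, blocks)
    means = []
    for bw, bi in zip(parts_w, parts_i):
        tot = bw.sum()
        if tot <= 0 or bw.size == 0:
            warnings.warn("empty block dropped from the SEM estimate")
            continue
        means.append(float((bw * bi).sum() / tot))
    means = np.asarray(means)
    if means.size < 2:
        raise ValueError("fewer than 2 usable blocks")
    sem = float(means.std(ddof=1) / np.sqrt(means.size))
    return float(means.mean()), sem


# ---------------------------------------------------------------------------
# gridded text I/O (PLUMED-like)

def write_fes(path: str, fes: FreeEnergySurface) -> None:
    mesh = np.meshgrid(*fes.axes, indexing="ij")
    cols = [m.reshape(-1) for m in mesh] + [fes.values.reshape(-1)]
    names = [f"cv{i+1}" for i in range(fes.ndim)] + ["free_energy"]
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(names) + "\n")
        fh.write(f"#! SET temperature {fes.temperature}\n")
        for i in range(fes.ndim):
            fh.write(f"#! SET nbins_cv{i+1} {len(fes.axes[i])}\n")
        for row in zip(*cols):
            fh.write(" ".join(f"{v:.9f}" for v in row) + "\n")


def read_fes(path: str) -> FreeEnergySurface:
    nbins = []
    temperature = 300.0
    with open(path) as fh:
        lines = fh.readlines()
    data_rows = []
    for ln in lines:
        if ln.startswith("#! SET temperature"):
            temperature = float(ln.split()[-1])
        elif ln.startswith("#! SET nbins"):
            nbins.append(int(ln.split()[-1]))
        elif not ln.startswith("#"):
            data_rows.append([float(v) for v in ln.split()])
    data = np.asarray(data_rows)
    ndim = data.shape[1] - 1
    if len(nbins) != ndim:
        raise ValueError(f"malformed FES file {path}")
    axes = []
    vals = data[:, -1].reshape(nbins)
    grid_cols = data[:, :ndim]
    full = grid_cols[:, 0].reshape(nbins)
    axes.append(full[(slice(None),) + (0,) * (ndim - 1)])
    for d in range(1, ndim):
        full = grid_cols[:, d].reshape(nbins)
        axes.append(full[(0,) * d + (slice(None),)])
    return FreeEnergySurface(axes=axes, values=vals, temperature=temperature)
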