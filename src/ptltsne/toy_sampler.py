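"""Desk-scale Langevin dynamics with well-tempered metadynamics.

A BAOAB Langevin integrator samples analytic potentials (1-D double well,
2-D triple well, or a double well embedded in a higher-dimensional harmonic
landscape) at a fixed temperature.  Gaussian hills are deposited along any
differentiable collective variable — an analytic CV or a trained
:class:`~ptltsne.parametric_model.CVModel` — with the well-tempered height
schedule ``w = w0 exp(-V_bias(s) / (kB dT))``, ``dT = (gamma - 1) T``.
Hills and CV series are written in the PLUMED HILLS/COLVAR text dialects.

Energies are kJ/mol, temperatures K, times ps, ``kB`` in kJ/(mol K).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Boltzmann constant, kJ/(mol K)
KB = 0.008314462618


# ---------------------------------------------------------------------------
# potentials

@dataclass
class DoubleWell1D:
    """``U(x) = barrier * (x^2 - 1)^2`` — minima at +-1, barrier at 0 (kJ/mol)."""

    barrier: float = 15.0
    dimension: int = 1

    def energy(self, x: np.ndarray) -> float:
        return float(self.barrier * (x[0] ** 2 - 1.0) ** 2)

    def force(self, x: np.ndarray) -> np.ndarray:
        return np.array([-4.0 * self.barrier * x[0] * (x[0] ** 2 - 1.0)])


@dataclass
class TripleWell2D:
    """Three Gaussian wells of depth ``depth`` on a harmonic background."""

    depth: float = 12.0
    dimension: int = 2
    centers: np.ndarray = field(
        default_factory=lambda: np.array([[-1.0, 0.0], [1.0, 0.0], [0.0, 1.5]])
    )
    width: float = 0.45
    confine: float = 2.0

    def energy(self, x: np.ndarray) -> float:
        d2 = np.sum((self.centers - x) ** 2, axis=1)
        wells = -self.depth * np.exp(-d2 / (2 * self.width**2))
        return float(wells.sum() + 0.5 * self.confine * np.sum(x**2))

    def force(self, x: np.ndarray) -> np.ndarray:
        d = self.centers - x  # (3, 2)
        d2 = np.sum(d**2, axis=1)
        g = -self.depth * np.exp(-d2 / (2 * self.width**2)) / self.width**2
        return (g[:, None] * d).sum(axis=0) - self.confine * x


@dataclass
class EmbeddedDoubleWell:
    """Double well along a fixed unit direction, harmonic in the orthogonal
    complement — a pseudo-molecular stand-in with many coupled coordinates."""

    direction: np.ndarray
    barrier: float = 15.0
    stiffness: float = 50.0

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        self.direction = self.direction / np.linalg.norm(self.direction)
        self.dimension = self.direction.size

    def energy(self, x: np.ndarray) -> float:
        s = float(self.direction @ x)
        perp = x - s * self.direction
        return float(
            self.barrier * (s**2 - 1.0) ** 2 + 0.5 * self.stiffness * perp @ perp
        )

    def force(self, x: np.ndarray) -> np.ndarray:
        s = float(self.direction @ x)
        perp = x - s * self.direction
        return (
            -4.0 * self.barrier * s * (s**2 - 1.0) * self.direction
            - self.stiffness * perp
        )


@dataclass
class ToySystem:
    """Analytic potential + Langevin thermostat parameters."""

    potential: object
    mass: float = 1.0
    friction: float = 1.0  # 1/ps
    temperature: float = 300.0  # K

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def dimension(self) -> int:
        return self.potential.dimension

    @property
    def kT(self) -> float:
        return KB * self.temperature


# ---------------------------------------------------------------------------
# collective variables

class IdentityCV:
    """CV = the system coordinates themselves."""

    def __init__(self, dimension: int = 1):
        self.n_cvs = dimension

    def value(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float)

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        return np.eye(self.n_cvs)


class LinearCV:
    """CV = A @ x for a fixed matrix A (n_cvs x dim)."""

    def __init__(self, A: np.ndarray):
        self.A = np.atleast_2d(np.asarray(A, dtype=float))
        self.n_cvs = self.A.shape[0]

    def value(self, x: np.ndarray) -> np.ndarray:
        return self.A @ x

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        return self.A


class ModelCV:
    """Adapter exposing a trained CVModel as a differentiable CV."""

    def __init__(self, model, frozen_rotation: bool = False):
        self.model = model
        self.frozen_rotation = frozen_rotation
        self.n_cvs = model.net_cfg.output_dim

    def value(self, x: np.ndarray) -> np.ndarray:
        from .parametric_model import forward

        return forward(self.model, x, kind="raw")

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        from .parametric_model import cv_gradient

        return cv_gradient(self.model, x, frozen_rotation=self.frozen_rotation)


# ---------------------------------------------------------------------------
# metadynamics bias

@dataclass
class MetadynamicsParams:
    """Well-tempered hill schedule (PLUMED width convention: sigma in the
    exponent's ``2 sigma^2``)."""

    hill_height: float = 0.5  # kJ/mol
    hill_widths: tuple[float, ...] = (1.0,)
    deposition_stride: int = 500  # steps (1 ps at dt = 2 fs)
    bias_factor: float = 8.0
    well_tempered: bool = True

    def __post_init__(self) -> None:
        if self.hill_height <= 0 or any(w <= 0 for w in self.hill_widths):
            raise ValueError("hill height and widths must be positive")
        if self.well_tempered and self.bias_factor <= 1:
            raise ValueError("bias factor must exceed 1 in well-tempered mode")


class HillsLog:
    """Deposited Gaussian hills: time (ps), center, widths, height (kJ/mol).

    Backed by capacity-doubling numpy buffers so per-step bias evaluation
    during a run never copies the whole log.
    """

    def __init__(self, n_cvs: int, bias_factor: float = 8.0):
        self.n_cvs = n_cvs
        self.bias_factor = bias_factor
        self._n = 0
        cap = 64
        self._t = np.empty(cap)
        self._c = np.empty((cap, n_cvs))
        self._w = np.empty((cap, n_cvs))
        self._h = np.empty(cap)

    def __len__(self) -> int:
        return self._n

    @property
    def times(self) -> np.ndarray:
        return self._t[: self._n]

    @property
    def heights(self) -> np.ndarray:
        return self._h[: self._n]

    def append(self, time: float, center, widths, height: float) -> None:
        if self._n == self._t.shape[0]:
            cap = 2 * self._n
            self._t = np.concatenate([self._t, np.empty(self._n)])
            self._c = np.concatenate([self._c, np.empty((self._n, self.n_cvs))])
            self._w = np.concatenate([self._w, np.empty((self._n, self.n_cvs))])
            self._h = np.concatenate([self._h, np.empty(self._n)])
        self._t[self._n] = time
        self._c[self._n] = np.atleast_1d(np.asarray(center, dtype=float))
        self._w[self._n] = np.atleast_1d(np.asarray(widths, dtype=float))
        self._h[self._n] = height
        self._n += 1

    def arrays(self):
        n = self._n
        return self._t[:n], self._c[:n], self._w[:n], self._h[:n]


def bias_value_and_gradient(
    hills: HillsLog, s: np.ndarray, n_hills: int | None = None
) -> tuple[float, np.ndarray]:
    """Bias ``V(s) = sum_k h_k exp(-sum_d (s_d - c_kd)^2 / (2 sigma_kd^2))``
    and its analytic gradient; optionally truncated to the first ``n_hills``."""
    s = np.atleast_1d(np.asarray(s, dtype=float))
    m = len(hills) if n_hills is None else min(n_hills, len(hills))
    if m == 0:
        return 0.0, np.zeros_like(s)
    _, C, W, H = hills.arrays()
    C, W, H = C[:m], W[:m], H[:m]
    diff = s[None, :] - C
    g = H * np.exp(-np.sum(diff**2 / (2.0 * W**2), axis=1))
    V = float(g.sum())
    grad = -(g[:, None] * diff / W**2).sum(axis=0)
    return V, grad


def bias_on_grid(
    hills: HillsLog, axes: list[np.ndarray], n_hills: int | None = None
) -> np.ndarray:
    """Evaluate the hill sum on a tensor grid (1-D or 2-D)."""
    m = len(hills) if n_hills is None else min(n_hills, len(hills))
    mesh = np.meshgrid(*axes, indexing="ij")
    out = np.zeros(mesh[0].shape)
    if m == 0:
        return out
    _, C, W, H = hills.arrays()
    for k in range(m):
        e = np.zeros(mesh[0].shape)
        for d, ax in enumerate(mesh):
            e += (ax - C[k, d]) ** 2 / (2.0 * W[k, d] ** 2)
        out += H[k] * np.exp(-e)
    return out


# ---------------------------------------------------------------------------
# integration

def total_energy(system: ToySystem, cv, hills: HillsLog | None, x: np.ndarray) -> float:
    """``U(x) + V_bias(cv(x))`` — the energy whose negative gradient drives
    a biased run."""
    e = system.potential.energy(x)
    if hills is not None and len(hills):
        e += bias_value_and_gradient(hills, cv.value(x))[0]
    return e


def total_force(system: ToySystem, cv, hills: HillsLog | None, x: np.ndarray) -> np.ndarray:
    """``-grad U - J_cv^T dV_bias/ds`` at x."""
    f = system.potential.force(x)
    if hills is not None and len(hills):
        _, dVds = bias_value_and_gradient(hills, cv.value(x))
        f = f - cv.jacobian(x).T @ dVds
    return f


def run_metadynamics(
    system: ToySystem,
    cv,
    meta: MetadynamicsParams | None,
    n_steps: int,
    dt: float,
    seed: int,
    x0: np.ndarray | None = None,
    colvar_stride: int = 10,
) -> tuple[np.ndarray, dict, HillsLog]:
    """BAOAB Langevin dynamics with optional well-tempered metadynamics.

    With ``meta=None`` the run is unbiased but otherwise identical (same
    integrator, same random stream usage).  Returns the position series
    sampled every ``colvar_stride`` steps, a COLVAR-style dict with keys
    ``time``/``cv``/``bias``, and the hills log.

    The total force is ``-grad U - J_cv^T dV_bias/ds``; hill heights follow
    the well-tempered schedule evaluated at the current bias.
    """
    rng = np.random.default_rng(seed)
    dim = system.dimension
    x = np.zeros(dim) if x0 is None else np.asarray(x0, dtype=float).copy()
    v = rng.normal(0.0, np.sqrt(system.kT / system.mass), size=dim)
    n_cvs = getattr(cv, "n_cvs", 1)
    biased = meta is not None
    hills = HillsLog(n_cvs, bias_factor=meta.bias_factor if biased else 0.0)
    if biased and len(meta.hill_widths) != n_cvs:
        raise ValueError("hill_widths length must match the number of CVs")
    c1 = np.exp(-system.friction * dt)
    c2 = np.sqrt((1.0 - c1**2) * system.kT / system.mass)
    times, positions, cv_series, bias_series = [], [], [], []

    bias_log = hills if biased else None
    f = total_force(system, cv, bias_log, x)
    for step in range(1, n_steps + 1):
        v = v + 0.5 * dt * f / system.mass
        x = x + 0.5 * dt * v
        v = c1 * v + c2 * rng.normal(size=dim)
        x = x + 0.5 * dt * v
        f = total_force(system, cv, bias_log, x)
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(f"non-finite state at step {step}")
        v = v + 0.5 * dt * f / system.mass
        if biased and step % meta.deposition_stride == 0:
            s = cv.value(x)
            if meta.well_tempered:
                Vb, _ = bias_value_and_gradient(hills, s)
                dT = (meta.bias_factor - 1.0) * system.temperature
                h = meta.hill_height * np.exp(-Vb / (KB * dT))
            else:
                h = meta.hill_height
            hills.append(step * dt, s, meta.hill_widths, h)
            f = total_force(system, cv, bias_log, x)
        if step % colvar_stride == 0:
            s = cv.value(x)
            Vb, _ = bias_value_and_gradient(hills, s) if biased else (0.0, None)
            times.append(step * dt)
            positions.append(x.copy())
            cv_series.append(np.atleast_1d(s))
            bias_series.append(Vb)
    colvar = {
        "time": np.asarray(times),
        "cv": np.stack(cv_series) if cv_series else np.zeros((0, n_cvs)),
        "bias": np.asarray(bias_series),
    }
    return np.stack(positions) if positions else np.zeros((0, dim)), colvar, hills


# ---------------------------------------------------------------------------
# replica exchange

@dataclass
class ReplicaState:
    x: np.ndarray
    v: np.ndarray


def replica_exchange_step(
    states: list[ReplicaState],
    temperatures: list[float],
    system: ToySystem,
    rng: np.random.Generator,
    biases: list[HillsLog] | None = None,
    cv=None,
    parity: int = 0,
) -> list[tuple[int, int, bool]]:
    """Attempt neighbor swaps (pairs of the given parity) with the
    parallel-tempering-metadynamics Metropolis rule.

    The acceptance exponent includes both replicas' own bias potentials:
    ``delta = b_i [E_i(x_i) - E_i(x_j)] + b_j [E_j(x_j) - E_j(x_i)]`` with
    ``E_k = U + V_k(s(.))``; accept with probability ``min(1, exp(delta))``.
    Velocities are rescaled by ``sqrt(T_new / T_old)`` on exchange.
    """
    n = len(states)
    if len(temperatures) != n or (biases is not None and len(biases) != n):
        raise ValueError("replica count mismatch")
    if any(temperatures[i] > temperatures[i + 1] for i in range(n - 1)):
        raise ValueError("temperatures must be sorted ascending")
    results = []
    for i in range(parity % 2, n - 1, 2):
        j = i + 1
        bi = 1.0 / (KB * temperatures[i])
        bj = 1.0 / (KB * temperatures[j])
        xi, xj = states[i].x, states[j].x
        Ui, Uj = system.potential.energy(xi), system.potential.energy(xj)

        def bias_at(k: int, x: np.ndarray) -> float:
            if biases is None or cv is None or len(biases[k]) == 0:
                return 0.0
            return bias_value_and_gradient(biases[k], cv.value(x))[0]

        Ei_xi = Ui + bias_at(i, xi)
        Ei_xj = Uj + bias_at(i, xj)
        Ej_xj = Uj + bias_at(j, xj)
        Ej_xi = Ui + bias_at(j, xi)
        delta = bi * (Ei_xi - Ei_xj) + bj * (Ej_xj - Ej_xi)
        accept = bool(np.log(rng.uniform()) < delta)
        if accept:
            scale_up = np.sqrt(temperatures[j] / temperatures[i])
            states[i].x, states[j].x = states[j].x, states[i].x
            states[i].v, states[j].v = states[j].v / scale_up, states[i].v * scale_up
        results.append((i, j, accept))
    return results


# ---------------------------------------------------------------------------
# PLUMED text dialects

def write_hills(path: str, hills: HillsLog, cv_names: list[str] | None = None) -> None:
    T, C, W, H = hills.arrays()
    names = cv_names or [f"cv{i+1}" for i in range(hills.n_cvs)]
    fields = ["time"] + names + [f"sigma_{n}" for n in names] + ["height", "biasf"]
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(fields) + "\n")
        for k in range(len(H)):
            row = [T[k], *C[k], *W[k], H[k], hills.bias_factor]
            fh.write(" ".join(f"{v:.9f}" for v in row) + "\n")


def read_hills(path: str) -> HillsLog:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#! FIELDS"):
            raise ValueError(f"{path} is not a HILLS file (missing FIELDS header)")
        fields = header.split()[2:]
        n_cvs = sum(1 for f in fields if f.startswith("sigma_"))
        data = np.loadtxt(fh, ndmin=2)
    if data.size == 0:
        return HillsLog(max(n_cvs, 1))
    hills = HillsLog(n_cvs)
    for row in data:
        hills.append(row[0], row[1 : 1 + n_cvs], row[1 + n_cvs : 1 + 2 * n_cvs], row[1 + 2 * n_cvs])
    if data.shape[1] > 2 + 2 * n_cvs:
        hills.bias_factor = float(data[0, 2 + 2 * n_cvs])
    return hills


def write_colvar(path: str, colvar: dict, cv_names: list[str] | None = None) -> None:
    cvs = colvar["cv"]
    names = cv_names or [f"cv{i+1}" for i in range(cvs.shape[1])]
    with open(path, "w") as fh:
        fh.write("#! FIELDS time " + " ".join(names) + " bias\n")
        for t, s, b in zip(colvar["time"], cvs, colvar["bias"]):
            fh.write(" ".join(f"{v:.9f}" for v in [t, *s, b]) + "\n")


def read_colvar(path: str) -> dict:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#! FIELDS"):
            raise ValueError(f"{path} is not a COLVAR file (missing FIELDS header)")
        fields = header.split()[2:]
        data = np.loadtxt(fh, ndmin=2)
    n_cvs = len(fields) - 2  # time ... bias
    return {
        "time": data[:, 0],
        "cv": data[:, 1 : 1 + n_cvs],
        "bias": data[:, 1 + n_cvs],
    }
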