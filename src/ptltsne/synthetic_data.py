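"""Synthetic trajectories with a planted slow degree of freedom.

The generator emulates the statistical situation the time-lag machinery is
designed to resolve: a low-variance SLOW coordinate ``z`` hopping between
two metastable wells (overdamped Langevin on a symmetric double well,
rare barrier crossings) superposed with high-variance FAST noise
(independent Ornstein-Uhlenbeck processes relaxing in 1-2 frames whose
amplitude dominates the variance).  The signals are then lifted nonlinearly
to pseudo-atomic Cartesian coordinates with optional random per-frame
rigid-body motion, so superposition, scaling, whitening, the lagged basis
and the network all get exercised with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory_io import ReferenceStructure, Trajectory


@dataclass
class SyntheticGroundTruth:
    """Planted signals behind a synthetic trajectory."""

    slow_series: np.ndarray
    fast_series: np.ndarray
    state_labels: np.ndarray
    generator_params: dict = field(default_factory=dict)


def _kramers_time(barrier_kT: float, mobility: float) -> float:
    """Mean well lifetime (frames) of ``U = B (z^2-1)^2`` by the Kramers rate.

    Curvatures: ``U''(min) = 8B``, ``|U''(barrier)| = 4B``.
    """
    if barrier_kT <= 0:
        return 1.0 / mobility  # OU relaxation of the harmonic fallback
    omega = np.sqrt(8.0 * barrier_kT * 4.0 * barrier_kT)
    rate = mobility * omega / (2.0 * np.pi) * np.exp(-barrier_kT)
    return 1.0 / rate


def generate_slow_fast(
    n_frames: int,
    n_fast: int = 10,
    slow_barrier_kT: float = 6.0,
    fast_amplitude: float = 3.0,
    seed: int = 0,
    mobility: float = 0.02,
    fast_relax: float = 1.5,
    n_substeps: int = 20,
) -> SyntheticGroundTruth:
    """Simulate the slow double-well coordinate and the fast OU noise.

    ``z`` follows overdamped Langevin dynamics (Euler-Maruyama with
    ``n_substeps`` substeps per frame for stability) on
    ``U(z) = barrier * (z^2 - 1)^2`` in units of kT; with zero barrier the
    potential degenerates to a unit harmonic well, making ``z`` a free OU
    process.  Fast coordinates are independent OU processes with stationary
    standard deviation ``fast_amplitude`` (>= 3x the slow amplitude, so fast
    modes dominate the variance) and relaxation ``fast_relax`` frames.
    State labels are the sign of ``z``.
    """
    if n_frames < 1000:
        raise ValueError("need n_frames >= 1000 for meaningful statistics")
    if fast_amplitude < 3.0:
        raise ValueError("fast amplitude must be >= 3x the slow amplitude (1)")
    tau_slow = _kramers_time(slow_barrier_kT, mobility)
    if tau_slow / fast_relax < 20.0:
        raise ValueError(
            f"slow/fast timescale ratio {tau_slow / fast_relax:.1f} < 20; "
            "raise the barrier or lower the mobility"
        )
    rng = np.random.default_rng(seed)
    B = slow_barrier_kT
    dt = 1.0 / n_substeps
    z = np.empty(n_frames)
    zc = 1.0 if B > 0 else 0.0  # start in the right-hand well
    noise_scale = np.sqrt(2.0 * mobility * dt)
    for t in range(n_frames):
        for _ in range(n_substeps):
            if B > 0:
                grad = 4.0 * B * zc * (zc**2 - 1.0)
            else:
                grad = zc
            zc = zc - mobility * grad * dt + noise_scale * rng.normal()
        z[t] = zc
    a = np.exp(-1.0 / fast_relax)
    fast = np.empty((n_frames, n_fast))
    fast[0] = rng.normal(0.0, fast_amplitude, size=n_fast)
    innov = rng.normal(0.0, fast_amplitude * np.sqrt(1 - a**2), size=(n_frames - 1, n_fast))
    for t in range(1, n_frames):
        fast[t] = a * fast[t - 1] + innov[t - 1]
    labels = (z > 0).astype(int)
    return SyntheticGroundTruth(
        slow_series=z,
        fast_series=fast,
        state_labels=labels,
        generator_params={
            "n_frames": n_frames,
            "n_fast": n_fast,
            "slow_barrier_kT": slow_barrier_kT,
            "fast_amplitude": fast_amplitude,
            "mobility": mobility,
            "fast_relax": fast_relax,
            "expected_well_lifetime_frames": tau_slow,
            "seed": seed,
        },
    )


def count_transitions(z: np.ndarray, lo: float = -0.5, hi: float = 0.5) -> int:
    """Well-to-well crossings with hysteresis (must traverse [lo, hi])."""
    state = 1 if z[0] > 0 else -1
    count = 0
    for v in z:
        if state == 1 and v < lo:
            state = -1
            count += 1
        elif state == -1 and v > hi:
            state = 1
            count += 1
    return count


def lift_to_pseudo_atoms(
    gt: SyntheticGroundTruth,
    n_atoms: int = 10,
    nonlinearity: str = "mild",
    rigid_noise: bool = True,
    seed: int = 0,
    signal_scale: float = 0.1,
    scaffold_scale: float = 1.0,
    translation_scale: float = 0.5,
) -> tuple[Trajectory, ReferenceStructure]:
    """Lift (z, fast) into 3A Cartesian coordinates (nm).

    A fixed random scaffold gives each pseudo-atom a resting position; the
    signals deform it through a fixed random linear mixing, optionally warped
    by mild trigonometric/quadratic terms (``nonlinearity="mild"``; use
    ``"identity"`` for the purely affine lift).  With ``rigid_noise`` every
    frame additionally receives a uniform random rotation and a Gaussian
    translation, which superposition must remove.  Returns the trajectory
    and the undeformed scaffold as the reference structure.
    """
    if n_atoms < 4:
        raise ValueError("need at least 4 pseudo-atoms")
    rng = np.random.default_rng(seed)
    S = np.column_stack([gt.slow_series, gt.fast_series])
    n, k = S.shape
    m = 3 * n_atoms
    scaffold = rng.normal(0.0, scaffold_scale, size=m)
    mix = rng.normal(size=(k, m)) / np.sqrt(k)
    deform = S @ mix
    if nonlinearity == "mild":
        mix2 = rng.normal(size=(k, m)) / np.sqrt(k)
        mix3 = rng.normal(size=(k, m)) / np.sqrt(k)
        deform = deform + 0.5 * np.sin(S @ mix2) + 0.1 * (S @ mix3 / 3.0) ** 2
    elif nonlinearity != "identity":
        raise ValueError(f"unknown nonlinearity {nonlinearity!r}")
    coords = scaffold + signal_scale * deform
    coords = coords.reshape(n, n_atoms, 3)
    if rigid_noise:
        quats = rng.normal(size=(n, 4))
        quats /= np.linalg.norm(quats, axis=1, keepdims=True)
        trans = rng.normal(0.0, translation_scale, size=(n, 3))
        for t in range(n):
            w, x, y, zq = quats[t]
            R = np.array(
                [
                    [1 - 2 * (y * y + zq * zq), 2 * (x * y - w * zq), 2 * (x * zq + w * y)],
                    [2 * (x * y + w * zq), 1 - 2 * (x * x + zq * zq), 2 * (y * zq - w * x)],
                    [2 * (x * zq - w * y), 2 * (y * zq + w * x), 1 - 2 * (x * x + y * y)],
                ]
            )
            c = coords[t].mean(axis=0)
            coords[t] = (coords[t] - c) @ R.T + c + trans[t]
    traj = Trajectory(coords=coords.reshape(n, m))
    ref = ReferenceStructure(coords=scaffold)
    return traj, ref


#: shipped presets; the small one is sized for quick test cycles, the full
#: one for long acceptance runs
PRESETS = {
    "twostate-small": {
        "n_frames": 5000,
        "n_fast": 10,
        "n_atoms": 10,
        "slow_barrier_kT": 4.0,
        "fast_amplitude": 3.0,
        "mobility": 0.02,
        "fast_relax": 1.5,
        "lag": 10,
    },
    "twostate-full": {
        "n_frames": 50000,
        "n_fast": 10,
        "n_atoms": 10,
        "slow_barrier_kT": 6.0,
        "fast_amplitude": 3.0,
        "mobility": 0.02,
        "fast_relax": 1.5,
        "lag": 10,
    },
}


def generate_preset(
    name: str, seed: int = 0, rigid_noise: bool = True
) -> tuple[Trajectory, ReferenceStructure, SyntheticGroundTruth]:
    """Generate a shipped preset end to end (signals + pseudo-atom lift)."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    p = PRESETS[name]
    gt = generate_slow_fast(
        n_frames=p["n_frames"],
        n_fast=p["n_fast"],
        slow_barrier_kT=p["slow_barrier_kT"],
        fast_amplitude=p["fast_amplitude"],
        seed=seed,
        mobility=p["mobility"],
        fast_relax=p["fast_relax"],
    )
    traj, ref = lift_to_pseudo_atoms(
        gt, n_atoms=p["n_atoms"], rigid_noise=rigid_noise, seed=seed + 1
    )
    return traj, ref, gt
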