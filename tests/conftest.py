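import numpy as np
import pytest

from ptltsne.synthetic_data import generate_preset, generate_slow_fast, lift_to_pseudo_atoms


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_preset():
    """The shipped small two-state preset (seed 1), generated once."""
    return generate_preset("twostate-small", seed=1)


@pytest.fixture(scope="session")
def tiny_lifted():
    """A short lifted trajectory with ground truth for fast pipeline tests."""
    gt = generate_slow_fast(
        n_frames=1500, n_fast=6, slow_barrier_kT=2.5, fast_amplitude=3.0,
        seed=7, mobility=0.05,
    )
    traj, ref = lift_to_pseudo_atoms(gt, n_atoms=6, rigid_noise=True, seed=8)
    return traj, ref, gt
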