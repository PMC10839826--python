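import numpy as np
import pytest

from ptltsne import parametric_model as pm
from ptltsne.timelag import apply_basis, build_basis
from ptltsne.trajectory_io import (
    ReferenceStructure,
    Trajectory,
    center_scale,
    kabsch_superpose,
)
from ptltsne.tsne_core import joint_affinities, kl_gradient


@pytest.fixture()
def small_model(rng):
    """A model with a real basis (random 6-atom trajectory) and random weights."""
    coords = rng.normal(size=(200, 18))
    traj = Trajectory(coords)
    ref = ReferenceStructure(coords[0])
    sup = kabsch_superpose(traj, ref)
    basis = build_basis(center_scale(sup, ref), lag=1)
    cfg = pm.NetworkConfig(hidden_layers=(16, 16))
    weights = pm.build_network(cfg, basis.n_components, seed=5)
    return pm.CVModel(basis=basis, weights=weights, net_cfg=cfg)


class TestBuildNetwork:
    def test_default_parameter_count(self):
        cfg = pm.NetworkConfig()
        w = pm.build_network(cfg, input_dim=30, seed=0)
        count = sum(arr.size for arr in w)
        assert count == 30 * 256 + 256 * 256 * 2 + 256 * 2 + 2

    def test_seed_determinism(self):
        cfg = pm.NetworkConfig(hidden_layers=(8,))
        w1 = pm.build_network(cfg, 4, seed=42)
        w2 = pm.build_network(cfg, 4, seed=42)
        assert all(np.array_equal(a, b) for a, b in zip(w1, w2))

    def test_zero_weights_output_is_bias(self, rng):
        cfg = pm.NetworkConfig(hidden_layers=(8, 8))
        w = [np.zeros_like(a) for a in pm.build_network(cfg, 5, seed=0)]
        w[-1] = np.array([1.5, -2.5])  # output biases
        out = pm.network_forward(w, cfg, rng.normal(size=(7, 5)))
        assert np.allclose(out, [1.5, -2.5])


class TestForward:
    def test_hand_built_single_layer(self):
        """1 hidden layer, width 2, unit weights: output = sum(tanh(sum x))."""
        cfg = pm.NetworkConfig(hidden_layers=(2,), output_dim=1)
        weights = [np.ones((3, 2)), np.ones((2, 1)), np.zeros(1)]
        x = np.array([0.1, 0.2, 0.3])
        expect = 2 * np.tanh(0.6)
        out = pm.network_forward(weights, cfg, x)
        assert out[0, 0] == pytest.approx(expect, abs=1e-14)

    def test_raw_path_equals_projection_path(self, small_model, rng):
        frame = rng.normal(size=18)
        raw = pm.forward(small_model, frame, kind="raw")
        # manual: superpose then project then network
        sup = pm._superpose_frame(frame, small_model.basis)
        z = apply_basis(small_model.basis, sup)
        proj = pm.forward(small_model, z, kind="projections")
        assert np.allclose(raw, proj, atol=1e-12)

    def test_rigid_motion_invariance(self, small_model, rng):
        from scipy.spatial.transform import Rotation

        frame = rng.normal(size=18).reshape(6, 3)
        R = Rotation.from_euler("zxz", [33, 140, -61], degrees=True).as_matrix()
        moved = frame @ R.T + np.array([0.3, -1.0, 2.0])
        s1 = pm.forward(small_model, frame.reshape(-1), kind="raw")
        s2 = pm.forward(small_model, moved.reshape(-1), kind="raw")
        assert np.abs(s1 - s2).max() < 1e-8

    def test_batch_single_agree(self, small_model, rng):
        frames = rng.normal(size=(5, 18))
        batch = pm.forward(small_model, frames, kind="raw")
        single = np.stack([pm.forward(small_model, f, kind="raw") for f in frames])
        assert np.abs(batch - single).max() < 1e-12

    def test_dimension_mismatch(self, small_model):
        with pytest.raises(ValueError):
            pm.forward(small_model, np.zeros(7))


class TestTrain:
    def _clusters(self, rng, n=400, d=5):
        a = rng.normal(size=(n // 2, d)) + 4.0
        b = rng.normal(size=(n // 2, d)) - 4.0
        Z = np.vstack([a, b])
        labels = np.array([0] * (n // 2) + [1] * (n // 2))
        return Z, labels

    def test_two_clusters_separable(self, rng):
        from sklearn.metrics import silhouette_score

        Z, labels = self._clusters(rng)
        cfg = pm.TrainConfig(epochs=150, batch_size=200, shuffle_period=10,
                             perplexity=20, seed=0)
        net = pm.NetworkConfig(hidden_layers=(32, 32))
        model = pm.train(Z, net_cfg=net, train_cfg=cfg)
        S = pm.forward(model, Z, kind="projections")
        assert silhouette_score(S, labels) > 0.5

    def test_loss_decreases(self, rng):
        Z = rng.normal(size=(120, 4))
        cfg = pm.TrainConfig(epochs=60, batch_size=120, shuffle_period=10,
                             perplexity=15, seed=0)
        model = pm.train(Z, net_cfg=pm.NetworkConfig(hidden_layers=(16,)), train_cfg=cfg)
        h = model.loss_history
        assert np.median(h[-10:]) < np.median(h[:10])

    def test_seed_reproducibility(self, rng):
        Z = rng.normal(size=(60, 3))
        cfg = pm.TrainConfig(epochs=20, batch_size=30, shuffle_period=5,
                             perplexity=8, seed=11)
        net = pm.NetworkConfig(hidden_layers=(8,))
        h1 = pm.train(Z, net_cfg=net, train_cfg=cfg).loss_history
        h2 = pm.train(Z, net_cfg=net, train_cfg=cfg).loss_history
        assert h1 == h2

    def test_gradient_step_reduces_loss(self, rng):
        """Plain gradient step along the analytic training gradient reduces
        the KL loss for a small enough step size."""
        Z = rng.normal(size=(40, 3))
        cfg = pm.NetworkConfig(hidden_layers=(8,))
        weights = pm.build_network(cfg, 3, seed=2)
        P = joint_affinities(Z, 8.0).P
        S, acts = pm.network_forward(weights, cfg, Z, cache=True)
        loss0, dS = kl_gradient(P, S)
        grads = pm.network_backprop(weights, cfg, acts, dS)
        for step in (1e-2, 1e-3, 1e-4):
            new_w = [w - step * g for w, g in zip(weights, grads)]
            loss1, _ = kl_gradient(P, pm.network_forward(new_w, cfg, Z))
            if loss1 < loss0:
                break
        else:
            pytest.fail("no step size reduced the loss")


class TestCVGradient:
    def test_zero_network_zero_jacobian(self, small_model, rng):
        model = pm.CVModel(
            basis=small_model.basis,
            weights=[np.zeros_like(w) for w in small_model.weights],
            net_cfg=small_model.net_cfg,
        )
        jac = pm.cv_gradient(model, rng.normal(size=18))
        assert np.all(jac == 0)

    def test_matches_finite_differences(self, small_model, rng):
        h = 1e-5
        for _ in range(3):
            frame = rng.normal(size=18)
            jac = pm.cv_gradient(small_model, frame)
            num = np.empty_like(jac)
            for i in range(18):
                fp, fm = frame.copy(), frame.copy()
                fp[i] += h
                fm[i] -= h
                num[:, i] = (
                    pm.forward(small_model, fp, kind="raw")
                    - pm.forward(small_model, fm, kind="raw")
                ) / (2 * h)
            assert np.abs(jac - num).max() < 1e-5

    def test_frozen_rotation_drops_rotation_coupling(self, small_model, rng):
        frame = rng.normal(size=18)
        full = pm.cv_gradient(small_model, frame)
        frozen = pm.cv_gradient(small_model, frame, frozen_rotation=True)
        assert full.shape == frozen.shape
        assert np.abs(full - frozen).max() > 1e-10  # rotation term is real


class TestExport:
    def test_roundtrip_forward_equivalence(self, small_model, tmp_path, rng):
        p = tmp_path / "model.ptl"
        pm.export_model(small_model, str(p))
        loaded = pm.load_model(str(p))
        frames = rng.normal(size=(100, 18))
        a = pm.forward(small_model, frames, kind="raw")
        b = pm.forward(loaded, frames, kind="raw")
        assert np.abs(a - b).max() < 1e-7

    def test_schema_checked(self, small_model, tmp_path):
        p = tmp_path / "model.ptl"
        pm.export_model(small_model, str(p))
        blob = bytearray(p.read_bytes())
        # corrupt the schema string
        idx = blob.find(b"ptltsne-model-1")
        blob[idx : idx + 7] = b"unknown"
        p.write_bytes(bytes(blob))
        with pytest.raises(ValueError):
            pm.load_model(str(p))

    def test_truncated_weights_rejected(self, small_model, tmp_path):
        p = tmp_path / "model.ptl"
        pm.export_model(small_model, str(p))
        blob = p.read_bytes()
        p.write_bytes(blob[: len(blob) - 64])
        with pytest.raises(ValueError):
            pm.load_model(str(p))


class TestParametricVsDirect:
    def test_neighbor_agreement_with_direct_tsne(self, rng):
        """The network embedding shares neighborhood structure with the
        classical direct optimization of the same objective, though the
        network trade-off costs some separation."""
        from ptltsne.evaluation import neighbor_preservation
        from ptltsne.tsne_core import direct_embed, squared_distances

        Z = np.vstack(
            [rng.normal(size=(100, 6)) + m for m in (-3.0, 0.0, 3.0)]
        )
        cfg = pm.TrainConfig(epochs=1000, batch_size=300, shuffle_period=10,
                             perplexity=30, seed=3, learning_rate=3e-3)
        model = pm.train(Z, net_cfg=pm.NetworkConfig(hidden_layers=(64, 64)),
                         train_cfg=cfg)
        S_net = pm.forward(model, Z, kind="projections")
        P = joint_affinities(Z, 30.0)
        S_dir = direct_embed(P, n_iter=400, seed=3)
        dist_net = np.sqrt(squared_distances(S_net))
        score = neighbor_preservation(dist_net, S_dir, k=20)
        assert score.mean > 10
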