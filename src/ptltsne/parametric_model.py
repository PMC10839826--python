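"""Parametric embedding network: training, out-of-sample projection, gradients.

A small feed-forward network (default three tanh hidden layers of width 256
without biases, linear 2-D output with biases) maps time-lag projections to
two collective variables.  Training minimizes the t-SNE Kullback-Leibler
divergence batch-wise with the Adam optimizer; affinities P are computed
within each batch and the batch partition is re-drawn every
``shuffle_period`` epochs.

Everything is plain numpy with hand-written backpropagation, so the analytic
Jacobian of the CVs with respect to Cartesian coordinates — including the
dependence of the optimal superposition rotation on the frame, obtained by
first-order perturbation of the Horn quaternion eigenproblem — is available
for biased sampling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import tsne_core
from .timelag import TimeLagBasis, apply_basis
from .trajectory_io import Trajectory, optimal_rotation


@dataclass
class NetworkConfig:
    hidden_layers: tuple[int, ...] = (256, 256, 256)
    activation: str = "tanh"
    hidden_biases: bool = False
    output_dim: int = 2
    output_biases: bool = True

    def __post_init__(self) -> None:
        self.hidden_layers = tuple(int(w) for w in self.hidden_layers)
        if self.output_dim < 1 or any(w < 1 for w in self.hidden_layers):
            raise ValueError("layer widths and output_dim must be >= 1")
        if self.activation != "tanh":
            raise ValueError("only tanh hidden activation is supported")


@dataclass
class TrainConfig:
    epochs: int = 10000
    batch_size: int = 1024
    shuffle_period: int = 10
    perplexity: float = 30.0
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 8:
            raise ValueError("batch_size must be >= 8")
        if self.shuffle_period < 1:
            raise ValueError("shuffle_period must be >= 1")
        if self.optimizer.lower() != "adam":
            raise ValueError("only the Adam optimizer is supported")


@dataclass
class CVModel:
    """Trained collective-variable map: time-lag basis + network weights."""

    basis: TimeLagBasis
    weights: list[np.ndarray]
    net_cfg: NetworkConfig
    train_cfg: TrainConfig | None = None
    loss_history: list[float] = field(default_factory=list)

    @property
    def input_dim(self) -> int:
        return self.weights[0].shape[0]


# ---------------------------------------------------------------------------
# network construction / evaluation

def build_network(cfg: NetworkConfig, input_dim: int, seed: int) -> list[np.ndarray]:
    """Glorot-scaled uniform initialization, reproducible from the seed.

    Returns ``[W1, ..., Wk, W_out, b_out]`` (hidden layers are bias-free by
    default; a hidden bias row is appended to each W when configured).
    """
    rng = np.random.default_rng(seed)
    weights: list[np.ndarray] = []
    fan_in = input_dim
    for width in cfg.hidden_layers:
        lim = np.sqrt(6.0 / (fan_in + width))
        weights.append(rng.uniform(-lim, lim, size=(fan_in, width)))
        if cfg.hidden_biases:
            weights.append(np.zeros(width))
        fan_in = width
    lim = np.sqrt(6.0 / (fan_in + cfg.output_dim))
    weights.append(rng.uniform(-lim, lim, size=(fan_in, cfg.output_dim)))
    if cfg.output_biases:
        weights.append(np.zeros(cfg.output_dim))
    return weights


def _unpack(weights: Sequence[np.ndarray], cfg: NetworkConfig):
    """Split the flat weight list into (hidden W, hidden b, W_out, b_out)."""
    ws, bs = [], []
    i = 0
    for _ in cfg.hidden_layers:
        ws.append(weights[i])
        i += 1
        if cfg.hidden_biases:
            bs.append(weights[i])
            i += 1
        else:
            bs.append(None)
    W_out = weights[i]
    b_out = weights[i + 1] if cfg.output_biases else None
    return ws, bs, W_out, b_out


def network_forward(
    weights: Sequence[np.ndarray], cfg: NetworkConfig, Z: np.ndarray, cache: bool = False
):
    """Evaluate the network; optionally keep activations for backprop."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    ws, bs, W_out, b_out = _unpack(weights, cfg)
    acts = [Z]
    h = Z
    for W, b in zip(ws, bs):
        pre = h @ W
        if b is not None:
            pre = pre + b
        h = np.tanh(pre)
        acts.append(h)
    out = h @ W_out
    if b_out is not None:
        out = out + b_out
    return (out, acts) if cache else out


def network_backprop(
    weights: Sequence[np.ndarray],
    cfg: NetworkConfig,
    acts: list[np.ndarray],
    dOut: np.ndarray,
) -> list[np.ndarray]:
    """Gradients of a scalar loss w.r.t. every weight array, given dL/dOut."""
    ws, bs, W_out, b_out = _unpack(weights, cfg)
    grads_hidden_W = [None] * len(ws)
    grads_hidden_b = [None] * len(ws)
    gW_out = acts[-1].T @ dOut
    gb_out = dOut.sum(axis=0) if b_out is not None else None
    delta = dOut @ W_out.T
    for k in range(len(ws) - 1, -1, -1):
        delta = delta * (1.0 - acts[k + 1] ** 2)  # tanh'
        grads_hidden_W[k] = acts[k].T @ delta
        if bs[k] is not None:
            grads_hidden_b[k] = delta.sum(axis=0)
        delta = delta @ ws[k].T
    grads: list[np.ndarray] = []
    for k in range(len(ws)):
        grads.append(grads_hidden_W[k])
        if bs[k] is not None:
            grads.append(grads_hidden_b[k])
    grads.append(gW_out)
    if b_out is not None:
        grads.append(gb_out)
    return grads


def network_jacobian(
    weights: Sequence[np.ndarray], cfg: NetworkConfig, z: np.ndarray
) -> np.ndarray:
    """Jacobian d(output)/d(input) at a single input point (out_dim x D)."""
    z = np.asarray(z, dtype=float).reshape(1, -1)
    ws, bs, W_out, _ = _unpack(weights, cfg)
    _, acts = network_forward(weights, cfg, z, cache=True)
    J = W_out.T  # (out_dim, width_last)
    for k in range(len(ws) - 1, -1, -1):
        J = (J * (1.0 - acts[k + 1][0] ** 2)) @ ws[k].T
    return J


# ---------------------------------------------------------------------------
# training

_kl_and_grad = tsne_core.kl_gradient


class _Adam:
    def __init__(self, shapes, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, weights, grads):
        self.t += 1
        for w, g, m, v in zip(weights, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            w -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train(
    Z: np.ndarray,
    net_cfg: NetworkConfig | None = None,
    train_cfg: TrainConfig | None = None,
    basis: TimeLagBasis | None = None,
) -> CVModel:
    """Train the parametric embedding on projections ``Z`` (N x D).

    Each epoch runs over a fixed partition of the data into batches;
    within-batch affinities ``P`` (at the configured perplexity, clipped with
    a warning when a batch is too small) are recomputed whenever the
    partition is re-drawn, i.e. every ``shuffle_period`` epochs.
    ``loss_history`` records the per-epoch sum of batch KL losses.
    """
    net_cfg = net_cfg or NetworkConfig()
    train_cfg = train_cfg or TrainConfig()
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    n, d = Z.shape
    if n < 3 * train_cfg.perplexity:
        warnings.warn("fewer than 3x perplexity samples; calibration may clip")
    rng = np.random.default_rng(train_cfg.seed)
    weights = build_network(net_cfg, d, train_cfg.seed)
    opt = _Adam([w.shape for w in weights], train_cfg.learning_rate)
    n_batches = max(1, int(np.ceil(n / train_cfg.batch_size)))
    history: list[float] = []
    batches: list[np.ndarray] = []
    P_batches: list[np.ndarray] = []
    for epoch in range(train_cfg.epochs):
        if epoch % train_cfg.shuffle_period == 0:
            perm = rng.permutation(n)
            batches = np.array_split(perm, n_batches)
            P_batches = []
            for idx in batches:
                if len(idx) - 1 <= train_cfg.perplexity:
                    warnings.warn(
                        f"batch of {len(idx)} smaller than perplexity bound; clipped"
                    )
                P_batches.append(
                    tsne_core.joint_affinities(Z[idx], train_cfg.perplexity).P
                )
        epoch_loss = 0.0
        for idx, P in zip(batches, P_batches):
            S, acts = network_forward(weights, net_cfg, Z[idx], cache=True)
            loss, dS = _kl_and_grad(P, S)
            grads = network_backprop(weights, net_cfg, acts, dS)
            opt.step(weights, grads)
            epoch_loss += loss
        history.append(epoch_loss)
    return CVModel(
        basis=basis, weights=weights, net_cfg=net_cfg, train_cfg=train_cfg,
        loss_history=history,
    )


def fit_pipeline(
    traj: Trajectory,
    ref,
    lag: int,
    net_cfg: NetworkConfig | None = None,
    train_cfg: TrainConfig | None = None,
    n_components: int | None = None,
) -> CVModel:
    """Full training pipeline on raw coordinates.

    Superposes the trajectory onto the reference, applies the global 0-1
    scaling, builds the time-lag basis at the given lag, and trains the
    embedding network on the projections.
    """
    from .timelag import build_basis
    from .trajectory_io import center_scale, kabsch_superpose

    sup = kabsch_superpose(traj, ref)
    scaled = center_scale(sup, ref)
    basis = build_basis(scaled, lag=lag, n_components=n_components)
    Z = apply_basis(basis, sup.coords)
    return train(Z, net_cfg=net_cfg, train_cfg=train_cfg, basis=basis)


# ---------------------------------------------------------------------------
# evaluation on raw frames

def _superpose_frame(frame: np.ndarray, basis: TimeLagBasis) -> np.ndarray:
    fr = frame.reshape(-1, 3)
    ref = basis.ref_coords.reshape(-1, 3)
    R, pc, qc = optimal_rotation(fr, ref)
    return ((fr - pc) @ R + qc).reshape(-1)


def forward(model: CVModel, X: np.ndarray | Trajectory, kind: str = "auto") -> np.ndarray:
    """CV values for raw coordinates (full superpose-scale-basis-net path)
    or for precomputed projections (network only).

    ``kind`` is ``"raw"``, ``"projections"`` or ``"auto"`` (resolved by the
    input width; raw wins if both match).
    """
    arr = X.coords if isinstance(X, Trajectory) else np.asarray(X, dtype=float)
    single = arr.ndim == 1
    arr2 = np.atleast_2d(arr)
    d_proj = model.input_dim
    if kind == "auto":
        if model.basis is not None and arr2.shape[1] == model.basis.linear.shape[0]:
            kind = "raw"
        elif arr2.shape[1] == d_proj:
            kind = "projections"
        else:
            raise ValueError(
                f"input width {arr2.shape[1]} matches neither raw coordinates "
                f"nor projections"
            )
    if kind == "raw":
        if model.basis is None:
            raise ValueError("model has no basis; only projections accepted")
        sup = np.stack([_superpose_frame(f, model.basis) for f in arr2])
        Z = apply_basis(model.basis, sup)
    else:
        if arr2.shape[1] != d_proj:
            raise ValueError("projection width mismatch")
        Z = arr2
    out = network_forward(model.weights, model.net_cfg, Z)
    return out[0] if single else out


# ---------------------------------------------------------------------------
# analytic CV gradient through the rigid-body fit

def _horn_matrix(M: np.ndarray) -> np.ndarray:
    """Horn's symmetric 4x4 quaternion matrix built from the 3x3 correlation."""
    return np.array(
        [
            [M[0, 0] + M[1, 1] + M[2, 2], M[1, 2] - M[2, 1], M[2, 0] - M[0, 2], M[0, 1] - M[1, 0]],
            [M[1, 2] - M[2, 1], M[0, 0] - M[1, 1] - M[2, 2], M[0, 1] + M[1, 0], M[2, 0] + M[0, 2]],
            [M[2, 0] - M[0, 2], M[0, 1] + M[1, 0], M[1, 1] - M[0, 0] - M[2, 2], M[1, 2] + M[2, 1]],
            [M[0, 1] - M[1, 0], M[2, 0] + M[0, 2], M[1, 2] + M[2, 1], M[2, 2] - M[0, 0] - M[1, 1]],
        ]
    )


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Column-vector rotation matrix of a unit quaternion (w, x, y, z)."""
    w, x, y, z = q
    return np.array(
        [
            [w * w + x * x - y * y - z * z, 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), w * w - x * x + y * y - z * z, 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), w * w - x * x - y * y + z * z],
        ]
    )


def _dmatrix_dquat(q: np.ndarray) -> np.ndarray:
    """(4, 3, 3) array of d(rotation matrix)/d(q_e), valid for dq orthogonal
    to the unit quaternion q (first-order perturbations keep |q| = 1)."""
    w, x, y, z = q
    dw = np.array([[2 * w, -2 * z, 2 * y], [2 * z, 2 * w, -2 * x], [-2 * y, 2 * x, 2 * w]])
    dx = np.array([[2 * x, 2 * y, 2 * z], [2 * y, -2 * x, -2 * w], [2 * z, 2 * w, -2 * x]])
    dy = np.array([[-2 * y, 2 * x, 2 * w], [2 * x, 2 * y, 2 * z], [-2 * w, 2 * z, -2 * y]])
    dz = np.array([[-2 * z, -2 * w, 2 * x], [2 * w, -2 * z, 2 * y], [2 * x, 2 * y, 2 * z]])
    return np.stack([dw, dx, dy, dz])


def cv_gradient(
    model: CVModel, frame: np.ndarray, frozen_rotation: bool = False
) -> np.ndarray:
    """Analytic Jacobian ``ds/dx`` (out_dim x M) of the full composed map.

    The chain runs network <- basis affine <- global scaling <- superposition.
    The optimal rotation's dependence on the frame is differentiated exactly:
    the fit quaternion is the principal eigenvector of Horn's 4x4 matrix
    ``N(M)`` with ``M`` the weighted frame/reference correlation, so
    ``dq = (lambda I - N)^+ dN q``.  With ``frozen_rotation`` the rotation is
    treated as locally constant (only centering and rotation of the gradient
    remain), matching engines that fit frames externally.
    """
    if model.basis is None:
        raise ValueError("cv_gradient requires a model with a basis")
    basis = model.basis
    fr = np.asarray(frame, dtype=float).reshape(-1, 3)
    ref = basis.ref_coords.reshape(-1, 3)
    A = fr.shape[0]
    w = np.full(A, 1.0 / A)
    pc = w @ fr
    qc = w @ ref
    Pc = fr - pc
    Qc = ref - qc
    M = (Pc * w[:, None]).T @ Qc
    N = _horn_matrix(M)
    evals, evecs = np.linalg.eigh(N)
    lam = evals[-1]
    q = evecs[:, -1]
    Omega = _quat_to_matrix(q)  # column convention: maps frame onto reference
    R = Omega.T  # row convention: superposed = Pc @ R + qc
    sup = (Pc @ R + qc).reshape(-1)
    if not np.all(np.isfinite(sup)):
        raise FloatingPointError("non-finite coordinates after superposition")
    z = apply_basis(basis, sup)
    J_net = network_jacobian(model.weights, model.net_cfg, z)  # (out, D)
    if not np.all(np.isfinite(J_net)):
        raise FloatingPointError("non-finite network Jacobian")
    G_flat = J_net @ basis.linear.T  # (out, M): d s / d sup
    out_dim = G_flat.shape[0]
    jac = np.empty((out_dim, 3 * A))
    if not frozen_rotation:
        pinv = np.linalg.pinv(lam * np.eye(4) - N, rcond=1e-10)
        dRdq = _dmatrix_dquat(q)  # dOmega/dq; dR = transpose in last two axes
    for o in range(out_dim):
        G = G_flat[o].reshape(A, 3)
        GR = G @ R.T
        term = GR - w[:, None] * GR.sum(axis=0)
        if not frozen_rotation:
            # contraction coefficients: Acorr : dR
            Acorr = Pc.T @ G  # (3, 3); d s = sum_ab Acorr[a,b] dR[a,b]
            v = np.array([np.sum(Acorr * dRdq[e].T) for e in range(4)])
            u = pinv @ v  # pinv is symmetric
            # B[a,b] = u^T (dN/dM_ab) q, via linearity of Horn's matrix
            B = np.empty((3, 3))
            for a in range(3):
                for b in range(3):
                    E = np.zeros((3, 3))
                    E[a, b] = 1.0
                    B[a, b] = u @ _horn_matrix(E) @ q
            term = term + w[:, None] * (Qc @ B.T)
        jac[o] = term.reshape(-1)
    return jac


# ---------------------------------------------------------------------------
# serialization

def export_model(model: CVModel, path: str) -> None:
    """Write the model as a JSON header plus little-endian float64 blocks."""
    arrays: dict[str, np.ndarray] = {}
    if model.basis is not None:
        for key in ("ref_coords", "mean", "whitening_map", "lag_map",
                    "eigenvalues", "eigenvalue_signs"):
            arrays[f"basis.{key}"] = getattr(model.basis, key)
    for i, wt in enumerate(model.weights):
        arrays[f"weight.{i}"] = wt
    header = {
        "schema": "ptltsne-model-1",
        "net_cfg": {
            "hidden_layers": list(model.net_cfg.hidden_layers),
            "activation": model.net_cfg.activation,
            "hidden_biases": model.net_cfg.hidden_biases,
            "output_dim": model.net_cfg.output_dim,
            "output_biases": model.net_cfg.output_biases,
        },
        "basis": None
        if model.basis is None
        else {
            "lag": int(model.basis.lag),
            "offset": float(model.basis.offset),
            "scale": float(model.basis.scale),
        },
        "n_weights": len(model.weights),
        "loss_history": [float(v) for v in model.loss_history],
        "shapes": {k: list(v.shape) for k, v in arrays.items()},
    }
    head = json.dumps(header).encode()
    with open(path, "wb") as fh:
        fh.write(len(head).to_bytes(8, "little"))
        fh.write(head)
        for v in arrays.values():
            fh.write(np.ascontiguousarray(v, dtype="<f8").tobytes())


def load_model(path: str) -> CVModel:
    with open(path, "rb") as fh:
        n = int.from_bytes(fh.read(8), "little")
        header = json.loads(fh.read(n).decode())
        if header.get("schema") != "ptltsne-model-1":
            raise ValueError(f"unknown model schema in {path}")
        arrays = {}
        for key, shape in header["shapes"].items():
            count = int(np.prod(shape)) if shape else 1
            buf = fh.read(count * 8)
            if len(buf) != count * 8:
                raise ValueError(f"truncated model file {path}")
            arrays[key] = np.frombuffer(buf, dtype="<f8").reshape(shape).copy()
    net_cfg = NetworkConfig(
        hidden_layers=tuple(header["net_cfg"]["hidden_layers"]),
        activation=header["net_cfg"]["activation"],
        hidden_biases=header["net_cfg"]["hidden_biases"],
        output_dim=header["net_cfg"]["output_dim"],
        output_biases=header["net_cfg"]["output_biases"],
    )
    basis = None
    if header["basis"] is not None:
        basis = TimeLagBasis(
            ref_coords=arrays["basis.ref_coords"],
            offset=header["basis"]["offset"],
            scale=header["basis"]["scale"],
            mean=arrays["basis.mean"],
            whitening_map=arrays["basis.whitening_map"],
            lag_map=arrays["basis.lag_map"],
            lag=header["basis"]["lag"],
            eigenvalues=arrays["basis.eigenvalues"],
            eigenvalue_signs=arrays["basis.eigenvalue_signs"],
        )
    weights = [arrays[f"weight.{i}"] for i in range(header["n_weights"])]
    return CVModel(
        basis=basis,
        weights=weights,
        net_cfg=net_cfg,
        loss_history=list(header.get("loss_history", [])),
    )
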