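# ptltsne — parametric time-lagged t-SNE collective variables

`ptltsne` learns low-dimensional, differentiable collective variables (CVs)
from molecular trajectories and lets you exercise them end to end: a
time-lagged whitened representation emphasizes *slow* motions over intense
but fast ones, a parametric t-SNE network maps coordinates to two CVs with
analytic gradients suitable for biased sampling, and a desk-scale Langevin /
well-tempered-metadynamics sandbox plus free-energy and embedding-quality
tools close the loop — all without any external simulation engine or data.

It is aimed at people designing machine-learned CVs for enhanced sampling
(metadynamics, parallel-tempering metadynamics) who want a compact, fully
testable implementation of the method and its analysis chain.

## The method

Given a trajectory of `N` frames with `M = 3A` Cartesian coordinates:

1. **Superposition and scaling.** Frames are fitted to a reference structure
   (Kabsch), centered on it, and mapped into `[0, 1]` by one global affine
   transform.
2. **Time-lag expansion** (AMUSE-style). Coordinates are whitened by
   projection on covariance eigenvectors divided by `sqrt(eigenvalue)`; the
   lag-`τ` covariance `C` of the whitened series is symmetrized,
   `C_sym = (C + Cᵀ)/2`, and its eigenvectors are expanded by
   `sqrt(|λ|)`.  Slowly decorrelating modes (|λ| near 1) dominate the
   projected geometry.
3. **Parametric t-SNE.** High-dimensional proximities

   `p_{j|i} ∝ exp(−‖x_i − x_j‖² / 2σ_i²)`, `p_ij = (p_{j|i} + p_{i|j}) / 2N`,

   with bandwidths `σ_i` calibrated to a target perplexity, are matched to
   Student-t proximities of the 2-D embedding,
   `q_ij ∝ (1 + ‖s_i − s_j‖²)^{-1}`, by minimizing `KL(P‖Q)`.  Instead of
   optimizing the points `s` directly, a feed-forward network
   (default 3 × 256 tanh units without biases, linear 2-D output with
   biases) computes `s = f(x)`; Adam minimizes the KL loss batch-wise.
4. **Biasing.** Because `f` is differentiable through the whole chain —
   including the dependence of the optimal superposition rotation on the
   frame — the analytic Jacobian `ds/dx` drives well-tempered metadynamics:
   Gaussian hills with heights `w₀ exp(−V/k_B ΔT)`, `ΔT = (γ−1)T`, are
   summed into a bias whose scaled negative image, `F = −γ/(γ−1) V`,
   estimates the free-energy surface.  Umbrella-sampling reweighting with a
   time-dependent bias offset `c(t)` recovers free energies along any new CV.

## Worked example

Generate a synthetic two-state trajectory (a slow double-well coordinate
hidden under dominant fast noise, lifted to 10 pseudo-atoms with random
rigid-body motion), train the CVs, and check that they expose the planted
states:

```python
import numpy as np
from ptltsne import (generate_preset, kabsch_superpose, center_scale,
                     build_basis, apply_basis, train, forward,
                     TrainConfig, slow_mode_recovery)

traj, ref, truth = generate_preset("twostate-small", seed=1)
sup = kabsch_superpose(traj, ref)
basis = build_basis(center_scale(sup, ref), lag=10)
Z = apply_basis(basis, sup.coords)
model = train(Z[::4], train_cfg=TrainConfig(epochs=300, batch_size=512,
                                            perplexity=30, seed=1),
              basis=basis)
S = forward(model, Z, kind="projections")     # 2-D CVs for all 5000 frames
r, acc = slow_mode_recovery(S, truth)
print(f"|r| = {r:.3f}  state accuracy = {acc:.3f}")
print(f"top |eigenvalue| = {abs(basis.eigenvalues[0]):.3f}")
```

Output:

```
|r| = 0.908  state accuracy = 0.976
top |eigenvalue| = 0.761
```

`|r|` is the correlation between the best CV axis and the hidden slow
coordinate; the accuracy is the best single-threshold classification of the
two metastable states from the CVs.  The same pipeline with `lag=0` drops
to ≈ 0.68 accuracy — the time lag is what rescues the slow mode from the
high-variance fast noise (the lag-0 top eigenvalue has no slow content).

The same model can bias the toy sampler
(`run_metadynamics(..., cv=ModelCV(model), ...)`), and the CLI mirrors the
library: `ptltsne synth | fit | embed | toy-sim | eval-neighbors`.

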