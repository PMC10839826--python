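# Methods

This note records the models implemented in `ptltsne`, the defaults and why
they were chosen, the numerical conventions, and what the synthetic
benchmarks do and do not demonstrate.

## Coordinate preparation

Frames are superposed on a reference structure by weighted Kabsch fitting
(SVD of the weighted correlation matrix, determinant-corrected to a proper
rotation; uniform weights by default, optional per-atom weights).  The
superposed coordinates are centered on the reference and mapped into
`[0, 1]` by **one global offset and scale** over all entries.  A
per-coordinate min-max mode exists behind a flag, but the global map is the
default because per-coordinate scaling distorts geometry anisotropically and
corrupts the RMSD-like distance structure everything downstream relies on.
The offset/scale pair is stored with the data and frozen: out-of-sample
frames are transformed with the training constants, never rescaled, so the
CV function is well defined outside the training set.

Internal units are nm (inputs in Å are converted on read by format
convention); energies kJ/mol, temperatures K, times ps,
`k_B = 0.008314462618 kJ/(mol K)`.  Lag is always counted in frames;
timestamps are carried but not used by the lag machinery.

## Time-lag expansion

The scaled coordinates are whitened: projection on the eigenvectors of the
(1/N-normalized) covariance, each divided by the root of its eigenvalue.
Components with eigenvalue below `1e-10 ×` the largest are dropped (the
superposition itself removes six rigid-body directions, which would
otherwise whiten pure noise).  The covariance of the whitened series with
its copy shifted by `lag` frames is estimated over the `N − lag` available
pairs, with one global mean removed beforehand (stationarity assumption; no
separate re-centering of the shifted copies — choosing otherwise changes
results at the `1/N` level).  The symmetrized matrix `C_sym = (C + Cᵀ)/2`
is exactly symmetric by construction, so its eigendecomposition is real.

Eigenvalues of `C_sym` can be negative (anticorrelated modes).  Eigenvectors
are sorted by `|λ|` descending and expanded by `sqrt(|λ|)`, with the signs
recorded separately; this keeps the map real and matches AMUSE practice.
The whole pipeline — centering, scaling, whitening, expansion — collapses
into a single affine map stored in the basis, which makes single-frame and
batch evaluation identical and the Jacobian a constant matrix.

At lag 0 the construction degenerates gracefully: `C_sym` is the identity
up to round-off, all `|λ| ≈ 1`, and the projections reproduce whitened
coordinates up to an orthogonal transform.  This lag-0 limit serves as the
"plain t-SNE" comparator throughout.

## Parametric t-SNE

Bandwidths `σ_i` are calibrated by bisection on `log σ` (bracket expansion
by factors of 2, tolerance `1e-5` in perplexity, 100 iterations max; a
vectorized all-rows variant performs the same search and is used during
training).  Perplexity is `2^H` with `H` in bits; entropy of a Gibbs
distribution is non-decreasing in `σ`, so bisection is safe.  Equidistant
rows have σ-independent entropy and return immediately.  `p` and `q` are
floored at `1e-12` inside logarithms only.  Duplicate points are legal
(zero distances give uniform conditionals); an all-identical point cloud is
rejected.

The network defaults follow the method's standard configuration: three
hidden tanh layers of width 256 without biases and a linear 2-D output with
biases; 10,000 epochs of Adam with batch size 1024, shuffle period 10,
perplexity 30.  Unstated knobs are package choices: Glorot-uniform
initialization from the run seed, learning rate `1e-3` (exposed as
`--lr`), no early exaggeration.  Affinities `P` are computed **within each
batch**; the batch partition is fixed and re-drawn every `shuffle_period`
epochs — the only reading under which a "shuffle period" exists.  Since `P`
depends only on the fixed input projections, each partition's affinities
are computed once when it is drawn.  `loss_history` records the per-epoch
*sum* of batch KL losses, so histories are comparable across batch sizes
only at fixed batch count.  Training is single-threaded-deterministic given
the seed.

### CV gradients

Biased sampling needs `ds/dx` through the full composition
superpose → scale → basis → network.  The network and affine parts are
chain-rule matrices; the subtle term is the optimal rotation's dependence on
the frame.  The rotation is expressed through the Horn quaternion
formulation: the fit quaternion is the principal eigenvector of a symmetric
4×4 matrix `N(M)` built linearly from the 3×3 frame/reference correlation
`M`.  First-order eigenvector perturbation gives
`dq = (λ_max I − N)⁺ dN q`, and the remaining factors (`dM/dx`, `dR/dq`)
are closed-form.  The implementation contracts these into three rank-1-ish
terms per CV, so the exact Jacobian costs little more than a forward pass.
A `frozen_rotation` mode treats the rotation as locally constant for
engines that fit frames externally.  The analytic Jacobian matches central
finite differences to better than `1e-9` in practice; the acceptance suite
asserts `1e-5` at step `1e-5`.

Degenerate geometries (collinear reference, near-degenerate top eigenvalue
of `N`) are rejected or will show as finite-difference disagreement; they do
not occur for generic molecular frames.

## Toy sampler

BAOAB-splitting Langevin dynamics on analytic potentials (1-D double well
`U = B(x²−1)²`, a 2-D triple well, and a double well embedded along a random
direction of a higher-dimensional harmonic landscape).  Metadynamics follows
the PLUMED conventions: hill value `h exp(−Σ (s−c)²/2σ²)` (σ in the
`2σ²` denominator), well-tempered heights `w₀ exp(−V/k_B ΔT)` with
`ΔT = (γ−1)T`; defaults `w₀ = 0.5 kJ/mol`, `γ = 8`, deposition every 500
steps (1 ps at dt = 2 fs).  Replica exchange attempts neighbor swaps of
alternating parity; the Metropolis exponent includes both replicas' own
bias potentials (per-replica biases, the standard parallel-tempering
metadynamics choice), and velocities are rescaled by `sqrt(T_new/T_old)` on
exchange.  HILLS and COLVAR files are written/read in the PLUMED text
dialect so external outputs can be analyzed with the same tools.

The benchmark condition for the double well is 6 k_BT barrier at 300 K,
friction 5 ps⁻¹, mass 1, dt 0.002 ps, 2×10⁵ steps, hill width 0.3 (≈ 1/3 of
the well separation, per the usual width-relative-to-CV-range
recommendation).  Friction and run length were fixed by pilot calibration
so that unbiased dynamics crosses the barrier about once per run — the
regime in which acceleration is meaningful to measure; the biased runs then
show a ≈ 40× transition speed-up.

## Free-energy tools

`F = −γ/(γ−1) V_bias` in well-tempered mode (`−V` otherwise), anchored to
minimum 0.  Marginalization converts to probability (`exp(−F/k_BT)` with
max-shifted log-sum-exp), Riemann-sums one axis on the grid (default 100
bins per axis), and converts back.  Reweighting uses per-frame weights
`exp(β(V(s_t, t) − c(t)))` with

`c(t) = β⁻¹ ln [ ∫ exp(βγV/(γ−1)) ds / ∫ exp(βV/(γ−1)) ds ]`

evaluated by grid quadrature; the bias grid is accumulated hill by hill, so
the cost is (hills × grid), and `c(t)` is updated at each deposition.  This
expression reduces correctly to the static-umbrella constant as `γ → ∞`,
which the tests verify against an exactly known biased density.  `c(t)` is
monotone non-decreasing up to grid-quadrature noise (observed dips
< 0.01 kJ/mol against a ≈ 26 kJ/mol total rise).  Block averages (default
ten equally sized time windows) give the mean ± SEM of weighted state
populations.

## Synthetic data

The generator emulates the statistical problem the time lag solves, not any
particular molecule: a **slow** coordinate `z` under overdamped
Euler–Maruyama dynamics on `U(z) = B(z²−1)²` (units of kT; barrier `B`,
mobility 0.02/frame, 20 substeps per frame — halving the substep changes
transition counts by < 10%), plus **fast** independent Ornstein–Uhlenbeck
coordinates with relaxation 1.5 frames and stationary σ = 3, so the fast
block dominates the variance ≈ 90:1.  With `B = 0` the slow potential
degenerates to a unit harmonic well (free OU).  Parameters violating a
20× slow/fast timescale separation (Kramers estimate for the slow
lifetime) are rejected.  State labels are the sign of `z`.

The lift embeds `(z, fast)` into `3A` coordinates: a fixed random scaffold
(σ = 1 nm) deformed through a fixed random linear mixing at amplitude
0.1 nm, optionally warped by mild `sin`/quadratic terms, then per-frame
uniform random rotations and Gaussian translations (σ = 0.5 nm) that
superposition must remove.  Shipped presets: `twostate-small`
(N = 5000, 10 fast modes, 10 atoms, barrier 4 kT — chosen so several
barrier crossings occur within the preset length) and `twostate-full`
(N = 50,000, barrier 6 kT, ≈ 10 crossings).

**What passing these benchmarks shows** is that the pipeline recovers a
planted slow mode hidden under dominant fast variance and rigid-body
noise, and that its gradients drive a correct sampler.  **What it does not
show**: real proteins have many coupled slow modes, anharmonic fast
motions correlated with slow ones, and force-field specifics; none of that
is emulated, so quantitative transfer to molecular systems is not implied.

## Benchmark protocols and sizes

The recovery benchmark trains on every 4th frame of `twostate-small`
(1250 training frames, batch 512, 300 epochs, perplexity 30, lag 10 ≈ the
slow within-well relaxation /5) and classifies all 5000 frames through the
parametric out-of-sample map — deliberately exercising the property that
non-parametric t-SNE lacks.  Median best-threshold accuracy over five
seeds is ≈ 0.98 for the time-lagged pipeline vs ≈ 0.69 at lag 0.  The
comparator study for neighborhood preservation (mean common top-20
neighbors against the pairwise-RMSD ordering, 250 frames) reproduces the
expected ordering: plain t-SNE ≥ time-lagged t-SNE, with the parametric
variant within 20% of the non-parametric time-lagged embedding — the
network trades some separation quality for differentiability and
out-of-sample evaluation.

## Known limitations

- Full-dataset (non-batched) affinities are quadratic in N; no Barnes–Hut
  or interpolation acceleration is provided.
- One symmetrized lagged covariance only; no multi-lag Koopman/VAC
  estimators.
- The model artifact is the package's own JSON + float64-block format; no
  traced computational-graph export.
- The toy sampler is not an MD engine: no constraints, barostats, or
  periodic boundaries.
- Negative `C_sym` eigenvalues are kept by magnitude; with strongly
  anticorrelated inputs (period-2 artifacts) the leading "slow" component
  can be an alternating mode — inspect recorded eigenvalue signs.
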