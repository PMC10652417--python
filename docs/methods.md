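# Methods

This note documents the model, the measurement protocols, and the
numerical choices the package makes where the mathematics leaves room.
Everything quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted from memory.

## Model

The network is a one-dimensional continuous attractor on the ring
(−π, π] — the canonical abstraction of head-direction circuits — with
divisively normalised quadratic rate transfer and Gaussian excitatory
coupling, augmented by two fields implementing NMDAR-based short-term
postsynaptic plasticity (STPP):

- `Q(x, t)` — the proportion of receptors in the bound-but-blocked
  (primed) state. Bounded in [0, 1] by construction: its sources vanish
  at `Q = 1` and its sinks at `Q = 0`.
- `S(x, t)` — the transient gain from primed receptors opening; the
  network drive is `(1 + S) I_tot`. Non-negative for non-negative
  initial conditions.

Assumptions inherited from the model class: the dynamics are
deterministic (no noise term), rates are population averages (no
spikes), the firing rate serves as a proxy for the average membrane
potential in the magnesium-removal function `f_S`, and the stimulus
shares the Gaussian footprint of the recurrent coupling. The model is
the re-scaled formulation in which the number of grid nodes is a
discretisation choice, not a physiological parameter.

### Parameters (defaults)

| name | default | units | role |
| --- | --- | --- | --- |
| `tau_s` | 10 | ms | neuronal (synaptic input) time constant |
| `tau_1` | 50 | ms | decay of the gain `S` (NMDAR current time scale) |
| `tau_2` | 500 | ms | decay of the primed pool `Q` (latent storage) |
| `a` | 0.5 | rad | excitatory interaction range |
| `k` | 0.5 | — | divisive inhibition strength (`k < 1`: bump exists) |
| `alpha` | 0 | — | opening rate of primed receptors |
| `beta` | 0 | — | priming rate into the bound-but-blocked state |
| `r0`, `sigma_S` | 6, 2 | rate units | location/scale of the normal CDF `f_S` |
| `mu_Q`, `sigma_Q` | 0.25, 0.5 | log-input units | location/scale of the log-normal `f_Q` |

`alpha` and `beta` are the experimental dials; all sweeps cover
[0, 0.2]. Angle/time units are radians and milliseconds throughout;
conversions to deg/s (1 rad/ms = 180000/π deg/s) happen only in
reports.

Two small definitional choices: `f_Q` is defined as 0 for non-positive
total input (the log-normal density is undefined there, and
sub-threshold input cannot prime receptors), and the Heaviside gate in
the rate function applies to the numerator only — nodes with negative
`u` still contribute `u²` to the divisive normalisation, as the
transfer function is written.

## Discretisation and integration

- Uniform ring grid, default `n_points = 200` (`dx = 2π/200`), chosen
  so the intrinsic-speed intervention's 2π/200 shift is exactly one
  node. Doubling the grid changes the stability eigenvalue by < 1%
  (tested).
- All ring integrals are dx-weighted Riemann sums; the lateral
  interaction is a circulant convolution evaluated by FFT, which equals
  the dense matrix–vector product to ~1e−16 (tested).
- Time stepping is explicit Euler with `dt = 0.1 ms` (= τ_s/100) by
  default; RK4 is available. A guard rejects `dt > τ_s/10`. The suite
  verifies first-order self-convergence for Euler and the expected
  large accuracy gap to RK4.
- Integration is vectorised over leading batch axes, so a parameter
  sweep (per-row `alpha`, `beta`, `v_ext`, `A`) advances as one array.

## Tracking protocols

- **Warm start.** Every protocol first relaxes the network under a
  static stimulus until the scaled residual
  `max(|du|·τ_s, |dS|·τ_1, |dQ|·τ_2)` falls below 1e−7 (cap 12 s of
  model time). The slow pool `Q` (τ₂ = 500 ms) sets this time scale.
- **Bump centre.** Centre of mass anchored at the peak node, with node
  offsets computed in index arithmetic so that rotating the field by m
  nodes rotates the centre by exactly m·dx — the ±π boundary then wraps
  identically for every rotation.
- **Displacement.** Bump and stimulus angles are unwrapped by
  minimal-angle increments before subtraction (sampling of 1 ms keeps
  per-sample motion far below π/2), so `s(t)` is continuous across the
  ring seam. Sign convention: `s·v_ext > 0` is anticipation.
- **Steadiness.** Tracking runs last 6 s; a run is steady when
  `|s(t) − s(t − W)| < 1e−4 rad` throughout the final window
  `W = 500 ms` (the dynamics settle by roughly 1.2 s in the strong
  plasticity regime, so the horizon is comfortable). `τ_ant` is the
  final-window mean of `s` divided by `v_ext`.
- **Anticipation interval.** Steady `s(v)` changes sign twice in
  anticipatory regimes (a tiny delay persists at very low speeds); the
  interval endpoints are located by linear interpolation between scan
  points. The zero-lag bisection targets the upper
  (anticipation→delay) crossing by default; the lower crossing is
  exposed as an option.
- **Intrinsic speed.** Settle under a static stimulus of magnitude 3.0,
  remove it, roll `u` one 2π/200 step forward every τ_s for 100·τ_s,
  release, and fit the drift of the unwrapped centre over successive
  1 s windows until the slope changes by < 1e−6 rad/ms (cap 10 s).
  Speeds ≤ 1e−5 rad/ms (≈ 0.57°/s) count as static. Only `u` is
  shifted; co-shifting `S` and `Q` is exposed as an option (they relax
  during the 1 s intervention, so the released speed is insensitive to
  it). Collapse of the bump is reported distinctly from staticness.
- **Confluence point.** Below a regime-specific velocity a weaker
  stimulus yields *greater* anticipation; above it the ordering
  reverses. The confluence is located as the descending zero crossing
  of the weakest-minus-strongest displacement difference; minimising
  raw spread instead would latch onto the low-velocity delay zone where
  all curves hug zero. Its velocity matches the measured intrinsic
  speed within one velocity-grid step (tested).

## Translational stability analysis

The input-free stationary bump is found by integrating the dynamics
while symmetrising the fields about x = 0 every few steps; the
symmetric subspace is invariant, and the (possibly unstable)
translation direction is projected out, so the relaxation converges to
the static solution even deep in the moving phase (residual ≤ 1e−10 on
every raw time derivative).

The 3×3 displacement-mode matrix is built numerically: perturbation
modes `du₀/dx`, `(x − z)S₀`, `(x − z)Q₀` are applied with central
differences and the exact right-hand side, and responses are projected
back onto the modes with dx-weighted inner products normalised by each
mode's self-inner product. The perturbation amplitude is validated by a
two-point Richardson check (the matrix is recomputed at half the
amplitude; their difference is reported as `fd_error`). Two entries are
structural zeros — the `u` equation never reads `Q` and the `Q`
equation never reads `S` — and are asserted to vanish numerically
(≤ 1e−8) before being zeroed. Without plasticity the S and Q modes do
not exist (`S₀ = Q₀ = 0`); their diagonal entries are set to the bare
leak rates so the spectrum is led by the translation mode.

Classification uses a tolerance: *moving* means `λ̃ > 1e−7`. The plain
network's translation mode is neutral (a continuous attractor), so its
eigenvalue sits within ~1e−8 of zero and a strict sign test would be
noise.

**What λ̃ measures.** The displacement-mode reduction is a *mobility*
indicator, not strict linear stability. Cross-checks against the full
discretised Jacobian restricted to antisymmetric perturbations show a
band of regimes (e.g. `alpha = 0.02, beta = 0.1`) where the static bump
is locally stable to infinitesimal perturbations yet a finite
positional kick — exactly what the shift-and-release protocol applies —
sustains steady intrinsic motion; genuine linear instability appears
only at stronger plasticity (e.g. `alpha = beta = 0.2`). λ̃ > 0 tracks
the kicked (intrinsic-motion) behaviour: on the coarse sweep grid the
moving-phase cells coincide with the cells of measured intrinsic
motion. The suite therefore checks the two implications that hold —
linear instability implies λ̃ > 0, and a static classification implies
no linear instability — rather than a sign equality that the bistable
band would violate.

## Problem sizes

Desk-scale defaults keep every analysis on one CPU in minutes: velocity
scans use the full published grid (41 velocities, batched into a single
integration), while (α, β) maps default to a 6×6 sub-grid of [0, 0.2]²
with a thinned velocity list (step 5e−4 rad/ms) — the full 51×51 maps
are a long-running option via `SweepSpec()`. Robustness of the
intrinsic-speed maps to the latent time constant can be probed with the
`tau_2` option of the phase-map protocol (300–700 ms leaves the
static/moving topology unchanged on the coarse grid).

## What the simulations do and do not show

All inputs are self-generated: the "data" are simulations of the model
itself at published parameter values, so passing tests establish
internal reproducibility of the model's phenomenology (tracking
regimes, anticipation bands, intrinsic motion, phase structure) — not
agreement with physiological recordings. Real HD-cell populations are
noisy, heterogeneous across cells, and show anticipatory times with
complex velocity dependence; the model is deterministic and
homogeneous, and its anticipatory time varies with stimulus speed
(rising then falling). The 0–30 ms range of maximal anticipatory times
is an order-of-magnitude comparison with thalamic recordings, not a
fit.

## Known limitations

- Explicit Euler is first-order; halving `dt` moves the steady
  anticipatory time of the canonical regime by under 0.1%
  (spot-checked), but very stiff parameter choices (`beta·max f_Q`
  approaching 2/dt) would need a smaller step.
- The steadiness detector is a windowed drift test; quasi-periodic
  tracking states (not observed in the scanned ranges) would be flagged
  unsteady rather than characterised.
- The stationary solver assumes a mirror-symmetric bump; it cannot find
  asymmetric fixed points (none are expected for this coupling).
- The 3×3 mode truncation ignores shape deformations beyond the three
  displacement modes; its eigenvalue should be read as a mobility
  index (see above), and only its sign and pattern are used.
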