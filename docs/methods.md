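# Methods

This note records the model, its parameters and defaults, the numerical
choices, and the known limitations of `neurogrn`.  It documents what the
code computes; every number quoted here is produced by the test suite or
the scripts in this repository.

## Model

The state is a 2n-vector of molecule counts: mRNAs `x` and TF proteins
`y` for n genes (default n = 4).  Deterministic kinetics are linear
except for transcription control:

    dx_i/dt = m_i f_i(y) − δ_i x_i
    dy_i/dt = s_i x_i − γ_i y_i        (+ u(t) for the light-coupled gene)

with maximum transcription rate `m_i` (molecules/day), mRNA decay `δ_i`
(/day), translation `s_i` (/day), and protein decay `γ_i` (/day).

**Regulatory function.**  Each gene owns a two-layer network.  Inputs
are `log(1 + y)` (natural log); the hidden layer has 5n nodes, each
summing per-edge affine transforms `α + β·r` of every input, passed
through mish; the head sums per-node affine transforms and applies the
logistic sigmoid, so `f_i ∈ (0,1)`.  The per-edge `α`s collapse to one
bias per node; the package stores the per-edge layout (10n³ + 10n²
scalars) as the canonical parameter set and evaluates the equivalent
dense form.  The log(1+y) offset (rather than log y) keeps zero counts
finite and only reparameterizes the learned weights; the transform is
configurable.

**Noise.**  Each state variable receives an independent Wiener
increment scaled by `g(z) = √z` for `z > 16`, `z/4` for `z ≤ 16` — the
diffusion approximation of birth–death noise, linearized at low counts
so relative fluctuations stay bounded and the integrator does not drive
counts negative.  The two branches agree at the threshold (g(16) = 4).

**Environment.**  The target rhythm is
`v(t) = (sin(2πt + π) + 1)/2`, period 1 day; upward crossings of 0.5
(dawn) fall on half-integer days.  The external light signal is a
telegraph process starting "off", with exponential waiting times (mean
`w = 2` days) between switches; evaluation at a switch time takes the
post-switch state (right-continuous).  While on, it boosts TF 2's
production by `u(t) = A·v(t)^p` with amplitude `A = 10⁶` molecules/day
and sharpness `p = 4` — a pulse peaking at midday.  Both constants are
configurable; p = 4 is adopted as the reading of the forcing law (the
alternative reading `10⁶·v − 4` is rejected because it would be
negative at night).

**Objective.**  Abundance and target are made commensurate by order-2
Hill transforms: `ỹ = y²/(S² + y²)` with state-switch threshold
`S = 10³` molecules, and `ṽ = v²/(c + v²)` with `c = 0.25` so that the
half-point of the transform sits exactly at the day/night transition
value v = 0.5, mirroring ỹ's half-point at y = S (`c` is configurable
via `objective.target_half`; c = 0.5 behaves nearly identically and
remains available).  The loss sums squared transformed gaps over the
grid t = 0, 0.02, 0.04, … (50 points/day, half-open at the horizon),
read off the integrator's own save points — never interpolated.

## Training

Gradients are pathwise: per optimization step, light schedules and
Wiener increments are freshly sampled and then frozen while the loss is
differentiated through the unrolled Euler–Maruyama integration.  The
package implements this reverse sweep directly (`_adjoint.py`) as the
discrete adjoint of the integrator: forward states are cached, layer
activations recomputed, and the clamp at the abundance floor
back-propagates the subgradient of `max` (zero through clamped
entries).  Correctness is enforced by tests comparing every gradient
pathway against central finite differences (relative error < 10⁻³).

Defaults: Adam, learning rate 10⁻², batch 1; kinetic rates are trained
in log space so positivity is structural; curriculum horizons
(0.5, 1, 2, 3, 4) days with 100 steps per stage (first fits part of a
day, final range 4 days); optional noise-off warmup stage
(`pretrain_deterministic`) before stochastic fitting.  Training-start
kinetics default to m = 2·10⁴, δ = 8, s = 4, γ = 2 (per day), putting
the protein scale near the 10³ switch threshold; initial network
weights are i.i.d. normal with scale 0.1, so every gene starts near
f ≈ 0.5.  The best (lowest-loss) parameter snapshot across the history
is returned; a wall-clock budget, when set, stops training gracefully.

## Integration

Euler–Maruyama with dt = 10⁻³ days and post-step clamping at the
abundance floor (default 0) is the default scheme: it is simple to
differentiate through, and the linearized low-count noise already
prevents most negativity.  A drift-implicit variant (fixed-point
iteration on the implicit step, noise evaluated at the step start) is
available via `scheme = "implicit_em"` for stiff parameter regions.
Light forcing is evaluated at each step's left endpoint, consistent
with the right-continuous schedule convention.  Initial conditions
default to 10 molecules per species (configurable); realistic runs are
insensitive to this choice after the first transient day.

Deterministic accuracy: on a constant-f (linear) system with rates of
order 1/day the integrator matches the closed-form solution to relative
10⁻⁴ along the whole path at the default dt; the empirical convergence
order is first order in dt, verified by step-halving.

## Deviation analytics

For each day, the target's dawn (upward 0.5-crossing) is paired with
the cell's nearest upward crossing of TF 1 abundance through S within
±12 h.  The deviation is (cell − dawn) × 24 hours — negative when the
cell runs early.  Days with no crossing inside the window are censored;
censored days are counted but excluded from percentiles.  Crossings are
linearly interpolated between save points with a strict-crossing
convention (a series resting exactly on the threshold crosses nowhere).
Ensembles run replicates in vectorized chunks, each with its own light
schedule and noise path; a replicate whose integration fails is
recorded as fully censored rather than aborting the ensemble.
Plot-friendly scalings (log₁₀(1+y) axes, 1 + 4ỹ state traces) belong to
export helpers only and never enter loss or deviation arithmetic.

## Fixtures

The test vehicle is the repressilator: gene i repressed by gene i−1
(mod n) through a Hill rule `K^h/(K^h + y^h)`.  Documented defaults:
K = 500 molecules, h = 4, kinetics m = 4·10⁴, δ = s = γ = 8 (/day).
These were chosen so that the maximal protein level m·s/(δγ) = 5·10³
sits an order of magnitude above K (repression sweeps its full range)
and the matched mRNA/protein timescales minimize the ring's instability
threshold; the 3-ring then holds a deep limit cycle (peak/trough ≈ 100,
counts 10¹–10⁴, several peaks per 6 days), which the suite
cross-checked once against an independent `scipy.integrate.solve_ivp`
integration.  Two subtleties are deliberate: the documented initial
state is asymmetric (a symmetric start lies on the symmetric invariant
manifold and never oscillates in the deterministic system), and the
even 4-ring carries no oscillation guarantee (it is used for static
input–output surface tests only).

`fit_net_to_rules` distills Hill rules into the network architecture by
per-gene Levenberg–Marquardt with an analytic Jacobian over ~700
log-spaced and log-uniform abundance points, plus a small ridge penalty
(3·10⁻³) on the weights — without the ridge, LM drives the training
residual to machine precision and the interpolant oscillates wildly
between grid points (held-out error near 1); with it, training and
held-out errors are both ~10⁻³.

`make_shifted_tracking_trajectory` inverts the Hill state transform to
build a readout series whose internal state equals the transformed
target shifted by a chosen number of hours — an exact oracle for the
deviation pipeline (recovered shift equals the imposed shift to within
one save step).

## What the synthetic conditions do and do not show

The simulated conditions are the model's own: exponential light
switching (mean 2 days unless varied), intrinsic noise via the
piecewise amplitude, and the 4-day curriculum.  Desk-scale training
runs in this repository (e.g. 200 steps on a 1-day deterministic
horizon, n = 3) demonstrate that the pathwise gradients optimize the
loss — they roughly halve it from a random start — but are orders of
magnitude short of the multi-day optimization needed for tightly
entrained solutions; the analytics are therefore validated on
constructed oracles and fixture circuits rather than on a fully trained
4-TF network.  Real transcriptional systems also violate several model
assumptions: noise is not exactly √z-Langevin at low copy number,
transcription responds with delays and bursts absent here, and the
light input enters through a single additive production term.

## Numerical conventions

* 1-based gene indices in all public configuration (readout gene 1,
  light-coupled gene 2), converted internally to 0-based.
* Loss-grid times must land on integration save points; `sample_dt`
  not an integer multiple of `dt` is a configuration error.
* Same seed ⇒ bitwise-identical schedules, trajectories, and training
  histories (PCG64 generators seeded explicitly everywhere).
* JSON parameter files round-trip doubles bit-exactly (shortest-repr
  serialization); schedule CSVs carry `initial_on`/horizon in a JSON
  comment line.
* Degenerate inputs fail loudly with typed exceptions: non-finite
  states carry the failure time, fit failures carry the achieved
  residual, all-censored summaries refuse to produce percentiles.

## Known limitations

* No exact-stochastic (Gillespie) reference simulation; the model is
  the Langevin SDE by construction.
* No adaptive step-size control; stiff optimized parameter sets may
  need the implicit scheme or a smaller dt, chosen manually.
* The trainer's batch is vectorized but single-threaded numpy; large
  curricula are CPU-bound.
* Percentile summaries ignore censoring beyond reporting its count; no
  survival-style correction is attempted for days without crossings.
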