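# Methods

## Model

The package models one morphogen `M(x, t)` and one expander `E(x, t)` on a
1D tissue `x ∈ [0, L]` with zero-flux boundaries:

```
∂t M = D_M ∂²x M − k M / (1 + E/ξ)  + ν_M θ(w_M − x)
∂t E = D_E ∂²x E − μ E / (1 + E/ζ)  + ν_E m^h / (m^h + M^h)
```

The morphogen is produced at rate `ν_M` in a source region of width `w_M`
at the left edge and degraded at a rate that the expander suppresses
hyperbolically (half-suppression at `E = ξ`); `k` is therefore the *upper
limit* of the morphogen degradation rate, reached when `E → 0`. The
expander is produced where the morphogen is low (repressive Hill function
with threshold `m` and coefficient `h`) and suppresses its own degradation
the same way (`ζ`, upper limit `μ`). The self-suppression is what allows a
position-dependent expander profile to scale with tissue length, and hence
to support morphogen scaling.

Assumptions: the tissue is quasi-static (length changes are handled as
independent steady-state problems at each length, justified when gradients
relax much faster than the tissue grows); concentrations are deterministic
(noise enters only through the closed-form precision metric); geometry is
1D with no growth, advection or dilution.

Units: lengths in µm, times in model time units, concentrations in
arbitrary model units. No nondimensionalization is imposed; parameter
ranges are chosen in these units around the reference length L₁ = 50 µm.

Source-region variants: `w_M = βL` (source scales with the tissue, the
default, with β = 0.1), `w_M = w0` fixed, or a constant influx `j0` at
x = 0 with no distributed source. A constant influx behaves like a narrow
fixed source with matched total production (verified to 5% beyond five
source widths), so the flux mode is implemented as a boundary term only.

## Discretization and solvers

Method of lines on a uniform grid (default 1001 nodes; 501 in sweeps),
second-order central Laplacian, ghost-node reflection at the boundaries.
The source indicator is discretized by the fractional overlap of each
node's control volume with `[0, w_M)`, so total production is continuous
in `w_M` and discrete conservation holds exactly: the weighted sum of the
right-hand side equals total production minus total degradation (plus
`j0` in flux mode) to round-off. The state is interleaved
`(M₀, E₀, M₁, E₁, …)`, making the Jacobian banded with bandwidth 2; it is
assembled analytically.

**Steady states** use pseudo-transient continuation: backward-Euler steps
whose pseudo-time step doubles after each accepted step, each step solved
by Newton iteration with a banded LU solve (O(Nx) per iteration). A step
is rejected (and the step size cut) when Newton fails *or* when the
steady-state residual grows by more than a factor of 2 — the safeguard
that prevents overshoot to spurious large-concentration states when the
step has grown aggressively and the initial state is far from the
attractor. Because residual contraction is per-step rather than
per-unit-pseudo-time, the march is bounded by a step budget (2000) and an
overflow guard (10¹² concentration units, reported as "blow-up") rather
than by a pseudo-time horizon; an explicit `t_max` is honoured if set.
Convergence is declared when `max|∂t M| / (max M + atol) < ss_tol` (and
likewise for E; defaults `ss_tol = 1e-8`, `atol = 1e-10`), after which a
direct Newton polish of the algebraic system drives the residual toward
round-off — this is why the mass-balance residual of converged profiles
is typically ~1e-12 rather than ~1e-8. Failures never raise; they are
reported through `converged=False` plus a message.

**Transients** (and relaxation timing after a production-rate step) use
scipy's adaptive BDF integrator with the same analytic Jacobian in sparse
form (`rtol = 1e-8`, `atol = 1e-10`). Relaxation runs integrate in
geometrically growing chunks and scan the steady-state criterion at every
accepted integrator step. The detection threshold for *trajectory* states
is `ss_tol_transient = 1e-6`: the pointwise residual of an integrated
state has a floor of roughly `rate × rtol` (≈1e-7 for the fastest rates in
the sweep ranges), so the strict 1e-8 criterion would never trigger there.
`τΔ` is defined as the time from the perturbation to steady-state
detection (`t_ss`); the time `t_max` at which the spatially integrated
morphogen is extremal (maximal after a production increase, minimal after
a decrease) is reported alongside, so either timing convention can be
recovered.

Observed accuracy: the no-feedback steady state matches the closed-form
piecewise-cosh solution to <1e-4 relative error at 2001 nodes, and the
empirical convergence order between 501/1001/2001 nodes is 2.0 on the
reference feedback systems.

## Metrics and conventions

Threshold-position inversion interpolates **log**-concentration linearly
(exact for exponential decay; linear fallback in cells containing zeros)
and returns the smallest matching position. The search region runs from
the profile's global maximum to the far edge: the morphogen can dip
slightly at x = 0, where the expander minimum maximizes degradation, so a
rise strictly before the maximum is tolerated while any rise after it is
an error. Positions falling outside `[0, 1]` are clamped and flagged;
clamping keeps the metrics defined tissue-wide where plateaus would
otherwise make the inversion diverge, and the flags let aggregation report
clamp frequency.

Scaling and robustness compare **absolute** concentrations (not
normalized), so amplitude changes count as scaling/robustness failures —
this is deliberate: a readout cell sees absolute concentration.

Precision is the deterministic formula `σ_r = √(M / (d (∂r M)²))` with
`∂r M` by central differences in relative coordinates, `M` in solver
concentration units and `d = 0.02 L₁ = 1 µm`; the dimensional convention
(whether `M` is a 1D number density) is adopted literally and recorded
here rather than reinterpreted. `P_M = 1 − σ_r` is floored at 0 with the
raw `σ_r` retained; zero-slope positions get a divergence sentinel.

Expander summaries: dynamic range `f_E = (E(L) − E(w_M))/E(L)` (undefined
when `E(L) = 0`); source width `w_E = ∫ m^h/(m^h + M^h) dx`; integrated
effective degradation `μ̄ = ∫ μ/(1 + E/ζ) dx` (trapezoid rules). The
half-decay length `λ_E` is measured from the far edge to the largest
position where `E` crosses `E(L)/2` *absolute* (not the range midpoint):
the two conventions coincide for the high-dynamic-range systems the
quantity is used for, and the absolute convention gives a clean sentinel
(no crossing) for flat profiles.

Classification: "global" scaling requires `S_M ≥ 0.98` at every evaluated
position of the target tissue `r ∈ (w_M/L, 1]`; "local" requires it
somewhere; the 0.98 default corresponds to a <2% boundary shift. The
useful-patterning region is where `min(S, R, P) > 0.95`, with interval
endpoints interpolated at the threshold crossing. Both thresholds are
configurable and recorded with results. Metrics are *evaluated* on the
full `r ∈ [0, 1]` (101 uniform points) for reporting; classification uses
the target tissue only.

## Sweep design

Parameters are drawn log-uniformly and independently: `D_M, D_E ∈ [0.1,
100] µm²/t`, `k, μ, ν_M, ν_E ∈ [1e-3, 10]`, `ξ, ζ, m ∈ [1e-3, 10]`, `h ∈
{2, 4, 8}`, with `β = 0.1` fixed. These ranges span effective decay
lengths from far below to far above L₁ = 50 µm and are the package's
defaults, configurable per campaign. The protocol solves each system at
L₁ = 50 µm and L₂ = 100 µm (scaling) and at ν_M × 1.5±1 at L₁
(robustness and relaxation timing). The RNG for draw `i` is seeded from
`(seed, i)`, so single systems are reproducible in isolation and results
are order-independent.

Filters, in order, with reason codes retained on failing records:
f1 all solves converged; f2 no blow-up; f3 morphogen monotonically
non-increasing on the target tissue at both lengths; f4 informative
gradient, `M(L)/M(0) < 0.5` at L₁; f5 expander feedback active,
`E(r) > ξ` for all `r ≥ 0.1` at both lengths. f3–f4 implement the
requirement of a biologically meaningful gradient (monotone and carrying
positional information); their thresholds are configurable and logged.
For economy the f3–f5 checks run on the L₁ base solve before the three
remaining solves are attempted; the verdict is unchanged by the ordering.
Relaxation timing is computed only for systems passing all filters.

Aggregation bins passing systems by `f_E` (width 0.1) and by membership
`S(r*) ≥ 0.98` at anchor positions r* ∈ {0.2, 0.5, 0.8}, reporting mean
and SD metric profiles per bin, the per-position probability of useful
patterning among local/global scalers, `λ_E/L` pairs at both lengths for
global scalers, and Spearman correlations (gradient-shape preference vs
`f_E`; mean `τΔ` vs `μ̄`).

## Gradient-shape classification

`fit_gradient_shape` fits `A exp(−x/λ)` (linear least squares on log M)
and `B (x + c)^(−α)` (linear fit on log(x+c), offset `c` by a bounded 1D
search) over `r ∈ [w_M/L + 0.05, 0.95]`, excluding the source and the
far-boundary plateau, with uniform weights. The signed preference
`(rss_exp − rss_pl)/(rss_exp + rss_pl)` is positive when the power law
fits better. Note the power-law family has one more parameter and the
true uniform-expander solution is a cosh (flattening near x = L), so even
low-`f_E` systems can show mildly positive preference; the *correlation*
of preference with `f_E` across systems, not its sign in isolation, is
the meaningful signal.

## What the generated data does and does not show

The sweep generator produces steady-state systems of the model itself, so
passing tests demonstrate internal consistency of solver, metrics and
sweep logic, and the emergent relationships between dynamic range and
patterning properties *within this model family*. It does not emulate
measurement noise, 2D/3D geometry, growth-coupled advection or dilution,
shuttling, nonlinear (quadratic) self-enhanced morphogen degradation, or
transcriptional readout — conclusions about real tissues inherit all of
those idealizations.

## Problem sizes

Default single-system solves use 1001 nodes; sweep campaigns use 501
nodes and 101 metric positions. The bundled test suite runs a 200-system
seeded sweep for the emergent-property checks; `scripts/acceptance.py`
runs 400 systems. Larger campaigns (e.g. thousands of systems) use the
same code paths via the `sweep` CLI and scale linearly, at roughly 0.5–1 s
per system on one CPU.

## Known limitations

* The steady-state criterion is relative (`|∂t M| / max M`), so a
  pathological system whose total concentration grows linearly forever
  can eventually satisfy it; such systems have flat, uninformative
  gradients and are removed by filter f4, but the `converged` flag alone
  should not be read as proof of a genuine steady state for unfiltered
  parameter sets (the mass-balance diagnostic is the cross-check).
* Relaxation times depend on the detection threshold
  (`ss_tol_transient`); comparisons between systems are meaningful,
  absolute values shift with the threshold roughly as the slowest
  system rate times the log of the threshold change.
* The power-law/exponential discrimination is a goodness-of-fit contest
  between non-nested families of different sizes, not a likelihood-ratio
  test; it is used as a correlate, not a hypothesis test.
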