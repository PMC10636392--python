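# Methods

This note documents the model, the estimators, the numerical choices, and
the limits of what the test suite demonstrates.

## The automaton

The state is a vector of labels {F, G, B, A} on a periodic square lattice
with 4-nearest-neighbour adjacency; the dynamics are a continuous-time
Markov chain.  Per-cell conversion channels and rates (1/y):

- grass/ash → forest: β (spontaneous, long-range seed rain) plus α per
  forest neighbour (local spread);
- forest → grass: γ (background mortality);
- grass → burning: φ per cell (ignition) plus ρ_g per burning neighbour;
- forest → burning: ρ_f per burning neighbour;
- burning → ash: μ; ash → grass: λ.

The default rates (α=3e-2, β=2e-4, γ=2e-2, λ=5, μ=1e6, ρ_g=9e6,
ρ_f=1.11e5, φ configured via the domain total φN, typically 0–2/y) encode
three separated timescales: fires (hours), grass regrowth (months), forest
demography (decades).  `Params.validate_timescales()` warns — never errors —
when a custom set breaks that ordering, since every analytical reduction in
the package assumes it.

φ is stored per cell; figures and configuration quote the domain-total φN,
and `Params.with_phi_N`/`phi_N` convert explicitly to avoid the
N-ambiguity.

## Exact simulation

`simulate` uses the Gillespie direct method with per-cell propensities in a
binary sum tree (O(log N) sampling and update; only the event cell and its
four neighbours are touched per event).  Rates span ten orders of
magnitude, which the direct method handles exactly; the tree is rebuilt
every 10⁶ events to cancel float drift, and a drift-selected zero-rate leaf
is treated as a null event.  Elapsed time uses Kahan summation so that
~10⁷ fire-scale increments (~10⁻¹⁰ y) accumulate without precision loss.

The ignition channel is kept out of the tree as a single global propensity
φ·(number of G cells) with O(1) uniform sampling of the ignited cell.  This
makes a state-dependent φ — the feedback-control law — an O(1) update after
each forest-count-changing event instead of an O(N) propensity sweep.

Recording is decoupled from events: fractions are recorded on a fixed
cadence, landscape snapshots at requested times, and the integrals
∫[F]dt, ∫[G]dt, ∫φdt are accumulated event-exactly so that window averages
(`Trajectory.window_average_*`) are integrals of the piecewise-constant
path, not sample means.  The event log stores per-channel counts and every
ignition timestamp; individual fast fire events are not logged in full
(memory).

Correctness evidence: on a 2×2 torus with a reduced reaction set, the
sampled occupancy distribution matches the stationary law of the explicit
16-state generator to total-variation distance < 0.05; a mortality-only
ensemble reproduces the e^{−γt} decay; realized counts of
composition-proportional channels match their exactly integrated
propensities within Poisson error.

## Single-fire analysis

`simulate_fire_event` freezes vegetation and runs only
{G→B, F→B, B→A} until no cell burns — including fire spreading from
burning *forest* cells.  The analytic per-fire loss Δ_j = p_f·[FG]_j (with
the exact-exposure refinement q = 1−(1−p_f)^k per interface forest cell)
assumes the fire sweeps the whole interface once and that burning forest
does not propagate.  Measured behaviour at p_g≈1:

- exact-q ≤ linearized always (Bernoulli inequality);
- the Monte-Carlo mean *exceeds* both at the default p_f = 0.1, by ~30% on
  a square clearing, because each burned interface tree ignites further
  trees with probability ≈ p_f per pair — secondary spread the law ignores;
- at small p_f (≲0.02) the secondary term is inside Monte-Carlo error and
  the law is quantitative.  Tests therefore validate the law in its
  small-p_f validity regime and separately assert the direction of the
  secondary-spread bias at p_f = 0.1.

## Balance equation and emergent curves

`net_rate` measures geometry on the *slow view* (B, A mapped to G): on the
demographic timescale a burned tree is grass, since λ ≫ φN.  The raw-label
variant is available.  The loss term φ p_f N [G] [FG]cg is algebraically
identical to the per-cluster sum of (ignition rate) × (per-fire loss);
tests assert the identity exactly.

`fit_emergent_curves` fits [FG]*(F) and [FG]cg*(F) from trajectory scatter
with a boxcar local-mean (Nadaraya–Watson) smoother on a fixed grid
(default 60 nodes, bandwidth 2 grid spacings, widened adaptively where data
are sparse), pointwise standard-error bands, and a monotone PCHIP
interpolant through the node means.  The choice is deliberately simple: the
scatter is dense and narrow, and the smoother must pass a known-function
recovery test (max error < 2 noise SD against a curve + noise synthetic).
Fits are clipped non-negative, [FG]cg* is capped by [FG]* pointwise, and
when the scatter reaches within 0.02 of F = 0 or 1 the curve is pinned to
the exact boundary value 0 there (a pure landscape has no interface) —
without this the grassland root sits just outside the data-supported range.
Beyond the (possibly extended) grid, evaluation raises: the curves are
empirical and are not extrapolated.

`ode_steady_states` brackets sign changes of the closed one-variable ODE on
a 400-point scan and refines with Brent's method; stability is the sign of
a central-difference slope.  On curves fitted from a six-run tipping
ensemble at φN = 0.38 (30², 150 y each) it returns stable/unstable/stable
roots near 0.00/0.38/0.83.

With γ = β = 0 and a single grass hole in closed forest, the balance
reduces to d[F]/dt = (α − φNp_f[G])[FG]; the critical hole fraction is
[G]c = α/(φN p_f) (`critical_hole_size`, which enforces γ = β = 0).  A
seeded sweep on 30² confirms holes 20% below [G]c close and 20% above grow.

## Resilience

`sensitivity` is the ratio of the balance-equation change to the cover
change under a perturbation; `mean_sensitivity` is the ratio of weighted
sums over an ensemble (default 64 realizations), *not* the mean of ratios,
so rescaling all weights is a no-op.  The built-in ensemble mirrors the
natural processes — perimeter forest removal (weight φN p_f), perimeter
recruitment (α), random mortality (γ), random recruitment (β) — with the
flipped fraction per perturbation a required choice (default 0.1; there is
no canonical value).  Caveat: with strongly asymmetric weights the
denominator Σ w_i Δ[F] can nearly cancel, inflating the indicator; probing
a state with a symmetric perturbation pair avoids this.

## Unstable-branch tracing

The feedback law φ(t) = φ₀ + g([F](t) − F_ref), clamped at zero, is
re-evaluated after every event that changes the forest count and enters
only the ignition channel.  At a controlled equilibrium the feedback term
averages to zero, so the measured pair is an equilibrium of the
uncontrolled system.  [F]̄ is the exact window integral; φ̄N is the
ignition count per year divided by mean grass cover (the count's
expectation is φN[G] per year).

Gain selection is problem-specific.  The package measures saddles in two
stages (`measure_saddle`): a stiff settling stage (default gain
100–40 × φ₀, enough that the state cannot escape the saddle neighbourhood
during the transient), then a long weak-gain window (default 20 × φ₀,
400 y) re-centred at the settling estimate.  The weak stage matters for two
reasons: heavy φ modulation correlates φ(t) with the landscape, so the
ignition-weighted φ̄ stops matching any constant-φ system; and the φ̄
estimate carries Poisson error 1/√(ignition count), which only a long
window tames (~100 ignitions → ~10%).  Noninvasiveness is verified by (i)
evaluating the balance equation at φ̄ on window-sampled landscapes — the
mean net rate is zero within twice its standard error, where that SE
combines a moving-block bootstrap of the sampled nets with the propagated
Poisson error of φ̄ — and (ii) releasing the control: regular runs from the
stabilized landscape at fixed φ̄ tip both up and down across seeds.

`block_bootstrap_ci` implements the moving-block bootstrap of the mean
(overlapping blocks, resampled to the original length); block length is the
caller's choice and should exceed the series' correlation time.

## Mean field

Assuming no spatial correlations, [FG] = 4[F][G] and [FG]cg becomes
[FG]cg_u([F]), measured by Monte Carlo on uniform-random landscapes
(default 64², ≥10 replicates per grid value; there is no closed form) and
interpolated monotonically with exact zeros at F = 0, 1.  The closed model
gives [F]⁻ = 0, [F]⁺ = 1 − γ/(4α) = 0.8333 and, via the low-cover
single-cluster limit, (φN)min = (α − γ/4)/p_f = 0.25 (fire return interval
4 y) for the default rates.  Because β > 0 rounds the transcritical at
F = 0, the three-root window opens only ≈0.05 above (φN)min; the root-sweep
tests probe φN = 0.15 (one root) and 0.5, 1.0 (three roots).  Structured
landscapes from the dynamics violate the closure in a definite direction —
[FG] < 4[F][G] (forest aggregates) — quantified by `mf_bias_check`.

## Problem sizes and determinism

The default test suite runs lattices of 2²–60² and a 50² / 300 y ensemble
for the bistable-equilibrium check; the full suite takes a few minutes on
one core, and `scripts/acceptance.py` (which re-derives the headline
numbers, including the 4-seed 50² simulation) a few seconds.  These sizes
are the package's validation defaults; all entry points accept larger
domains (the simulator's cost is O(events × log N), ~10⁵ events/s in
practice).  Every stochastic path takes an explicit seed; ensembles derive
per-replicate seeds via `SeedSequence([base_seed, k])`, and reruns with the
same configuration and seed are byte-identical.

## What the synthetic conditions do and do not show

All validation uses landscapes generated by the package itself (uniform
random, constructed holes, or states grown by the dynamics) under the
default rate set.  Passing tests therefore demonstrate internal
consistency of simulator, balance equation, control and mean field under
the model's assumptions — homogeneous parameters, 4-neighbour spread,
periodic boundaries, cell-scale mixing of "grass" and "ash" — and
quantitative agreement with the closed-form predictions in their stated
regimes.  They do not show that real landscapes follow the balance
equation: real fire spread is anisotropic and weather-driven, dispersal is
not nearest-neighbour plus uniform rain, and parameters vary in space.
Known further limitations: finite domains make the macroscopic transitions
sharper than they would be on very large lattices; saddle measurements
carry the estimator caveats above; and the per-fire loss law degrades for
p_f ≳ 0.05 (secondary spread) or p_g ≲ 0.9 (incomplete sweep).
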