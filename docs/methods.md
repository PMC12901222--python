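# Methods

## Model

`ifxsim` simulates the interaction of free TNF-α (`L`, molar), the occupied
fraction of its cell-surface receptors (`r`, dimensionless), free anti-TNF
antibody (`A`, molar) and the antibody–TNF complex (`C`, molar) in a single
well-mixed compartment.  Both binding steps follow mass-action kinetics;
bound receptors are internalised at rate ε (`k_int`), free TNF-α, free
antibody and the complex are eliminated first-order at δ₁ (`k_el_tnf`),
δ_a (`k_el_ab`) and δ_c (`k_el_cx`).

The distinguishing closure is the TNF-α production term.  In the
*constant-production* variant, `L` gains a fixed zeroth-order input ω₁ and
loses δ₁L.  In the *dynamic-production* model, production is set equal to
the instantaneous losses (ε r R_tot + δ_c C + δ₁ L), so the weighted total

    P₀ = L + R_tot·r + C

is exactly conserved.  This encodes the assumption that the inflammatory
stimulus regenerates TNF-α in proportion to what the system removes — the
mechanism by which a dose keeps TNF-α suppressed for the whole inter-dose
interval instead of letting it rebound within days.  A *reduced* three-state
form substitutes `L = P₀ − R_tot·r − C`; it is algebraically equivalent and
is integrated as a cross-check (trajectories agree with the full system to
better than 1e-6 relative in the tests).

Structural guarantees used as runtime/test invariants rather than proofs:
solutions stay non-negative, `r ≤ 1`, `A + C ≤ max(A₀+C₀, ω*/min(δ_a, δ_c))`
for maximal infusion rate ω*, and `L ≤ P₀`.

## Parameters, units and presets

All internals are strict SI-molar (mol/L, seconds); weeks, hours, mg and
mg/L exist only at the interface layer.  Default rate constants (association
1.7e7 1/(M·s) and dissociation 5.5e-4 1/s for TNF–receptor, 1e6 and 1e-4 for
TNF–antibody, R_tot = 1.5e-10 M, ε = 6e-4 1/s, δ₁ = 1e-5 1/s,
δ_c = 8.5e-7 1/s) are literature estimates.  The antibody clearance δ_a is
the patient-specific quantity; values outside the literature window
[1.5e-6, 5e-6] 1/s trigger a warning, not an error, because the adaptive
loop legitimately walks below it.

Disease presets differ only in the baseline TNF-α: L₀ = 4.35e-11 M (CD) and
2.75e-11 M (UC), with r₀ = 0.0827 and no drug, chosen so the drug-free
equilibria match the reported levels in active disease (2.07e-11 and
1.41e-11 M).

Unit conventions are reverse-engineered from the standard correspondences
and are user-overridable: infliximab molar mass 144190 g/mol and a 1 L
reference distribution volume reproduce the 350 mg / 2 h infusion rate
3.3713e-10 M/s exactly; TNF-α at 17 kg/mol maps 2.6e-13 M to 4.42e-6 mg/L.
The 3 mg/L trough threshold converts to 2.0806e-8 M.  No multi-compartment
PK, bioavailability or anti-drug-antibody elimination is modelled.

## Numerical integration

The system is stiff (binding relaxes at ~1e-2 1/s against clearances at
~1e-6 1/s), so trajectories use scipy's BDF with an analytic Jacobian.
Infusions are piecewise-constant input rates; the integrator is restarted at
every infusion start/end instead of relying on event detection, so the
right-hand side is smooth within each segment.  Defaults: rtol 1e-8,
atol 1e-20 for molar states and 1e-12 for `r` (states span ~1e-13–1e-6 M),
200 output samples per segment so per-cycle extrema are resolved.  The
acceptance gate on accuracy is physical, not nominal: the conserved pool
must drift less than 1e-6·P₀ over the whole run, or the integration errors
out.  Solver-scale negative undershoot is clamped at segment boundaries
(warn beyond −1e-15, configurable to strict).

Degenerate cases: an empty dose schedule integrates as a single segment; a
double equilibrium root returns the same pair twice; equilibrium-root
selection uses the admissibility test (`r* ∈ [0,1]`, `L* ∈ [0,P₀]`) rather
than a sign convention so it is correct for arbitrary positive parameters.

## Regimens, cycles and the sweep

A cycle runs from one dose start to the next (the last one to the end of the
run).  `A_min` is the value at the cycle end — the pre-dose trough measured
in TDM — while peaks and TNF extrema are taken over the whole cycle.
"Steady-cycle" extrema are defined as the final cycle of the standard 3-dose
weeks-0/4/8, 12-week protocol, matching the usual presentation; an optional
run-to-convergence mode extends 4-weekly until cycle-to-cycle extrema change
by < 0.1 %.  The clearance sweep evaluates that protocol on a configurable
grid defaulting to 36 uniform points across [1.5e-6, 5e-6] 1/s (the grid
behind published versions of this curve is not stated anywhere we could
anchor to, so it is a package choice).

The per-cycle TNF peak at high clearance approaches the untreated
equilibrium only near the top of the clearance range: at 5e-6 1/s the final
cycle's peak is within 15 % of L*, whereas at 3.5e-6 1/s it is still ~3×
below.  The tests therefore pin that property at 5e-6 1/s.

## Inverted Hill clearance model and fitting

Inflammation increases drug loss, so clearance falls as exposure rises:
δ_a(A_min) = V/(1+(A_min/K)ⁿ), defaults V = 6.8939e-6 1/s,
K = 0.5809e-9 M, n = 0.2590.  `fit_hill` minimises untransformed clearance
residuals.  The loss surface in the shallow-exponent regime is badly
conditioned — V, K, n are strongly correlated and span ten orders of
magnitude — and a single gradient descent from heuristic starting values
(largest observed clearance, geometric-mean trough, n = 0.5) demonstrably
stalls in local minima with ~10× the optimal residual.  The fit therefore
scans a coarse (K, n) grid, solving V in closed form at each node (the model
is linear in V), and polishes the best node with Levenberg–Marquardt on the
log-parameters.  On noiseless self-generated data this recovers the
generating parameters to machine precision; refit from the package's own
default sweep it recovers the reference values to within 25 % (V +3 %,
K −21 %, n −3 %), the residual K gap reflecting the unstated sweep grid.
Under 1 % multiplicative noise, V and n recover to ~1 % (median); K is
intrinsically weakly identified, with ~10 % median sampling error, and is
therefore tested at a wider band.

## Adaptive regimen conventions

Dose 1 runs with the supplied initial clearance.  The trough is the state at
the instant immediately before the next infusion begins (final interval:
read at interval end); before each dose k ≥ 2 the measured trough is fed
through the Hill relation and the resulting clearance held for the next
4-week interval.  `doses_to_therapeutic` is the smallest k whose
end-of-interval trough (4 weeks after dose k) first meets the threshold; the
one-year horizon is 13 four-weekly doses starting at week 0.

These counts are extremely sensitive near the threshold: a trough scales as
exp(−δ_a·T) with δ_a·T ≈ 6–8.5 per interval, so a p % difference in
effective clearance amplifies to roughly (δ_a·T·p) % in the trough, and
cells whose troughs sit within ~15 % of 3 mg/L for several consecutive doses
can flip by one or more counts under tiny numerical differences
(solver tolerances included).  Moreover, reference dose-count tables of this
kind can be internally inconsistent with any single monotone
clearance–trough relation under this update rule: cells may simultaneously
require a lower and a higher clearance curve over overlapping trough ranges.
Alternative conventions (counting at the measurement before a dose;
updating from the previous interval's minimum, which lags one dose) are
documented and were evaluated; they fit reference behaviour worse overall,
so the convention above is the one implemented and tested.

## Synthetic data and what the tests do and do not show

There is no external data; the package's "data" are model-generated: preset
scenarios, dose schedules, sweep tables, and Hill-fit datasets (exact curves
and 1 %-noise seeded variants).  Fixture generation is deterministic given a
seed.  Passing tests therefore demonstrate internal consistency — exact
conservation, closed-form/numerical agreement, parameter recovery, correct
unit plumbing, and reproduction of the reference quantities the model is
calibrated to — not clinical validity: real patients have multi-compartment
kinetics, immunogenicity, weight- and albumin-dependent clearance, assay
noise and non-adherence, none of which are modelled.

## Known limitations

Single compartment; no anti-drug antibodies; clearance feedback only through
the trough (no continuous inflammation state); the autocrine TNF-α
production route is out of scope; dose counts within one dose of a boundary
should be treated as boundary cases, per the sensitivity analysis above.
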