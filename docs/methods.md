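# Methods

## The release model and its assumptions

Glucoamylase (EC 3.2.1.3) cleaves glucose from the non-reducing ends of
maltodextrin. Under cultivation-relevant conditions (30 °C, pH 7 — far from
the enzyme's pH 4.5–5 / 60 °C optimum) a single-pool Michaelis–Menten law
cannot reproduce the observed shape of release curves: an initially fast
release that slows long before the substrate is exhausted. The model
therefore splits dextrin into a susceptible pool `SS` and a resistant pool
`SR` sharing one Michaelis constant `K` (the data cannot discriminate two
affinities), with catalytic constants `kS >> kR`. Hydrolysis adds one water
per cleaved bond, so 1 g of polymerized anhydroglucose yields
`ν = 1.111` g of free glucose; `ν` is a parameter so other polymers can be
modeled. Working variables are the measurable `P, S, WS = SS/S, E, V`; the
`WS` equation follows from the quotient rule and vanishes at the boundaries
`WS ∈ {0, 1}`, so `WS` stays in `[0, 1]` along every trajectory.

Assumptions worth stating explicitly:

* the enzyme is not degraded or inactivated (`dE/dt` has only the dilution
  term); temperature and pH dependence of `kS, kR` are out of scope;
* evaporation (default `3e-5` L/h) removes water only, so it *concentrates*
  all species while the glucose-equivalent mass `V·(P/ν + S)` is conserved —
  this invariant is the backbone of the conservation tests;
* vessels are ideally mixed; every liquid addition is an instantaneous
  bolus: each concentration is diluted by `V/V'` and the added species
  receives its stock mass. Added dextrin carries the fresh-stock
  susceptible fraction `WS0`, which is what makes resistant dextrin
  accumulate during long feeds;
* all volume additions dilute, including pH reagents and water.

Units package-wide: g/L, U/L, L, h. The enzyme unit U is the
supplier-defined activity unit; all rates are linear in U/L.

## Model variants

Seven variants are implemented for model comparison: one-pool ("simple MM")
and two-pool families, each optionally with product inhibition
(competitive: `K → K(1 + P/Ki_P)`) and/or substrate inhibition
(`+ S²/Ki_S` in the denominator). The inhibition forms are this package's
design choice of the standard Michaelis–Menten extensions used in the
saccharification literature. The two-pool model with `kS = kR` reduces
exactly to the one-pool model, which the tests exploit.

## Event-driven integration

Between events the ODEs are solved with a stiff-capable adaptive
integrator (LSODA; default `rtol 1e-8`, `atol 1e-10`). Events segment the
integration — no root-finding. Same-timestamp events apply in listed
order; negative round-off concentrations are clipped to zero after each
step; below `S = 1e-12` g/L the `WS` derivative is defined as 0.

## Parameter estimation

All experiments of a campaign are fitted simultaneously against glucose
measurements only (the other states are not observed in the cell-free
stage); residuals are unweighted by default with optional per-point
weights. The global stage is seeded differential evolution over box
bounds (population 20, up to 200 generations, dithered self-adaptive
mutation; scipy's convergence criterion may stop it earlier), followed by
a bounded least-squares polish (lmfit) whose Jacobian-based covariance
provides the reported standard deviations. `WS0` plays a double role: it
is the composition of fresh dextrin stock *and* the initial condition
`WS(0)` of every calibration experiment, so the objective starts each
two-pool simulation from the trial `WS0` — this, not the bolus splits, is
what identifies it. `K` is fixed at 0.001 g/L: with
campaign substrate levels of 15–40 g/L it is orders of magnitude below `S`
and not identifiable. Default bounds: `kS, kR, k_single ∈ [1e-5, 1]`,
`WS0 ∈ [0, 1]`, `Ki ∈ [0.1, 1000]`.

The two-pool likelihood has an exact label-swap symmetry:
`(kS, kR, WS0) ↔ (kR, kS, 1−WS0)` leaves the model invariant. The
convention `kS ≥ kR` ("susceptible" = faster) is enforced as a penalty in
the DE stage and by canonicalizing local-fit results; without it the DE
population straddles the two mirror optima and stalls between them.

Nested-variant comparisons start the child variant's polish from the parent
optimum with the inhibition constant at its weak-inhibition bound, so the
child's RSS can only improve on the parent's — the nesting property the
comparison is meant to expose.

## Feed planning

Targets come in three forms sharing one dosing rule:

* an explicit release-rate profile `r(t)` (cell-free experiments);
* an explicit glucose-concentration trajectory `P_target(t)`, differenced
  per interval (the difference-quotient rule);
* a growth schedule (`mu_set` phases, grid `Δt`, induction switch): demand
  is derived from the **biomass-mass** trajectory
  `Xm(t) = X0·V0·exp(∫mu)` at yield `Y_XS` (default 0.5 g/g, a
  user-calibrated constant). Mass, not concentration, because the feed
  boluses themselves dilute the culture by ~2 %/h; a concentration target
  would conflate growth with that dilution.

At each grid time (default `Δt` = 10 min, the liquid handler's action
cadence) the planner: integrates the model exactly to the grid time,
applies the dextrin maintenance bolus (default 40 µL of 150 g/L stock
every 10 min) *first* so the dose is computed on the state the enzyme
actually meets, compares the cumulative released mass with the cumulative
target, and doses `E_add = (r − r_now)(S + K)/(ν(kS·SS + kR·SR))` via a
dilution-aware stock volume `v = V·ΔE/(E_stock − E_target)`. Differencing
against the *integrated* state gives the catch-up property: an interval's
shortfall raises the next interval's issued rate, so cumulative error stays
at the scale of a single interval instead of growing with the horizon.
`r_now` uses the reaction term only — dilution and evaporation are excluded
from the dosing rule, consistent with its derivation from the rate law.

Within an interval the realized rate drifts as `SS` depletes; the drift is
below 2% while `rS·Δt/S < 0.01` (the difference-quotient regime). The
tests assert tracking only on controlled intervals (a dose was issued and
the regime condition holds): release cannot be *lowered*, so right after a
setpoint reduction the plan necessarily overshoots until the reaction
decays — a structural property of the method, not a defect. An opt-in
shooting refinement polishes each closed-form dose by minimizing the
squared end-of-interval glucose error (default off).

## Growth coupling

The cultivation module couples the release model to a deliberately standard
macro-kinetic *E. coli* description: Monod glucose uptake (`qS_max`,
`K_s`), acetate overflow above a critical specific uptake `qS_crit`,
acetate re-consumption when oxidative capacity is spare, constant yields,
an oxygen balance mapping volumetric uptake through `kLa` to DOT (% air
saturation), and, after induction, a step reduction of uptake capacity
(metabolic load) plus first-order product formation. All coefficients are
configuration with illustrative defaults (`mu_max ≈ Y_XS·qS_max = 0.7` 1/h
as the reference strain value); none is a measured value, and the
growth-side checks are therefore property-based (setpoint tracking within
15%, ledger closure, qualitative DOT signatures) rather than curve
reproductions. With `X = 0` the coupled system reduces exactly to the
cell-free release model. The realized growth rate is estimated as the
least-squares slope of `ln X` vs `t`; in a fed vessel the concentration
series carries a `−V̇/V` dilution term, so tests use the biomass-mass
series `X·V`. OD600 readings convert to biomass with the factor 0.37.
An auxiliary biomass estimate integrates the base (ammonia) dosing ledger:
cumulative N added x a configurable nitrogen-to-biomass factor (default
8 g biomass per g N, i.e. ~12.5% nitrogen content).

## Synthetic campaigns

The generator reproduces the *designs* of the study conditions: 24
cell-free calibration runs (11 mL; dextrin 15/30 g/L; glucose 0–15 g/L;
enzyme 10/20 U/L; dextrin/glucose pulses of 5.25/10.5 and 3.75/7.5 g/L at
6 h; 30 h horizon; 2 h sampling grid) and the triplicated fed-batch
validation conditions (10 mL; enzymatic feed at several `mu_set` pairs
with induction switch; bolus-fed and cell-free controls; dextrin 40 or
80 g/L). The exact allocation of mid-run additions across the 24
calibration runs is a deterministic choice: the 16-run full factorial
without additions plus 8 runs cycling through the 8 non-zero addition
combinations. Measurement noise is additive Gaussian truncated at zero
with `σ = 0.2` g/L — a documented stand-in for the analyzer precision, not
a measured value; the sampling grid is a fixed 2 h.

What passing the recovery loop shows — and does not show: the pipeline
(designs → simulate → noise → global+local fit) identifies `kS` and `WS0`
to a few percent and `kR` to ~20% under the stated noise; it does not show
robustness to real-data effects the generator omits (lot-to-lot substrate
variability, enzyme inactivation by shear/aeration, analyzer bias,
pH/temperature drift). Re-calibration per substrate lot and per cultivation
condition is the intended workflow.

## Problem sizes and numerical choices

The test suite and the acceptance script use the full 24-design campaign
(384 observations) for the headline fits, six designs for fast unit-level
fits, and 6–10 h planning horizons — sizes chosen so the whole pipeline
reruns in minutes on one core. Solver tolerances (`1e-8/1e-10`) put
integration error far below measurement noise; the conservation invariant
holds to <1e-6 relative over 30 h. Determinism: every stochastic component
(noise, DE) takes an explicit seed, and plans/trajectories are bit-for-bit
reproducible for a fixed configuration.

## Known limitations

* Inhibition-variant functional forms are this package's documented choice;
  other standard forms (e.g. uncompetitive product inhibition) would fit
  the same interface.
* No enzyme-inactivation kinetics, no temperature/pH dependence, no
  polymer chain-length or branching structure.
* The feed planner is open-loop with respect to measurements: it plans on
  the model, exactly as the facility executes it; sensor feedback is out
  of scope.
* Growth-model coefficients are illustrative; quantitative reproduction of
  real cultivation trajectories requires fitting them to data.
* Setpoint *reductions* are realized only passively (release decay), so
  aggressive down-steps overshoot; resistant-dextrin accumulation bounds
  the feasible duration and magnitude of high release setpoints.
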