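# Methods

## Conventions

Isotope ratios are referenced to atmospheric N₂ (¹⁵N/¹⁴N = 0.0036765) and
VSMOW (¹⁸O/¹⁶O = 0.0020052); δ = (R/R_ref − 1) × 1000 in per mil. Kinetic
fractionation factors ε (‰) enter every flux through the divisor
α = 1 + ε/1000: heavy flux = light flux × substrate ratio / α. Positive ε
therefore means the light isotope reacts faster ("normal"), negative ε an
"inverse" effect in which the heavy isotopologue is consumed
preferentially. Model outputs in δ are insensitive to the reference-ratio
constants; they matter only when atom pools are initialised.

Under this convention the exact closed-system (Rayleigh) form for a single
substrate consumed by a single reaction is R/R₀ = f^(1/α − 1) with f the
fraction of the light pool remaining; `isotope_core.rayleigh_delta`
implements it and serves as the independent oracle for the ODE models in
the single-substrate limit.

## Open-system calculators

At steady state, influent (NT) and effluent (ANX) concentrations and δ
values of a continuously fed anammox reactor determine apparent isotope
effects without any kinetic model. The nitrite consumed between NT and ANX
splits three ways — residual (fraction *a*), oxidised to nitrate
(fraction *b*), reduced to N₂ (1 − a − b) — and the isotope balance

δ¹⁵N_NO₂^NT = (1 − a − b) δ¹⁵N_N₂ + a δ¹⁵N_NO₂^ANX + b δ¹⁵N_NO₃^ANX

is solved for the unmeasured δ¹⁵N_N₂, giving ¹⁵Δ_AMXNIR as
δ¹⁵N_NO₂^ANX − δ¹⁵N_N₂ (substrate minus product, positive = normal). The
equivalent closed-form quotient
[δ¹⁵N_NO₂^ANX − δ¹⁵N_NO₂^NT − b·¹⁵Δ_NXR]/(a + b − 1) evaluates with the
opposite sign on the packaged plant data; we report the
substrate-minus-product value and expose the raw quotient
(`apparent_amxnir_15_raw`) for audit.

The ¹⁸O budget of nitrate produced by nitrite oxidation inherits two O
atoms from nitrite and one from water, hence the combined effect
¹⁸E = ⅔δ¹⁸O_NO₂ + ⅓δ¹⁸O_H₂O − δ¹⁸O_NO₃. The plant's water δ¹⁸O was not
measured; the default −8‰ (typical fresh water, and the unlabelled
incubation water) is configurable and flagged in the CLI output.

The packaged fixture holds three-date mean concentrations and δ values for
the five-reactor train; per-date raw data are not available, so calculators
applied to the means land inside, not exactly on, per-date result ranges.

## Closed-system anammox model

State: ¹⁴N/¹⁵N atom pools of NH₄⁺, NO₂⁻, NO₃⁻ and N₂, plus ¹⁶O/¹⁸O atom
pools bound in nitrite (2 per ion) and nitrate (3 per ion). Doubly
¹⁸O-substituted species are negligible at natural abundance, so the pools
are exact atom inventories and the stoichiometric factors (2 O per nitrite
event, 3 per nitrate, +1 water O per NXR event) are exact atom fluxes.

Fluxes: AMX = AMXNIR = k·[¹⁴NH₄⁺] (first-order ammonium consumption;
nitrite reduction locked 1:1 to it), NXR = AMXNIR·x/(1 − x) where x is the
nitrate-produced : nitrite-consumed ratio (canonically 0.3/1.3 from
1.3 NO₂⁻ + 1 NH₄⁺ → 1 N₂ + 0.3 NO₃⁻; measured 0.13–0.48). N₂ pools are
tracked for closure only — no back-reaction.

Nitrite–water O exchange is implemented as first-order relaxation of the
nitrite ¹⁸O pool toward equilibrium with water,

d[¹⁸O_NO₂]/dt |_exch = k_exch ([¹⁶O_NO₂]·R_eq − [¹⁸O_NO₂]),

with a compensating term on the ¹⁶O pool so exchange conserves nitrite O
atoms. The equilibrium target is additive in δ space,
δ¹⁸O_NO₂,eq = δ¹⁸O_H₂O + ¹⁸ε_EQ with ¹⁸ε_EQ = 13‰ (the equilibrium
enrichment of nitrite O over water O at the relevant temperature and pH),
so the fast-exchange limit pins nitrite at exactly water + 13‰. Water is
an infinite reservoir of fixed δ¹⁸O.

Default ¹⁸ε_H₂ONXR (water-O incorporation during nitrite oxidation) is
10.0‰.

## Anammox–denitrification model

Adds NAR (NO₃⁻ → NO₂⁻, first-order in [¹⁴NO₃⁻]) and DENNIR
(NO₂⁻ → gas, first-order in [¹⁴NO₂⁻]). Defaults: ¹⁵¹⁸ε_NAR = 15‰ applied
identically to N and O (this is what makes pure denitrification trace a
1:1 line in δ¹⁸O vs δ¹⁵N of nitrate), ¹⁵ε_DENNIR = 5‰, ¹⁸ε_DENNIR =
¹⁵ε_DENNIR (no independently constrained value exists; configurable).

Branching: NAR expels one of nitrate's three O atoms to water,
preferentially the light one, so the two O atoms delivered to nitrite are
*enriched* by the branching factor (default +25‰) on top of the kinetic
NAR fractionation: heavy O influx to nitrite = R_NO₃,O·2NAR·α_br/α_NAR.
The opposite composition (dividing by α_br, i.e. depleting the retained O)
reverses the sign of the exchange effect on Δ(15,18) and contradicts the
expected behaviour (offset slightly *larger* with exchange); the
enrichment convention reproduces it, with the anomaly ordering
no exchange < kinetic < full exchange.

Exchange modes: `none`; `kinetic` (relaxation as above); `full`, in which
nitrite δ¹⁸O is pinned at water + 13‰ by slaving the heavy pool to the
light pool at the fixed equilibrium ratio.

Rate laws for NAR/DENNIR are a modelling choice (no canonical values
exist for a generic environmental setting): the AMX/NAR ratio — the sweep
axis — is defined on *initial* fluxes, k_amo is set from it, and k_dennir
defaults to balancing the chain at t = 0 (DENNIR(0) = NAR(0)), which keeps
nitrite turnover active for every ratio including 0.

Runs stop when a set fraction (default 25%) of the initial nitrite pool
has been consumed, counted as *gross* consumption (∫(NXR + AMXNIR +
DENNIR) dt, both isotopes): net nitrite can grow when NAR outruns its
sinks, so a net criterion would not terminate. The integrator runs
slightly past the event and the trajectory is sampled on a uniform grid
ending exactly at the event time (dense output interpolation).

Default initial state for the simulation exercise: 10 mM each NH₄⁺, NO₂⁻,
NO₃⁻; nitrate δ¹⁵N = δ¹⁸O = 5‰ (equal values make the pure-NAR 1:1 line
exact to first order), nitrite δ¹⁸O at equilibrium with ambient water,
other δ = 0‰. Absolute concentrations are immaterial for first-order
kinetics; only ratios of rates matter.

The trajectory summary is the OLS slope of δ¹⁸O_NO₃ on δ¹⁵N_NO₃ and the
endpoint anomaly Δ(15,18) = (δ¹⁵N − δ¹⁵N₀) − (δ¹⁸O − δ¹⁸O₀) (the 18:15
ratio of the reference denitrification line is 1). The slope is declared
undefined below a 0.1‰ δ¹⁵N span.

## Parameter estimation

Stage 1 fits (k, x) to concentration series; stage 2 holds them fixed and
fits the five ε values and optionally k_exch to all δ series
simultaneously. Residuals are weighted 1/sd with the analytical precisions
as defaults (0.2‰ for δ¹⁵N of NO₂⁻/NO₃⁻, 0.5‰ for δ¹⁸O and for δ¹⁵N of
NH₄⁺; concentration sd 0.05 mM, configurable — no instrument precision is
canonical for the colorimetric concentrations). The optimiser is bounded
trust-region nonlinear least squares (`scipy.optimize.least_squares`,
ftol = gtol = 1e-6 by default, matching the historical fitting tolerance),
started from both 5‰ and 10‰ for every ε; the better objective is kept, so
the procedure is deterministic. Default ε bounds are ±100‰: the
historically used 0–60‰ window cannot express the inverse NXR effects
(−78‰) that the method itself finds, but remains available via the bounds
argument. Estimates within 0.1% of a bound are flagged (`boundary_hit`) —
the classic symptom of an unidentifiable ¹⁸ε in this design — and results
always carry convergence metadata and per-series RMSE.

The ¹⁸O-labelled-water design (δ¹⁸O_H₂O = +229‰) makes k_exch strongly
identifiable from nitrite δ¹⁸O alone, which is why the synthetic
"Experiment C" scenario exists.

## Synthetic data

The incubation generator integrates the anammox model at a chosen truth
and adds independent Gaussian noise at the stated precisions to the
sampled observations only (the truth is stored alongside). The default
scenario consumes ~70% of a 3 mM ammonium pool over a 10-point, 24 h
schedule (k = 0.05 h⁻¹, x = 0.16) with the laboratory ε set (32.5, 13.7,
−77.8, 3.1, −20.6‰) and negligible exchange; the labelled-water variant
sets δ¹⁸O_H₂O = 229‰ and k_exch = 0.02 h⁻¹. What the generator does *not*
emulate: biomass growth or decay, substrate inhibition, pH/temperature
drift, DO intrusion, autocorrelated instrument drift, or nitrite–nitrate
abiotic isotope exchange. Parameter-recovery results on these synthetics
therefore demonstrate the estimator's correctness and statistical
behaviour under the model's own assumptions, not robustness to structural
model error in real incubations.

The reactor-train generator inverts the open-system algebra exactly:
choose target apparent effects, anchor two baseline δ values, and solve
for the remaining train; recovery is exact to rounding, which is the
basis of the round-trip property tests.

## Numerics

Default integrator: adaptive embedded Runge–Kutta (RK45) with
rtol = 1e-9, atol = 1e-12; a classic fixed-step RK4 (`method="rk4"`) is
provided for cross-checking and agrees with the adaptive path to < 0.01‰
on the reference incubation scenario. Light pools at zero concentration
yield zero fluxes (ratios defined as 0); initialising a δ for an absent
species warns and ignores it. Total N (both isotopes, including the gas
sink) is conserved to < 1e-8 relative on all models; exchange conserves
nitrite O atoms exactly. The heavy/light split of an initial pool uses the
exact atom fraction R/(1 + R), making `init_state`/observables a lossless
round trip.

Two quantities carry small, well-understood offsets from their idealised
values: the simulated nitrate-yield ratio at x = 0.3/1.3 is 0.3001 rather
than 0.3000 (heavy-isotope bookkeeping in the totals), and the pure-NAR
dual-isotope slope is 0.998 rather than 1.000 (the ¹⁶O and ¹⁴N light pools
normalise slightly differently), both well inside the tolerances used in
the tests.

## Known limitations

- Open-system calculators assume true steady state and a single NT→ANX
  path; hydraulic residence-time effects are out of scope.
- The kinetic-exchange relaxation form reproduces the no-exchange and
  full-exchange limits exactly, but partial-exchange trajectories depend
  on this closure choice.
- ¹⁸ε_DENNIR and the NAR/DENNIR rate laws are documented defaults, not
  measurements.
- Nitrite–nitrate abiotic isotope exchange and sulfide-dependent (Nap)
  denitrification, which can also displace the 1:1 line, are deliberately
  not modelled.
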