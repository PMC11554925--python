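# Methods

## Scope and conventions

All concentrations are g/L (biomass gDW/L), specific rates g·gDW⁻¹·h⁻¹
except growth (h⁻¹); FBA fluxes are mmol·gDW⁻¹·h⁻¹ with molar masses
glucose 180.16, acetoin 88.11, 2,3-butanediol 90.12 g/mol used at the
interface (`dcfba.units`). Exchange signs follow the FBA convention:
negative = uptake, positive = secretion. Fed-batch "titer" is the terminal
product concentration at constant reference volume (V ≡ 1 L); feeding is
modeled as a consumption budget `Gmax` (total glucose available, g per L of
broth) rather than explicit volume dynamics. Dilution by feeding is therefore
neglected — adequate for concentrated feeds, and stated here because it is
the main idealization separating the simulated titers from a volumetric
bioreactor balance.

## Strain model (`strainmodel`)

A minimal 15-reaction / 13-metabolite core network carries glucose uptake,
glycolysis, acetoin/butanediol formation, TCA/respiration lumps, maintenance
ATP (lower bound 8.39 mmol·gDW⁻¹·h⁻¹) and a biomass reaction with an ATP
cost of 165 mmol·gATP per gDW. Genotype edits are expressed as reaction
deletions and additions (with `reverse_edit` to undo them), emulating the
knockout/insertion construction of a butanediol production strain on a core
model; any SBML model in the *E. coli* core dialect can be loaded instead.
FBA runs through cobrapy/GLPK; the test-suite cross-checks optima against an
independent `scipy.optimize.linprog` (HiGHS) formulation to 1e-6. The
minimal-oxygen-uptake LP (`min_oxygen_uptake`) pins growth and the two
product exchanges and minimizes the oxygen exchange flux ξ; it defines what
"aerobic" vs "microaerobic" means for a given rate tuple.

## Production envelope (`envelope`)

Within one aeration condition all specific rates are assumed constant. Then
X(t) is exponential and every species obeys dS/dt = q·X, so S is linear in
the cumulative biomass integral ∫X dt with slope q. Estimators:

- μ: least-squares slope of ln X vs t.
- ∫X dt: trapezoid with the exponential-consistency factor
  tanh(z/2)/(z/2), z = μ̂·Δt — exact for exponential growth at the fitted μ
  and reduces to the plain trapezoid as z → 0. The plain trapezoid has a
  (μΔt)²/12 relative bias which is visible at realistic sampling intervals.
- γ: regression of cumulative glucose consumption on ∫X dt using only
  sampling intervals that do not contain a feed pulse. An interval
  containing a pulse confounds the (known) pulse amount with the (unknown)
  consumption inside the interval; subtracting the observed jump would drop
  that consumption and bias γ toward zero, so those intervals are excluded
  from both regression axes instead.
- microaerobic α, β, δ: the net diol rate δ is fitted on acetoin +
  butanediol, which stays linear in ∫X dt for the whole stage even after
  acetoin depletion (α → 0, β → δ there). α is fitted only on the
  strictly-active sub-window (acetoin above a floor, glucose present,
  depletion-crossing interval excluded), and β = δ − α.

The envelope interpolates γ(μ), δ(μ) and min α(μ) affinely between the
microaerobic and aerobic anchors. `verify_envelope` checks FBA feasibility
of sampled points with α = min α(μ), β = δ(μ) − min α(μ); infeasible points
are reported, not raised, because an envelope fitted from noisy data is
generically infeasible against an exactly-determined small network (four
pinned exchanges on a 2-degree-of-freedom flux cone) — the report is a
diagnostic, not a gate.

## Fed-batch optimal control (`fedbatch`)

State (X, B, A, Gcon) with piecewise-constant controls μ_k and α_k per
finite element; β_k = δ(μ_k) − α_k and γ_k = γ(μ_k) follow from the
envelope ("PE-reduced" formulation: the embedded FBA subproblem collapses to
linear constraints, so the complementarity term F2 ≡ 0). The objective
F = ψ1·F1 + ψ2·F2 + ψ3·F3(T) uses F1 = titer or productivity and the
productivity integrand telescoped to its terminal value; defaults ψ2 = 10,
ψ3 = 0.1, ψ1 = 1 (titer) or 10 (productivity).

Transcription: Radau IIA orthogonal collocation, degree 3, moving finite
elements h_k ∈ [0.1, 10]·T/n_FE with Σh_k = T, state lower bounds at every
node (A ≥ 0, Gcon ≥ 0), terminal constraint Gcon(T) ≤ Gmax. The NLP is
solved with SLSQP and analytic Jacobians (an interior-point NLP solver such
as Ipopt is the more common choice for collocation but is not available in
this environment; the problem sizes here — a few hundred variables — are
well within SLSQP's reach) from a deterministic multistart: a warm start
built from the brute-force oracle plus uniform/seeded-random profiles.

Each element additionally carries the constraint μ_k·h_k ≤ 1 (nat of
growth). Without it the optimizer can inflate the objective through
discretization error: a cubic collocation polynomial overestimates e^{μt}
badly at μ·h ≳ 3, and SLSQP will happily exploit that. At μ·h ≤ 1 the
per-element interpolation error of the exponential is ≲ 2e-4 relative, so
the reported objective matches a replay of the optimal profile with the
exact piecewise kinetics. The cap does not restrict the control space (any
profile is representable after splitting elements); a feasibility pre-check
raises if μ_lb·T exceeds the total capacity n_FE nats.

The independent oracle (`two_stage_oracle`) solves the same problem
restricted to one switch time: stage 1 at μ_ub, stage 2 at μ_lb with
α = min α until acetoin depletion, closed-form piecewise exponentials with
exact event handling for acetoin depletion and glucose-budget exhaustion,
on an 801-point switch grid with a 201-point local refinement.

## Design-space mapping (`design_space`)

One oracle (optionally NLP-polished) optimization per (T, μ_lb, objective)
grid point; failures are recorded with their status, never dropped. The map
is split at the productivity-maximizing length T* (taken at the smallest
swept μ_lb); non-unimodal productivity profiles trigger a warning listing
all local maxima rather than silently picking one. The Pareto front is the
non-dominated set of (titer, productivity) pairs in the trade-off region
(O(n²) dominance check), and `fit_pareto_quadratic` reports the least-squares
quadratic and its R² on the front points.

## Continuous two-reactor process (`chemostat`)

Two equal-volume chemostats in series share one feed flux φ (per reactor
volume); the feed carries glucose only. Steady state balances
φ·(c_in − c) + q·X = 0 per species and reactor, with per-reactor (μ_i, α_i)
coupled to the envelope. The design NLP maximizes B₂ or φ·B₂ subject to
steady state, complete glucose consumption (G₂ = 0), X_i ≤ X_max
(default 25 g/L), Gφ ≤ 600 g/L and the envelope α floor, solved by SLSQP
with analytic Jacobians from analytic warm starts (the reactor-1 biomass
balance forces μ₁ = φ whenever X₁ > 0). Productivity is reported both per
reactor-2 volume (φ·B₂, the optimization target) and per total volume
(φ·B₂/2).

On the packaged fixture the productivity optimum is *interior*:
φ = μ₁ ≈ 0.404 h⁻¹, not the envelope maximum 0.6 h⁻¹. The binding
mechanism is acetoin: reactor 1 secretes acetoin at min α(μ₁)·X₁ while
reactor 2 can reconsume at most |min α(μ₂)|·X₂; pushing φ higher raises
reactor-1 supply faster than reactor-2 uptake capacity, stranding acetoin
and lowering the diol titer. The optimum was confirmed against a dense
brute-force φ-scan (the test suite keeps a 4001-point scan as an independent
oracle, agreeing with SLSQP to ≤1e-4 relative). Start-up dynamics integrate
the frozen-rate ODEs with LSODA (rtol 1e-10, atol 1e-12) over 20/φ hours.

## Synthetic data (`synthetic`)

The generator produces exact event-based two-stage trajectories (lag phase
with frozen states, aerobic stage at the aerobic anchor, microaerobic stage
at the microaerobic anchor with acetoin-depletion and glucose-exhaustion
events), pulsed feeding that restores glucose to a 20 g/L set point whenever
it falls below 0.5 g/L, and multiplicative lognormal measurement noise of
configurable CV applied per sample. Defaults (stage 1 of 6 h, sampling every
0.25 h) keep at most one feed pulse per sampling interval so that glucose
consumption is reconstructible from the sampled series — with multiple
pulses between samples the consumed mass is not identifiable from
concentrations alone, which is a property of the sampling design, not of the
estimator. The fixture anchors were calibrated once so that the
titer-optimal reference fed-batch (T = 60 h, Gmax = 200 g/L, X₀ =
0.25 gDW/L) lands within 10% of a published-scale two-stage process
(≈65 g/L, ≈1.0–1.1 g/L/h); `default_envelope(with_metadata=True)` recomputes
and reports that calibration at call time.

## Process metrics (`process_metrics`)

`compute_metrics` is deliberately plain arithmetic (P = titer/T, yields per
consumed glucose and per biomass, stage decomposition) so that the published
endpoint table can be checked without any model in the loop. `lag_correct`
back-extrapolates the observed stage-1 endpoint at the fitted μ to estimate
the lag duration t_l = t_obs − ln(X_s1/X_0)/μ, clamping small negative
estimates to zero with a warning and rejecting non-growing inputs.

## Limitations

- The envelope is affine between exactly two anchors; curvature of the true
  attainable region between the aeration regimes is not represented.
- No oxygen-transfer or reactor hydrodynamics: aeration enters only through
  which anchor the rates are drawn from; reactor 2 of the chemostat uses the
  same envelope with no adaptation lag.
- Fed-batch volume is constant (consumption-budget feeding); titers from
  strongly diluting feeds would be lower.
- FBA verification of noisy-data envelopes reports infeasibility rather than
  certifying rates; it is a screening tool for gross inconsistencies.
- All performance claims in the test suite (e.g. the ≥3× continuous vs
  fed-batch productivity ratio) are conditional on the packaged fixture
  envelope and are asserted as such, not as universal statements.
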