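# dcfba — two-stage 2,3-butanediol bioprocess design

`dcfba` is a toolbox for designing two-stage fermentation processes in which
an engineered *Escherichia coli* strain first grows aerobically and then
produces 2,3-butanediol (via its precursor acetoin) under microaerobic
conditions. It implements a dynamic-control flux-balance-analysis (dcFBA)
workflow end to end:

1. **Strain model** — a compact core stoichiometric network of the
   butanediol-producing strain (or any SBML model in the *E. coli* core
   dialect), with genotype edits (gene deletions / pathway additions) and
   LP-based flux balance analysis, including the minimal-oxygen-uptake
   computation that separates the aerobic and microaerobic regimes.
2. **Production envelope** — per-condition specific rates (growth rate μ,
   glucose uptake γ, acetoin exchange α, butanediol secretion β, net diol
   rate δ = α + β) are fitted from two-stage fermentation time series; the
   envelope interpolates γ(μ), δ(μ) and min α(μ) affinely between the
   microaerobic and aerobic anchors, and every point on the line can be
   verified for FBA feasibility against the strain model.
3. **Fed-batch optimal control** — maximize terminal titer or volumetric
   productivity over piecewise-constant growth/acetoin profiles subject to a
   glucose budget, via a Radau orthogonal-collocation NLP with moving finite
   elements (SLSQP, analytic Jacobians) cross-checked against a closed-form
   two-stage switch-time brute force.
4. **Design-space mapping** — sweep process length T and the stage-2 growth
   floor μ_lb, classify the map into a proportionality region (T < T*,
   titer and productivity rise together) and a trade-off region (T > T*),
   and fit a quadratic to the titer–productivity Pareto front.
5. **Continuous process** — steady-state design of two chemostats in series
   (aerobic growth reactor feeding a microaerobic production reactor) with
   full glucose consumption, plus dynamic start-up integration.
6. **Synthetic data** — an event-exact generator of two-stage fed-batch time
   series (lag phase, pulsed glucose feeding, multiplicative measurement
   noise) used as the test fixture for round-trip validation.

## Worked example

The packaged fixture envelope (anchors: aerobic μ = 0.60 h⁻¹,
γ = −1.875, α = 0.20, β = 0.05 g·gDW⁻¹·h⁻¹; microaerobic μ = 0.005 h⁻¹,
γ = −0.275, α = −0.10, β = 0.20 g·gDW⁻¹·h⁻¹) is calibrated so that a
reference-like titer-optimal fed-batch (T = 60 h, 200 g/L glucose budget,
X₀ = 0.25 gDW/L) lands near published two-stage performance:

```python
from dcfba.synthetic import default_envelope
from dcfba.fedbatch import FedbatchProblem, solve_fedbatch, two_stage_oracle

pe = default_envelope()
prob = FedbatchProblem(pe=pe, T=60.0, Gmax=200.0, mu_lb=pe.mu_min,
                       X0=0.25, objective="titer")
print(two_stage_oracle(prob).titer)   # 65.72 g/L
sol = solve_fedbatch(prob)
print(sol.titer, sol.productivity)    # 65.73 g/L, 1.095 g/L/h
print(sol.t_s1)                       # 6.14 h aerobic stage
```

The collocation NLP and the switch-time brute force agree to well within 1%.
The continuous two-reactor design on the same envelope:

```python
from dcfba.chemostat import optimize_chemostat, chemostat_metrics

design = optimize_chemostat(pe, objective="productivity")
print(design.phi)                     # 0.4042 h^-1 feed flux
print(design.mu)                      # (0.4042, 0.0050): aerobic R1, microaerobic R2
print(chemostat_metrics(design))
# titer 18.44 g/L, productivity 7.454 g/L/h (3.727 per total volume)
```

giving a 6.8-fold volumetric-productivity gain over the titer-optimal
fed-batch (1.095 g/L/h) on this fixture.

The same pipeline is scriptable from the shell:

```bash
dcfba build-model --builtin --out model.json
dcfba synth-data --seed 3 --out series.csv
dcfba fit-envelope --data series.csv --aerobic-window 2 8 \
      --verify model.json --out pe.json
dcfba optimize-fedbatch --pe pe.json --config run.yaml --out fb.json
dcfba map-design-space --pe pe.json --out space.csv
dcfba optimize-chemostat --pe pe.json --out chemo.json
dcfba simulate-chemostat --design chemo.json --out startup.csv
dcfba metrics --titer 65.3 --length 64.6   # -> productivity 1.01 g/L/h
```

## Reproduction

- `python -m pytest -q tests/` runs the full suite, including
  `tests/test_acceptance.py` with the end-to-end claims: published
  productivity arithmetic (±0.01 g/L/h), NLP-vs-oracle equivalence (1% on 10
  seeded configurations), design-space structure (unique T*, region
  monotonicity, acetoin depletion and glucose exhaustion at the productivity
  optimum), Pareto quadratic fit R² ≥ 0.99, the continuous process
  (steady-state residual ≤ 1e-8, start-up convergence within 1% by
  t = 20/φ, ≥3× productivity vs the titer-optimal fed-batch), and generator
  round-trip recovery (rates ≤5% at 2% noise, lag ±0.1 h).
- `python scripts/acceptance.py --seed 1 --out results/acceptance.json`
  recomputes the headline metric (t5, the Pareto-front quadratic R² in the
  trade-off region; 0.99998 on 10 front points with the packaged fixture).

See `docs/methods.md` for model assumptions, parameter provenance, numerical
choices and limitations.
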