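# Methods

This note documents the model implemented by `odxcea`: its structure and
assumptions, the parameters that matter, the synthetic inputs, numerical
choices, and known limitations. Nothing here reports an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Decision problem and strategies

A cohort of 50-year-old women with ER/PR-positive, HER2-negative,
node-negative early breast cancer is followed from surgery to death. Each
woman carries a latent joint risk group: a clinicopathologic stratum
(low/intermediate/high, from a BCSM-style score cut at 9% and 17%) crossed
with a genomic stratum (21-gene recurrence score cut at 18 and 30). The
joint distribution, chemotherapy-provision probabilities, 10-year distant-
recurrence risks, toxicity model, costs (2011 €) and utilities are held in
a validated `ParameterSet`, loadable from YAML (`data/base_case.yaml`);
probabilities may be given as fractions or percent via a `units` flag, and
unknown or missing keys are rejected with named errors.

A strategy is a Y/N mask over the three clinicopathologic strata: tested
patients incur the assay cost (3,180 €) and are treated according to their
joint group; untested patients according to per-stratum observed practice
(55.06% / 57.57% chemotherapy in the intermediate/high strata, none in the
low stratum). Treatment pattern T1 is the base case; T2 differs only in
that tested intermediate-stratum/genomic-low patients receive no
chemotherapy (13.73% under T1).

## Event model

- **Recurrence.** Time to distant recurrence is exponential with constant
  lifelong hazard `λ = −ln(1 − p₁₀)/10` from the 10-year risk of the
  patient's *assigned* risk class and chemotherapy arm. Assigned means:
  tested patients use their joint-group risk; untested patients use the
  stratum-level (marginal) risk of their chemotherapy arm. The printed
  stratum marginals equal the proportion-weighted joint risks at 10 years
  (verified to ±0.1 pp by the test suite), but the two readings differ in
  lifetime event counts because the high-risk cells of a mixture saturate
  (Jensen's inequality). The information-state reading was adopted as the
  design choice because it reproduces the per-strategy pattern of
  recurrences and recurrence deaths, which the always-latent reading
  understates by ~10–16% for the no-testing strategy. No waning of the
  recurrence hazard is modelled.
- **Survival after recurrence.** Exponential with median 25.8 months
  (`λ = ln 2 / 2.15 y ≈ 0.3224/y`), competing with other-cause death.
- **Other-cause death.** Sampled by exact inverse-CDF from the
  piecewise-exponential survival implied by an annual life table
  (constant hazard `−ln(1 − qx)` within integer-age bands; ages are
  continuous; the terminal-age band caps survival).
- **Toxicity.** Chemotherapy patients visit hospital with probability
  0.1704; given a visit, one of four costed causes is drawn with the
  printed conditional probabilities (summing to 0.7273 — the residual
  visits carry no cost and are not counted as adverse drug events, the
  only reading that reconciles the chemotherapy shares implied by the
  published adverse-event proportions). Independently, toxicity is fatal
  with probability 0.001; fatal cases die at the end of chemotherapy
  (0.5 y, or at an earlier other-cause death) and cannot recur.

## Accounting

All accruals are discounted continuously, `e^{−rt}`, r = 5%/year, from
model entry; monthly cost streams are treated as continuous rates.

- Assay and chemotherapy bundle (11,372.96 €) are lump sums at t = 0;
  the adverse-event cost falls mid-chemotherapy (t = 0.25 y) and the
  fatal-toxicity cost (36,260 €) at death.
- Pre-recurrence: follow-up 21.54 €/month plus endocrine/other treatment
  5,016.8 € spread uniformly over months 0–60; thereafter 9.79 €/month
  until recurrence or death.
- Recurrence: 248.5 € diagnosis at onset; treatment at the constant rate
  32,015.26 € per 25.8 months while alive, **capped at the 25.8-month
  reference episode**. The cap is a deliberate design choice: with
  unbounded proration the exponential mean (37.2 months = 1.44 × median)
  inflates every absolute cost by 7–13% and makes recurrence-sparing
  strategies implausibly cheap relative to the published incremental
  costs; the episode reading treats the printed figure as the cost of a
  complete treatment course.
- Utilities: first year 0.620 (chemotherapy) or 0.744 (hormone therapy
  only), 0.779 thereafter until recurrence, 0.685 after recurrence, 0 when
  dead. QALY therefore lies in [0.620 × LY, LY] for every patient — a
  property test enforces this.

## Simulation engine

The engine is vectorised NumPy; 8 strategies × 100,000 patients run in
well under a second. Eight uniform streams per patient (group, chemo,
visit, cause, fatal, recurrence, other-cause death, post-recurrence death)
are drawn once per seed, independent of strategy, so different strategies
— and perturbed parameter sets in sensitivity analysis — share **common
random numbers**; a zero-width perturbation reruns bit-identically.
`run_strategy` reports means, Monte-Carlo standard errors and event
proportions; a single-patient path (`simulate_patient`) runs through the
identical array code.

## Deterministic cohort cross-check

`odxcea.cohort` evaluates the same model by numerical integration instead
of sampling. With constant recurrence hazard λR, post-recurrence hazard λM
and other-cause survival S(t), state occupancies are closed-form
(`P_pre = S e^{−λR t}`, `P_post = S λR (e^{−λM t} − e^{−λR t})/(λR − λM)`),
and each output is a trapezoidal integral of `e^{−rt}` against these
curves on a grid of 64 steps/year aligned with the model's breakpoints.
The acceptance suite requires the microsimulation means (LY, QALY, cost)
of every strategy to agree with the integrator within 3 Monte-Carlo
standard errors at n = 100,000.

## Cost-effectiveness analysis

`build_frontier` sorts strategies by cost, removes strictly dominated ones
(≥ cost, ≤ QALY; zero-QALY-gain ties resolve in favour of the cheaper
strategy, exact ties keep the lexicographically smaller code), then
iteratively removes extendedly dominated ones until the ICER sequence is
strictly increasing. The result is validated in tests against a
brute-force greedy-hull oracle on all 255 subsets of an eight-strategy
fixture and on randomly generated point sets. Net monetary benefit and
cost-effectiveness-plane export support threshold analysis; no default
willingness-to-pay threshold is baked in.

## Sensitivity analysis

One-way analyses rerun the full pipeline per perturbation under the base
seed: age scenarios 40/70 (shifting only the life-table entry age);
discount rate 0 and 2.5% (both below the 5% base case, which sits at the
top of its stated range); chemotherapy and assay costs ±10%; utilities and
10-year recurrence risks moved to equal-tailed 95% beta intervals
re-parameterised from the point estimate and an **effective sample size**
(default 100 — an explicit assumption, since no standard errors are
published; n_eff → ∞ collapses to zero width); stratum distribution ±20%
applied to one stratum's mass at a time with within-stratum composition
preserved and renormalisation to 1. The tornado outcome is the frontier
ICER of a designated comparison strategy (default `YYY`), with a
`dominated` flag when it leaves the frontier. The T2 scenario reruns the
eight strategies under the alternative provision pattern.

## Synthetic inputs

Two inputs are generated rather than published data:

- **Life table.** A Gompertz–Makeham schedule `μ(x) = a e^{bx} + c`
  (b = 0.095/y, c = 5×10⁻⁴/y, a root-found once so that remaining life
  expectancy at age 50 is exactly 33.0 y; ages 40–105) stands in for the
  unpublished national female table and is frozen as
  `data/life_table_austria_female_2011_synthetic.csv`. It reproduces the
  broad shape of high-income female mortality (e40 ≈ 42.2, e70 ≈ 16.5)
  but not cohort effects, accident humps, or the exact old-age tail.
  Absolute LY/QALY/cost results inherit this approximation; relative
  comparisons between strategies largely cancel it.
- **Perturbed parameter sets** for sensitivity analysis, as above.

Passing tests therefore demonstrate internal consistency and reproduction
of the published results under these stand-ins, not agreement with the
original microdata.

## Numerical choices

- Terminal-age band: `qx = 1` is represented as a hazard of
  `−ln(10⁻¹²)` with death times capped at the terminal age (an atom of
  mass ~10⁻¹² is ignored); simulation, sampling and integration share the
  convention.
- Exponential draws use `−ln(u)` with `u ~ U[0,1)`; the public
  `sample_death_age` takes the CDF quantile (u → 1 approaches the
  terminal age).
- Cohort integration: trapezoid, 1/64-year steps, utility and follow-up
  breakpoints placed on the grid.
- Frontier ties are resolved deterministically (see above) so repeated
  runs and perturbations are reproducible.

## Known limitations

- Local/locoregional recurrence, end-of-life care costs and
  adverse-event disutilities are outside the model's scope.
- The recurrence hazard is extrapolated as constant for life from a
  10-year risk; real hazards wane.
- The published record this model reproduces contains internal tensions
  the package does not attempt to tune away: the published per-strategy
  outcome deltas attributable to testing the *low* stratum are about
  twice what the published risk/provision tables can generate under any
  reading (the implied tested-low 10-year risk lies below the
  mathematical floor of the printed cells), and the published
  single-stratum gains do not sum to the published all-testing gain.
  Consequently this implementation yields a smaller all-testing (`YYY`)
  benefit, a correspondingly higher ICER for extending testing to the
  low stratum, and an efficiency frontier that can retain the
  intermediate-only strategy (`NYN`), whose published exclusion rests on
  an extended-dominance margin smaller than the published table's own
  Monte-Carlo noise.
- Chemotherapy provision probabilities are observed practice, not
  guideline rules; they embed the behaviour of one clinical setting.
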