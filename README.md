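# odxcea

Discrete-event microsimulation of **test-treatment strategies for adjuvant
chemotherapy in early breast cancer**, with full cost-effectiveness and
one-way sensitivity analysis.

## The problem

Women with ER/PR-positive, HER2-negative, node-negative early breast cancer
face an uncertain chemotherapy decision after surgery: chemotherapy lowers
the risk of distant (metastatic) recurrence but carries toxicity, cost and
quality-of-life losses, and most patients would never have recurred anyway.
Two risk tools inform the decision:

- a free clinicopathologic score (breast-cancer-specific mortality, *BCSM*),
  categorised **low** (< 9%), **intermediate** (9–17%), **high** (≥ 17%);
- the 21-gene expression assay (recurrence score *RS* 0–100), categorised
  **low** (< 18), **intermediate** (18–30), **high** (≥ 30) — accurate but
  costly (3,180 € per test).

A *strategy* is a three-letter Y/N mask saying which clinicopathologic
strata are sent for genomic testing before the chemotherapy decision: `NNN`
(never test) through `YYY` (test everyone), eight strategies in all.
Tested patients receive chemotherapy according to their joint (3 × 3) risk
group; untested patients according to observed per-stratum practice.

## The model

Each simulated woman enters at age 50 post-surgery and is followed for
life. Time to distant recurrence is exponential with a constant hazard
`λ = −ln(1 − p₁₀)/10` derived from the 10-year recurrence risk `p₁₀` of her
assigned risk class and chemotherapy arm; survival after recurrence is
exponential with median 25.8 months, competing with other-cause death drawn
from a female life table; chemotherapy carries a 17.04% hospital-visit
toxicity risk (four costed causes) and 0.1% fatal toxicity. Life-years,
QALYs (utilities 0.744/0.620 in the first year, 0.779 pre-recurrence,
0.685 post-recurrence) and direct costs (2011 euros: assay, chemotherapy
bundle, follow-up and endocrine therapy streams, recurrence diagnosis and
treatment episode) are discounted continuously at 5%/year.

Strategies are then compared on the cost-effectiveness plane: strictly and
extendedly dominated strategies are eliminated and incremental
cost-effectiveness ratios (ICER, € per QALY gained) are computed along the
efficiency frontier. All eight strategies are simulated under common random
numbers, so incremental comparisons are low-variance. A deterministic
continuous-time cohort integrator (`odxcea.cohort`) computes the same
expectations without sampling and serves as a cross-model check.

Because the national life table behind the original analysis is not
published, the package bundles a synthetic Gompertz–Makeham schedule
(`μ(x) = a·e^{bx} + c`) calibrated so that remaining life expectancy at age
50 is 33 years. See `docs/methods.md` for every modelling choice.

## Worked example

```python
import odxcea as ox

params = ox.default_parameters()          # Austrian base case, pattern T1
table = ox.default_life_table()           # bundled synthetic schedule
results = ox.run_all_strategies(params, table, n=100_000, seed=1)
cea = ox.build_frontier(results)
print(cea.table.round(3).to_string(index=False))
print("frontier:", " -> ".join(cea.frontier))
```

```
strategy      cost   qaly               status  delta_cost  delta_qaly      icer
     NNN 12648.375 10.827             frontier         NaN         NaN       NaN
     NYN 12801.708 10.938             frontier     153.333       0.112  1370.838
     NNY 13060.426 11.019 extendedly_dominated         NaN         NaN       NaN
     NYY 13213.759 11.130             frontier     412.051       0.192  2145.839
     YNN 15045.290 10.880            dominated         NaN         NaN       NaN
     YYN 15198.623 10.992            dominated         NaN         NaN       NaN
     YNY 15457.341 11.072            dominated         NaN         NaN       NaN
     YYY 15610.674 11.184             frontier    2396.915       0.053 44854.088
frontier: NNN -> NYN -> NYY -> YYY
```

Reading the output: never-test (`NNN`) costs ~12,650 € and yields ~10.83
discounted QALYs per patient. Testing the intermediate and high strata
(`NYY`) buys ~0.30 extra QALYs for ~565 € more; extending testing to
everyone (`YYY`) adds a further 0.053 QALYs at ~45,000 €/QALY. The four
strategies that test the low stratum without testing both other strata are
dominated — they cost more and deliver less than combinations on the
frontier. Per-strategy event outcomes (adverse drug events, recurrences,
recurrence deaths) are on each `StrategyResult`.

The same pipeline is scriptable from the shell:

```sh
odxcea run --n 100000 --seed 1 --out results/      # base case + CEA tables
odxcea scenario --seed 1 --out results/            # T2 treatment pattern
odxcea sa --seed 1 --out results/                  # tornado data
odxcea export-params --out parameters.csv          # audit the parameter set
```

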