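"""One-way sensitivity analyses and the alternative treatment-pattern scenario.

Each analysis perturbs exactly one parameter (or one coherent block, e.g.
all 10-year recurrence risks to the same confidence bound), reruns the full
eight-strategy pipeline under the *same* random draws as the base case, and
records the cost-effectiveness outcome of a designated comparison.  With
common random numbers, a zero-width perturbation returns bit-identical
results, so every difference in a tornado diagram is attributable to the
parameter alone.

Confidence intervals for probabilities and utilities assume a beta
distribution re-parameterised from the point estimate ``m`` and an
*effective sample size* ``n_eff`` (``alpha = m * n_eff``,
``beta = (1 - m) * n_eff``).  The published ranges give no standard errors,
so ``n_eff`` (default 100) is an explicit modelling assumption, not a
reproduction of any source value.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .cea import CEATable, build_frontier
from .mortality import LifeTable
from .parameters import AoCategory, ParameterSet
from .simulate import run_all_strategies

__all__ = [
    "SAParameterSpec",
    "DEFAULT_SPECS",
    "beta_interval",
    "perturb",
    "one_way_sa",
    "run_scenario_t2",
]


@dataclass(frozen=True)
class SAParameterSpec:
    """One tornado bar: which parameter moves, and how.

    ``kind`` selects the rule; ``field`` narrows it (a utility name or a
    clinicopathologic stratum).  ``n_eff`` is the beta effective sample
    size where the rule is a 95% confidence interval.
    """

    kind: str  # age | discount_rate | chemo_cost | odx_cost | utility | ao_distribution | recurrence_no_chemo | recurrence_chemo
    field: str | None = None
    n_eff: float = 100.0

    @property
    def label(self) -> str:
        return self.kind if self.field is None else f"{self.kind}:{self.field}"


#: The published one-way analysis set, in its content-specific order:
#: age, discount rate, chemotherapy cost, assay cost, utilities,
#: risk-group distribution, recurrence probabilities.
DEFAULT_SPECS: tuple[SAParameterSpec, ...] = (
    SAParameterSpec("age"),
    SAParameterSpec("discount_rate"),
    SAParameterSpec("chemo_cost"),
    SAParameterSpec("odx_cost"),
    SAParameterSpec("utility", "first_year_hormone"),
    SAParameterSpec("utility", "first_year_chemo"),
    SAParameterSpec("utility", "pre_recurrence"),
    SAParameterSpec("utility", "post_recurrence"),
    SAParameterSpec("ao_distribution", "low"),
    SAParameterSpec("ao_distribution", "intermediate"),
    SAParameterSpec("ao_distribution", "high"),
    SAParameterSpec("recurrence_no_chemo"),
    SAParameterSpec("recurrence_chemo"),
)


def beta_interval(mean: float, n_eff: float, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed beta interval for a probability from mean and ``n_eff``.

    Degenerate cases (``mean`` of 0 or 1, or ``n_eff`` -> infinity) collapse
    to the mean.
    """
    if not 0.0 <= mean <= 1.0:
        raise ValueError("mean must be a probability")
    if mean in (0.0, 1.0) or not np.isfinite(n_eff):
        return mean, mean
    if n_eff <= 0:
        raise ValueError("n_eff must be positive")
    a, b = mean * n_eff, (1.0 - mean) * n_eff
    tail = (1.0 - level) / 2.0
    lo, hi = stats.beta.ppf([tail, 1.0 - tail], a, b)
    return float(lo), float(hi)


def _clip01(x: float) -> float:
    return min(max(x, 0.0), 1.0)


def _perturb_prob_map(mapping, n_eff: float, upper: bool, cap: float = 1.0):
    out = {}
    for k, v in mapping.items():
        lo, hi = beta_interval(v, n_eff)
        out[k] = min(hi if upper else lo, cap)
    return out


def perturb(params: ParameterSet, spec: SAParameterSpec, direction: str) -> ParameterSet:
    """A new :class:`ParameterSet` with only the parameter(s) of *spec* moved.

    ``direction`` is ``"low"`` or ``"high"``.  For age the scenarios are 40
    and 70 years; for the discount rate 0 and 2.5% (both below the 5% base
    case); costs move +/-10%; utilities and recurrence risks to their beta
    95% bounds; a clinicopathologic stratum's mass +/-20% with the joint
    distribution rescaled within rows and renormalised.
    """
    if direction not in ("low", "high"):
        raise ValueError("direction must be 'low' or 'high'")
    up = direction == "high"
    kind = spec.kind

    if kind == "age":
        return replace(params, econ=replace(params.econ, cohort_age=70.0 if up else 40.0))
    if kind == "discount_rate":
        return replace(
            params, econ=replace(params.econ, discount_rate=0.025 if up else 0.0)
        )
    if kind == "chemo_cost":
        f = 1.1 if up else 0.9
        return replace(
            params, costs=replace(params.costs, chemo_total=params.costs.chemo_total * f)
        )
    if kind == "odx_cost":
        f = 1.1 if up else 0.9
        return replace(
            params, costs=replace(params.costs, odx_test=params.costs.odx_test * f)
        )
    if kind == "utility":
        if spec.field is None:
            raise ValueError("utility spec needs a field")
        current = getattr(params.utilities, spec.field)
        lo, hi = beta_interval(current, spec.n_eff)
        return replace(
            params,
            utilities=replace(params.utilities, **{spec.field: hi if up else lo}),
        )
    if kind == "ao_distribution":
        if spec.field is None:
            raise ValueError("ao_distribution spec needs a stratum field")
        stratum = AoCategory[spec.field]
        f = 1.2 if up else 0.8
        scaled = {
            g: p * (f if g.ao == stratum else 1.0)
            for g, p in params.group_proportions.items()
        }
        total = sum(scaled.values())
        props = {g: p / total for g, p in scaled.items()}
        return replace(params, group_proportions=props)
    if kind in ("recurrence_no_chemo", "recurrence_chemo"):
        risks = params.risks
        # keep the 10-year risks strictly below 1 so the hazard stays finite
        cap = 1.0 - 1e-9
        if kind == "recurrence_no_chemo":
            risks = replace(
                risks,
                p10_no_chemo=_perturb_prob_map(risks.p10_no_chemo, spec.n_eff, up, cap),
                marginal_no_chemo=_perturb_prob_map(
                    risks.marginal_no_chemo, spec.n_eff, up, cap
                ),
            )
        else:
            risks = replace(
                risks,
                p10_chemo=_perturb_prob_map(risks.p10_chemo, spec.n_eff, up, cap),
                marginal_chemo=_perturb_prob_map(
                    risks.marginal_chemo, spec.n_eff, up, cap
                ),
            )
        return replace(params, risks=risks)
    raise ValueError(f"unknown sensitivity parameter kind {spec.kind!r}")


def _comparison_outcome(cea: CEATable, strategy: str) -> tuple[float, bool]:
    """(ICER of *strategy* vs the previous frontier member, dominated?)."""
    if strategy not in cea.frontier:
        return float("nan"), True
    return cea.icer(strategy), False


def one_way_sa(
    base: ParameterSet,
    table: LifeTable,
    specs: tuple[SAParameterSpec, ...] = DEFAULT_SPECS,
    comparison: str = "YYY",
    n: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Tornado data: one row per spec, low/high/base comparison outcomes.

    The outcome is the ICER of *comparison* versus the previous strategy on
    the frontier (NaN with ``dominated=True`` when it falls off the
    frontier).  All runs reuse the base seed (common random numbers).
    """
    base_cea = build_frontier(run_all_strategies(base, table, n=n, seed=seed))
    base_icer, base_dom = _comparison_outcome(base_cea, comparison)
    rows = []
    for spec in specs:
        out = {"parameter": spec.label, "base": base_icer, "base_dominated": base_dom}
        for direction in ("low", "high"):
            p = perturb(base, spec, direction)
            cea = build_frontier(run_all_strategies(p, table, n=n, seed=seed))
            icer, dom = _comparison_outcome(cea, comparison)
            out[direction] = icer
            out[f"{direction}_dominated"] = dom
        rows.append(out)
    return pd.DataFrame(
        rows,
        columns=[
            "parameter",
            "low",
            "high",
            "base",
            "low_dominated",
            "high_dominated",
            "base_dominated",
        ],
    )


def run_scenario_t2(
    base: ParameterSet,
    table: LifeTable,
    n: int | None = None,
    seed: int = 0,
) -> CEATable:
    """The alternative treatment-pattern scenario (T2).

    Identical to the base case except that intermediate-stratum /
    genomic-low patients receive no chemotherapy when tested.
    """
    if base.pattern.id != "T1":
        raise ValueError("the T2 scenario perturbs a T1 base case")
    t2 = base.with_pattern("T2")
    return build_frontier(run_all_strategies(t2, table, n=n, seed=seed))
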