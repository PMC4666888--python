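"""Patient-level discrete-event simulation of the test-treatment strategies.

Each simulated woman enters post-surgery at the cohort age, is assigned a
latent joint risk group, is genomically tested if her clinicopathologic
stratum is flagged by the strategy mask, receives chemotherapy with the
provision probability of the applicable row, and is then followed through
recurrence-free time, possible distant recurrence, and death (from other
causes, from fatal chemotherapy toxicity, or from breast cancer after
recurrence).  Times to recurrence and to post-recurrence death are
exponential; other-cause death comes from the life table.  Life-years,
quality-adjusted life-years and costs are discounted continuously from
model entry.

The engine is fully vectorised; per-patient random draws depend only on
(seed, patient index), so running different strategies with the same seed
uses common random numbers, which stabilises incremental comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mortality import LifeTable, sample_death_times
from .parameters import (
    ALL_STRATEGIES,
    GROUPS,
    ParameterSet,
    StrategyCode,
    chemo_probability,
)

__all__ = [
    "PatientOutcome",
    "StrategyResult",
    "hazard_from_p10",
    "recurrence_survival_rate",
    "sample_toxicity",
    "discounted_interval",
    "simulate_patient",
    "run_strategy",
    "run_all_strategies",
]


def hazard_from_p10(p10: float) -> float:
    """Constant recurrence hazard implied by a 10-year risk.

    ``lambda = -ln(1 - p10) / 10`` per year, applied lifelong (exponential
    time to distant recurrence).
    """
    if not 0.0 <= p10 < 1.0:
        raise ValueError(f"10-year risk must be in [0, 1), got {p10}")
    return -math.log1p(-p10) / 10.0


def recurrence_survival_rate(median_months: float) -> float:
    """Exponential death rate after distant recurrence, from median survival.

    ``lambda = ln 2 / (median / 12)`` per year.
    """
    if median_months <= 0:
        raise ValueError("median survival must be positive")
    return math.log(2.0) / (median_months / 12.0)


def sample_toxicity(tox, u1: float, u2: float, u3: float) -> tuple[str | None, bool]:
    """Toxicity outcome for one chemotherapy patient from three uniforms.

    ``u1`` decides the hospital visit, ``u2`` its cause (visits beyond the
    costed causes carry no cost and no adverse-event flag), ``u3`` fatal
    toxicity (independent of the visit).
    """
    cause: str | None = None
    if u1 < tox.p_hospital_visit:
        acc = 0.0
        for name, p in tox.cause_probs.items():
            acc += p
            if u2 < acc:
                cause = name
                break
    return cause, u3 < tox.p_fatal


def discounted_interval(value_per_year: float, t0, t1, r: float):
    """Present value of a constant stream over ``[t0, t1]`` years.

    Continuous discounting: ``value * (e^(-r t0) - e^(-r t1)) / r`` for
    ``r > 0``, the plain duration for ``r = 0``.  Vectorised over times.
    """
    t0 = np.asarray(t0, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    if np.any(t1 < t0):
        raise ValueError("interval end must not precede its start")
    if r < 0:
        raise ValueError("discount rate must be >= 0")
    if r == 0.0:
        out = value_per_year * (t1 - t0)
    else:
        out = value_per_year * (np.exp(-r * t0) - np.exp(-r * t1)) / r
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PatientOutcome:
    """One simulated trajectory, discounted to model entry."""

    discounted_ly: float
    discounted_qaly: float
    discounted_cost: float
    got_chemo: bool
    got_test: bool
    ade_cause: str | None
    fatal_toxicity: bool
    recurred: bool
    died_of_recurrence: bool
    death_time: float


@dataclass(frozen=True)
class StrategyResult:
    """Per-strategy summary over ``n`` simulated patients."""

    strategy: StrategyCode
    n: int
    mean_ly: float
    mean_qaly: float
    mean_cost: float
    se_ly: float
    se_qaly: float
    se_cost: float
    p_test: float
    p_chemo: float
    p_ade: float
    p_recurrence: float
    p_death_recurrence: float
    p_fatal_toxicity: float

    @property
    def deaths_from_recurrence_per_100k(self) -> float:
        return self.p_death_recurrence * 100_000

    def to_dict(self) -> dict:
        d = {"strategy": self.strategy.name}
        for k in (
            "n",
            "mean_ly",
            "mean_qaly",
            "mean_cost",
            "se_ly",
            "se_qaly",
            "se_cost",
            "p_test",
            "p_chemo",
            "p_ade",
            "p_recurrence",
            "p_death_recurrence",
            "p_fatal_toxicity",
        ):
            d[k] = getattr(self, k)
        return d


# ---------------------------------------------------------------------------
# Vectorised engine

_N_STREAMS = 8  # group, chemo, visit, cause, fatal, recurrence, other-death, bc-death


def _draw_uniforms(n: int, seed: int) -> np.ndarray:
    """The per-patient uniforms, shape (8, n); independent of strategy."""
    rng = np.random.default_rng(seed)
    return rng.random((_N_STREAMS, n))


def _simulate_arrays(
    params: ParameterSet, strategy: StrategyCode, table: LifeTable, u: np.ndarray
) -> dict[str, np.ndarray]:
    """Core trajectory arithmetic on pre-drawn uniforms (shape (8, n))."""
    econ = params.econ
    costs = params.costs
    util = params.utilities
    tox = params.toxicity
    r = econ.discount_rate
    n = u.shape[1]

    u_group, u_chemo, u_visit, u_cause, u_fatal, u_rec, u_od, u_bc = u

    # (1) latent joint risk group
    props = np.array([params.group_proportions[g] for g in GROUPS])
    props = props / props.sum()
    group = np.searchsorted(np.cumsum(props), u_group, side="right")
    group = np.minimum(group, len(GROUPS) - 1)
    ao = np.array([int(g.ao) for g in GROUPS])[group]

    # (2) testing per strategy mask
    mask = np.array(strategy.mask, dtype=bool)
    tested = mask[ao]

    # (3) chemotherapy provision
    p_tested = np.array([chemo_probability(g, True, params.pattern) for g in GROUPS])
    p_untested = np.array([chemo_probability(g, False, params.pattern) for g in GROUPS])
    p_chemo = np.where(tested, p_tested[group], p_untested[group])
    chemo = u_chemo < p_chemo

    # (4) toxicity: hospital visit, costed cause, independent fatal toxicity
    cause_names = list(tox.cause_probs)
    cause_cum = np.cumsum([tox.cause_probs[c] for c in cause_names])
    cause_cost = np.array([tox.cost_by_cause[c] for c in cause_names])
    visit = chemo & (u_visit < tox.p_hospital_visit)
    cause_idx = np.searchsorted(cause_cum, u_cause, side="right")
    ade = visit & (cause_idx < len(cause_names))
    ade_cost = np.where(ade, cause_cost[np.minimum(cause_idx, len(cause_names) - 1)], 0.0)
    fatal = chemo & (u_fatal < tox.p_fatal)
    t_chemo_end = econ.chemo_duration_months / 12.0
    t_ade = t_chemo_end / 2.0

    # (5) event times.  The recurrence hazard follows the risk class the
    # patient was actually assigned: the joint group when tested, the
    # stratum-level (clinicopathologic) risk when untested.
    lam_joint = np.array(
        [
            [hazard_from_p10(params.risks.p10(g, False)) for g in GROUPS],
            [hazard_from_p10(params.risks.p10(g, True)) for g in GROUPS],
        ]
    )
    lam_marg = np.array(
        [
            [hazard_from_p10(params.risks.marginal_no_chemo[a]) for a in sorted(set(g.ao for g in GROUPS))],
            [hazard_from_p10(params.risks.marginal_chemo[a]) for a in sorted(set(g.ao for g in GROUPS))],
        ]
    )
    lam_rec = np.where(
        tested, lam_joint[chemo.astype(int), group], lam_marg[chemo.astype(int), ao]
    )
    with np.errstate(divide="ignore"):
        t_rec = np.where(lam_rec > 0, -np.log(u_rec) / np.where(lam_rec > 0, lam_rec, 1.0), np.inf)
    t_od = sample_death_times(table, econ.cohort_age, -np.log(u_od))
    lam_bc = recurrence_survival_rate(econ.median_survival_recurrence_months)
    t_bc_after = -np.log(u_bc) / lam_bc

    # event resolution: fatal-toxicity patients die at end of chemo (or at an
    # earlier other-cause death) and cannot recur
    t_fatal = np.where(fatal, t_chemo_end, np.inf)
    recurred = ~fatal & (t_rec < t_od)
    t_rec_eff = np.where(recurred, t_rec, np.inf)
    death = np.where(
        fatal,
        np.minimum(t_fatal, t_od),
        np.where(recurred, np.minimum(t_rec + t_bc_after, t_od), t_od),
    )
    died_of_rec = recurred & (t_rec + t_bc_after < t_od)
    # realized cause of death: 0 = other causes, 1 = recurrence, 2 = fatal toxicity
    death_cause = np.zeros(n, dtype=np.int8)
    death_cause[died_of_rec] = 1
    death_cause[fatal & (t_fatal <= t_od)] = 2

    # (6)-(8) discounted accruals
    pre_end = np.minimum(t_rec_eff, death)  # leave pre-recurrence state

    def disc(t0, t1):
        t0 = np.asarray(t0, dtype=float)
        t1 = np.maximum(np.asarray(t1, dtype=float), t0)
        if r == 0.0:
            return t1 - t0
        return (np.exp(-r * t0) - np.exp(-r * t1)) / r

    ly = disc(0.0, death)

    u_first = np.where(chemo, util.first_year_chemo, util.first_year_hormone)
    qaly = (
        u_first * disc(0.0, np.minimum(1.0, pre_end))
        + util.pre_recurrence * disc(1.0, np.maximum(1.0, pre_end))
        + util.post_recurrence * np.where(recurred, disc(np.minimum(t_rec_eff, death), death), 0.0)
    )

    t_switch = econ.followup_switch_months / 12.0
    fu_rate1 = (
        costs.followup_per_month_first5y * 12.0
        + costs.other_treatment_5y_total / t_switch
    )
    fu_rate2 = costs.followup_per_month_after5y * 12.0
    rec_rate = costs.recurrence_treatment_total / (costs.recurrence_treatment_months / 12.0)
    disc_factor = (lambda t: np.exp(-r * t)) if r > 0 else (lambda t: np.ones_like(np.asarray(t, dtype=float)))

    cost = (
        tested * costs.odx_test
        + chemo * costs.chemo_total
        + ade_cost * float(np.exp(-r * t_ade))
        + np.where(fatal, tox.cost_fatal * disc_factor(death), 0.0)
        + fu_rate1 * disc(0.0, np.minimum(t_switch, pre_end))
        + fu_rate2 * disc(t_switch, np.maximum(t_switch, pre_end))
        + np.where(
            recurred,
            costs.recurrence_diagnosis * disc_factor(np.minimum(t_rec_eff, death))
            # treatment episode: constant rate while alive, up to the costed
            # reference duration (longer survivors do not accrue beyond it)
            + rec_rate
            * disc(
                np.minimum(t_rec_eff, death),
                np.minimum(
                    np.minimum(t_rec_eff, death)
                    + costs.recurrence_treatment_months / 12.0,
                    death,
                ),
            ),
            0.0,
        )
    )

    cause_labels = np.array(cause_names + [""], dtype=object)
    return {
        "ly": ly,
        "qaly": qaly,
        "cost": cost,
        "tested": tested,
        "chemo": chemo,
        "ade": ade,
        "ade_cause": cause_labels[np.where(ade, np.minimum(cause_idx, len(cause_names) - 1), len(cause_names))],
        "fatal": fatal,
        "recurred": recurred,
        "died_of_recurrence": died_of_rec,
        "death_cause": death_cause,
        "death_time": death,
    }


def simulate_patient(
    params: ParameterSet,
    strategy: StrategyCode,
    table: LifeTable,
    rng: np.random.Generator,
) -> PatientOutcome:
    """Simulate a single trajectory, drawing its uniforms from *rng*."""
    u = rng.random((_N_STREAMS, 1))
    res = _simulate_arrays(params, strategy, table, u)
    cause = res["ade_cause"][0]
    return PatientOutcome(
        discounted_ly=float(res["ly"][0]),
        discounted_qaly=float(res["qaly"][0]),
        discounted_cost=float(res["cost"][0]),
        got_chemo=bool(res["chemo"][0]),
        got_test=bool(res["tested"][0]),
        ade_cause=cause if cause else None,
        fatal_toxicity=bool(res["fatal"][0]),
        recurred=bool(res["recurred"][0]),
        died_of_recurrence=bool(res["died_of_recurrence"][0]),
        death_time=float(res["death_time"][0]),
    )


def _summarise(strategy: StrategyCode, res: dict[str, np.ndarray]) -> StrategyResult:
    n = len(res["ly"])
    sqrt_n = math.sqrt(n)

    def mean_se(x):
        return float(np.mean(x)), float(np.std(x, ddof=1) / sqrt_n) if n > 1 else 0.0

    m_ly, se_ly = mean_se(res["ly"])
    m_q, se_q = mean_se(res["qaly"])
    m_c, se_c = mean_se(res["cost"])
    return StrategyResult(
        strategy=strategy,
        n=n,
        mean_ly=m_ly,
        mean_qaly=m_q,
        mean_cost=m_c,
        se_ly=se_ly,
        se_qaly=se_q,
        se_cost=se_c,
        p_test=float(np.mean(res["tested"])),
        p_chemo=float(np.mean(res["chemo"])),
        p_ade=float(np.mean(res["ade"])),
        p_recurrence=float(np.mean(res["recurred"])),
        p_death_recurrence=float(np.mean(res["died_of_recurrence"])),
        p_fatal_toxicity=float(np.mean(res["fatal"])),
    )


def run_strategy(
    params: ParameterSet,
    strategy: StrategyCode,
    table: LifeTable,
    n: int | None = None,
    seed: int = 0,
    return_patients: bool = False,
):
    """Simulate *n* patients under one strategy.

    With a fixed seed the underlying uniforms do not depend on the strategy,
    so calling this for several strategies with the same seed applies common
    random numbers.
    """
    if n is None:
        n = params.econ.n_patients
    if n < 1:
        raise ValueError("n must be >= 1")
    res = _simulate_arrays(params, strategy, table, _draw_uniforms(n, seed))
    summary = _summarise(strategy, res)
    if return_patients:
        return summary, res
    return summary


def run_all_strategies(
    params: ParameterSet,
    table: LifeTable,
    n: int | None = None,
    seed: int = 0,
    strategies: tuple[StrategyCode, ...] = ALL_STRATEGIES,
) -> list[StrategyResult]:
    """All strategies under common random numbers (one draw set, reused)."""
    if n is None:
        n = params.econ.n_patients
    u = _draw_uniforms(n, seed)
    return [_summarise(s, _simulate_arrays(params, s, table, u)) for s in strategies]


def results_frame(results: list[StrategyResult]) -> pd.DataFrame:
    """Per-strategy results as a tidy DataFrame (one row per strategy)."""
    return pd.DataFrame([r.to_dict() for r in results])
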