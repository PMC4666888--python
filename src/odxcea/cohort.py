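"""Deterministic continuous-time cohort evaluation of the same model.

This module computes the *expected* discounted life-years, QALYs and costs
of each strategy by numerical integration of state-occupancy curves, using
exactly the hazard, utility and cost schedule of the discrete-event engine
but no random numbers.  It serves as an independent cross-model check on
the microsimulation (and as a fast way to get noise-free expectations).

With a constant recurrence hazard ``lR``, a constant post-recurrence death
hazard ``lM`` and other-cause survival ``S(t)`` from the life table, the
state occupancies have closed form:

    pre-recurrence :  P_pre(t)  = S(t) * exp(-lR t)
    post-recurrence:  P_post(t) = S(t) * lR (exp(-lM t) - exp(-lR t)) / (lR - lM)

and every output is an integral of ``exp(-r t)`` against these curves (or
against the recurrence incidence ``lR exp(-lR t) S(t)``), evaluated with
the trapezoidal rule on a grid aligned with the model's breakpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mortality import LifeTable
from .parameters import (
    GROUPS,
    ParameterSet,
    StrategyCode,
    chemo_probability,
    strategy_requires_test,
)
from .simulate import hazard_from_p10, recurrence_survival_rate

__all__ = ["CohortExpectation", "cohort_expectations"]


@dataclass(frozen=True)
class CohortExpectation:
    """Expected (per-patient) outcomes of one strategy."""

    strategy: StrategyCode
    ly: float
    qaly: float
    cost: float
    p_test: float
    p_chemo: float
    p_ade: float
    p_recurrence: float
    p_death_recurrence: float


def _trapz(y: np.ndarray, dt: float) -> float:
    return float(np.trapezoid(y, dx=dt))


def cohort_expectations(
    params: ParameterSet,
    strategy: StrategyCode,
    table: LifeTable,
    steps_per_year: int = 64,
) -> CohortExpectation:
    """Expected outcomes by deterministic integration (no sampling).

    ``steps_per_year`` must place the model's breakpoints (mid-chemo,
    end-of-chemo, first year, follow-up switch) on the grid; the default of
    64 does.
    """
    econ, costs, util, tox = params.econ, params.costs, params.utilities, params.toxicity
    r = econ.discount_rate
    dt = 1.0 / steps_per_year

    horizon = table.terminal_age - econ.cohort_age
    t = np.arange(0.0, horizon + dt / 2, dt)
    times, cum = table.cumulative_hazard_from(econ.cohort_age)
    H = np.interp(t, times, cum)
    S_od = np.exp(-H)
    disc = np.exp(-r * t)

    lam_bc = recurrence_survival_rate(econ.median_survival_recurrence_months)
    t_chemo_end = econ.chemo_duration_months / 12.0
    t_ade = t_chemo_end / 2.0
    t_switch = econ.followup_switch_months / 12.0
    fu_rate1 = costs.followup_per_month_first5y * 12.0 + costs.other_treatment_5y_total / t_switch
    fu_rate2 = costs.followup_per_month_after5y * 12.0
    rec_rate = costs.recurrence_treatment_total / (costs.recurrence_treatment_months / 12.0)
    exp_ade_cost = tox.p_hospital_visit * sum(
        tox.cause_probs[c] * tox.cost_by_cause[c] for c in tox.cause_probs
    )

    i_year1 = int(round(1.0 / dt))
    i_switch = int(round(t_switch / dt))
    i_chemo_end = int(round(t_chemo_end / dt))

    def split_integral(w: np.ndarray, i_cut: int) -> tuple[float, float]:
        """Integral of w*disc over [0, t_cut] and [t_cut, horizon]."""
        a = _trapz((w * disc)[: i_cut + 1], dt)
        b = _trapz((w * disc)[i_cut:], dt)
        return a, b

    def nonfatal_path(lam_rec: float, u_first: float) -> dict[str, float]:
        cap = costs.recurrence_treatment_months / 12.0
        if lam_rec > 0:
            p_pre = S_od * np.exp(-lam_rec * t)
            p_post = (
                S_od
                * lam_rec
                * (np.exp(-lam_bc * t) - np.exp(-lam_rec * t))
                / (lam_rec - lam_bc)
            )
            f_rec = lam_rec * np.exp(-lam_rec * t) * S_od
            # occupancy restricted to within `cap` years of recurrence onset
            # (the costed treatment episode)
            lo = np.maximum(0.0, t - cap)
            d = lam_rec - lam_bc
            p_post_cap = (
                S_od
                * lam_rec
                * np.exp(-lam_bc * t)
                * (np.exp(-d * lo) - np.exp(-d * t))
                / d
            )
        else:
            p_pre = S_od
            p_post = np.zeros_like(t)
            f_rec = np.zeros_like(t)
            p_post_cap = np.zeros_like(t)
        ly = _trapz((p_pre + p_post) * disc, dt)
        q_pre_1, q_pre_rest = split_integral(p_pre, i_year1)
        qaly = (
            u_first * q_pre_1
            + util.pre_recurrence * q_pre_rest
            + util.post_recurrence * _trapz(p_post * disc, dt)
        )
        fu_a, fu_b = split_integral(p_pre, i_switch)
        cost = (
            fu_rate1 * fu_a
            + fu_rate2 * fu_b
            + costs.recurrence_diagnosis * _trapz(f_rec * disc, dt)
            + rec_rate * _trapz(p_post_cap * disc, dt)
        )
        p_rec = _trapz(f_rec, dt)
        p_die_rec = lam_bc * _trapz(p_post, dt)
        return {"ly": ly, "qaly": qaly, "cost": cost, "p_rec": p_rec, "p_die_rec": p_die_rec}

    # fatal-toxicity path: alive (pre-recurrence occupancy) until end of chemo
    # or an earlier other-cause death; the fatal treatment cost falls at death
    alive_f = S_od[: i_chemo_end + 1]
    disc_f = disc[: i_chemo_end + 1]
    ly_fatal = _trapz(alive_f * disc_f, dt)
    qaly_fatal = util.first_year_chemo * ly_fatal
    # E[e^{-r * min(t_chemo_end, T_od)}]: integrate density of T_od plus the
    # surviving mass at the cut-off
    band = np.minimum(np.searchsorted(times, t[: i_chemo_end + 1], side="right") - 1, len(times) - 2)
    haz_band = (np.diff(cum) / np.diff(times))[band]
    f_od = haz_band * alive_f
    e_disc_death_fatal = _trapz(f_od * disc_f, dt) + float(S_od[i_chemo_end] * disc[i_chemo_end])
    cost_fatal_path = (
        fu_rate1 * _trapz(alive_f * disc_f, dt) + tox.cost_fatal * e_disc_death_fatal
    )
    fatal_path = {
        "ly": ly_fatal,
        "qaly": qaly_fatal,
        "cost": cost_fatal_path,
        "p_rec": 0.0,
        "p_die_rec": 0.0,
    }

    # mix over latent groups and arms
    tot = {"ly": 0.0, "qaly": 0.0, "cost": 0.0, "p_rec": 0.0, "p_die_rec": 0.0}
    p_test_tot = 0.0
    p_chemo_tot = 0.0
    props = {g: params.group_proportions[g] for g in GROUPS}
    norm = sum(props.values())
    path_cache: dict[tuple[float, float], dict[str, float]] = {}
    for g in GROUPS:
        w = props[g] / norm
        tested = strategy_requires_test(strategy, g.ao)
        p_c = chemo_probability(g, tested, params.pattern)
        p_test_tot += w * tested
        p_chemo_tot += w * p_c
        for chemo, weight in ((False, 1.0 - p_c), (True, p_c * (1.0 - tox.p_fatal))):
            if weight == 0.0:
                continue
            # hazard of the assigned risk class: joint group if tested,
            # stratum marginal if not
            if tested:
                p10 = params.risks.p10(g, chemo)
            else:
                marg = (
                    params.risks.marginal_chemo
                    if chemo
                    else params.risks.marginal_no_chemo
                )
                p10 = marg[g.ao]
            lam = hazard_from_p10(p10)
            u1 = util.first_year_chemo if chemo else util.first_year_hormone
            key = (lam, u1)
            if key not in path_cache:
                path_cache[key] = nonfatal_path(lam, u1)
            for k in tot:
                tot[k] += w * weight * path_cache[key][k]
        w_fatal = p_c * tox.p_fatal
        if w_fatal > 0:
            for k in tot:
                tot[k] += w * w_fatal * fatal_path[k]
        # lump costs: test at t=0, chemo bundle at t=0, expected ADE at t_ade
        tot["cost"] += w * (
            tested * costs.odx_test
            + p_c * (costs.chemo_total + exp_ade_cost * np.exp(-r * t_ade))
        )

    p_ade = p_chemo_tot * tox.p_hospital_visit * tox.p_costed_visit
    return CohortExpectation(
        strategy=strategy,
        ly=tot["ly"],
        qaly=tot["qaly"],
        cost=tot["cost"],
        p_test=p_test_tot,
        p_chemo=p_chemo_tot,
        p_ade=p_ade,
        p_recurrence=tot["p_rec"],
        p_death_recurrence=tot["p_die_rec"],
    )
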