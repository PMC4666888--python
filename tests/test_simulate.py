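"""The discrete-event engine: rate conversions, discounting, trajectories."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import odxcea as ox
from helpers import degenerate_params, forced_survival_table
from odxcea.parameters import StrategyCode


def test_hazard_from_p10_examples():
    assert ox.hazard_from_p10(0.0) == 0.0
    # the intermediate-stratum 10-y risk of 20.36% implies 0.02277 / yr
    assert ox.hazard_from_p10(0.2036) == pytest.approx(0.02277, abs=5e-6)
    # median at 10 years corresponds to a 50% 10-year risk
    lam = math.log(2) / 10
    assert ox.hazard_from_p10(0.5) == pytest.approx(lam)
    with pytest.raises(ValueError):
        ox.hazard_from_p10(1.0)


def test_recurrence_survival_rate_examples():
    assert ox.recurrence_survival_rate(25.8) == pytest.approx(0.32239, abs=1e-5)
    assert ox.recurrence_survival_rate(12.0) == pytest.approx(math.log(2))
    # exponential mean = median / ln 2 = 37.2 months
    mean_months = 12.0 / ox.recurrence_survival_rate(25.8)
    assert mean_months == pytest.approx(25.8 / math.log(2))
    assert mean_months == pytest.approx(37.22, abs=0.01)
    with pytest.raises(ValueError):
        ox.recurrence_survival_rate(0.0)


def test_discounted_interval_closed_forms():
    assert ox.discounted_interval(1.0, 0.0, 10.0, 0.0) == pytest.approx(10.0)
    assert ox.discounted_interval(1.0, 0.0, 10.0, 0.05) == pytest.approx(7.8694, abs=1e-4)
    assert ox.discounted_interval(5.0, 3.0, 3.0, 0.07) == 0.0
    with pytest.raises(ValueError):
        ox.discounted_interval(1.0, 2.0, 1.0, 0.05)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    t0=st.floats(0, 50),
    dt1=st.floats(0, 20),
    dt2=st.floats(0, 20),
    r=st.floats(0, 0.2),
)
def test_discounted_interval_additivity(t0, dt1, dt2, r):
    """Splitting an interval never changes its present value."""
    whole = ox.discounted_interval(1.0, t0, t0 + dt1 + dt2, r)
    parts = ox.discounted_interval(1.0, t0, t0 + dt1, r) + ox.discounted_interval(
        1.0, t0 + dt1, t0 + dt1 + dt2, r
    )
    assert whole == pytest.approx(parts, abs=1e-9)
    assert whole <= dt1 + dt2 + 1e-12  # discounting never adds value


def test_sample_toxicity_forced_uniforms(params):
    tox = params.toxicity
    # no visit
    assert ox.simulate.sample_toxicity(tox, 0.9, 0.1, 0.5) == (None, False)
    # visit, first (most common) cause
    cause, fatal = ox.simulate.sample_toxicity(tox, 0.0, 0.5, 0.5)
    assert cause == "neutropenia_fever_infections" and not fatal
    assert tox.cost_by_cause[cause] == pytest.approx(5231.46)
    # visit beyond the costed causes: no adverse event recorded
    cause, fatal = ox.simulate.sample_toxicity(tox, 0.0, 0.99, 0.0005)
    assert cause is None and fatal


def test_degenerate_patient_lives_to_terminal_age(params, fixed_uniforms):
    """No recurrence, no chemo, no discounting: 50 undiscounted life-years."""
    p = degenerate_params(params)
    table = forced_survival_table()
    # u_od -> 0 maps to the upper tail of the death-time distribution
    #                 group chemo visit cause fatal  rec  death  bc
    rng = fixed_uniforms([0.5, 0.99, 0.9, 0.9, 0.9, 0.5, 1e-300, 0.5])
    out = ox.simulate_patient(p, StrategyCode.from_name("NNN"), table, rng)
    assert out.death_time == pytest.approx(50.0)
    assert out.discounted_ly == pytest.approx(50.0)
    assert out.discounted_qaly == pytest.approx(0.744 + 49 * 0.779)
    assert not (out.got_chemo or out.got_test or out.recurred or out.fatal_toxicity)


def test_fatal_toxicity_path(params, fixed_uniforms):
    """A forced fatal-toxicity draw kills at the end of chemotherapy."""
    p = degenerate_params(params)
    # force chemotherapy for everyone
    pattern = dataclasses.replace(
        p.pattern, by_ao={a: 1.0 for a in p.pattern.by_ao}
    )
    p = dataclasses.replace(p, pattern=pattern)
    table = forced_survival_table()
    rng = fixed_uniforms([0.5, 0.0, 0.9, 0.9, 0.0005, 0.5, 1 - 1e-16, 0.5])
    out = ox.simulate_patient(p, StrategyCode.from_name("NNN"), table, rng)
    assert out.fatal_toxicity and out.got_chemo and not out.recurred
    assert out.death_time == pytest.approx(0.5)
    assert out.discounted_ly == pytest.approx(0.5)
    assert out.discounted_qaly == pytest.approx(0.620 * 0.5)
    # chemotherapy bundle plus fatal-toxicity treatment (r = 0 here)
    fu_rate = 21.54 * 12 + 5016.8 / 5
    assert out.discounted_cost == pytest.approx(11372.96 + 36260.0 + fu_rate * 0.5)


def test_forced_recurrence_path_costs(params, fixed_uniforms):
    """Recurrence charges diagnosis plus the capped treatment episode."""
    p = degenerate_params(params)
    # recurrence certain and early: set every 10-y risk to ~1
    risks = dataclasses.replace(
        p.risks,
        marginal_no_chemo={a: 0.999999 for a in p.risks.marginal_no_chemo},
    )
    p = dataclasses.replace(p, risks=risks)
    table = forced_survival_table()
    u_rec = 1 - 1e-12  # quantile ~0 -> immediate recurrence
    rng = fixed_uniforms([0.5, 0.99, 0.9, 0.9, 0.9, u_rec, 1 - 1e-16, 0.5])
    out = ox.simulate_patient(p, StrategyCode.from_name("NNN"), table, rng)
    assert out.recurred and out.died_of_recurrence
    # u_bc = 0.5 -> median survival after recurrence, 25.8/2 months
    assert out.death_time == pytest.approx(out.discounted_ly)
    expected_rec_cost = 248.5 + 32015.26 / (25.8 / 12) * out.death_time
    assert out.discounted_cost == pytest.approx(expected_rec_cost, rel=1e-3)


def test_death_conservation_and_event_consistency(params, life_table):
    _, raw = ox.run_strategy(
        params, StrategyCode.from_name("YYY"), life_table, n=20_000, seed=3,
        return_patients=True,
    )
    causes = raw["death_cause"]
    n = len(causes)
    assert (causes == 0).sum() + (causes == 1).sum() + (causes == 2).sum() == n
    assert ((causes == 1) == raw["died_of_recurrence"]).all()
    assert raw["died_of_recurrence"].sum() <= raw["recurred"].sum()
    # fatal toxicity requires chemotherapy; recurrence deaths require recurrence
    assert (raw["fatal"] & ~raw["chemo"]).sum() == 0
    assert (raw["died_of_recurrence"] & ~raw["recurred"]).sum() == 0


def test_qaly_bounds_per_patient(params, life_table):
    """0.620 * LY <= QALY <= LY for every simulated trajectory."""
    for name in ("NNN", "YYY"):
        _, raw = ox.run_strategy(
            params, StrategyCode.from_name(name), life_table, n=20_000, seed=5,
            return_patients=True,
        )
        assert (raw["qaly"] <= raw["ly"] + 1e-12).all()
        assert (raw["qaly"] >= params.utilities.minimum_alive * raw["ly"] - 1e-12).all()


def test_discount_rate_monotonicity(params, life_table):
    """Raising the discount rate lowers mean discounted LY, QALY and cost."""
    means = []
    for r in (0.0, 0.05):
        p = dataclasses.replace(params, econ=dataclasses.replace(params.econ, discount_rate=r))
        res = ox.run_strategy(p, StrategyCode.from_name("NNN"), life_table, n=20_000, seed=9)
        means.append(res)
    assert means[1].mean_ly < means[0].mean_ly
    assert means[1].mean_qaly < means[0].mean_qaly
    assert means[1].mean_cost < means[0].mean_cost


def test_unit_utilities_make_qaly_equal_ly(params, life_table):
    utils = ox.parameters.UtilitySet(
        first_year_hormone=1.0, first_year_chemo=1.0, pre_recurrence=1.0,
        post_recurrence=1.0, dead=0.0,
    )
    p = dataclasses.replace(params, utilities=utils)
    _, raw = ox.run_strategy(
        p, StrategyCode.from_name("NYY"), life_table, n=5_000, seed=2, return_patients=True
    )
    assert np.allclose(raw["qaly"], raw["ly"])


def test_run_strategy_n1_equals_single_patient(params, life_table):
    res = ox.run_strategy(params, StrategyCode.from_name("NNN"), life_table, n=1, seed=42)
    rng = np.random.default_rng(42)
    out = ox.simulate_patient(params, StrategyCode.from_name("NNN"), life_table, rng)
    assert res.n == 1
    assert res.mean_ly == pytest.approx(out.discounted_ly)
    assert res.mean_qaly == pytest.approx(out.discounted_qaly)
    assert res.mean_cost == pytest.approx(out.discounted_cost)


def test_reproducibility_and_common_random_numbers(params, life_table):
    a = ox.run_strategy(params, StrategyCode.from_name("NNN"), life_table, n=5_000, seed=8)
    b = ox.run_strategy(params, StrategyCode.from_name("NNN"), life_table, n=5_000, seed=8)
    assert a == b
    # with common random numbers the genomic-testing strategy gains QALYs
    res = ox.run_all_strategies(params, life_table, n=20_000, seed=8)
    by = {r.strategy.name: r for r in res}
    assert by["YYY"].mean_qaly > by["NNN"].mean_qaly


def test_ade_proportion_matches_analytic_expectation(params, life_table):
    """ADE share = P(chemo) x P(visit) x P(costed cause), within MC error."""
    res = ox.run_strategy(params, StrategyCode.from_name("NNN"), life_table, n=50_000, seed=13)
    expected = res.p_chemo * 0.1704 * 0.7273
    se = math.sqrt(expected * (1 - expected) / res.n)
    assert abs(res.p_ade - expected) < 4 * se
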