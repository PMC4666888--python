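"""Parameter model: risk classification, strategy algebra, loading, validation."""

import dataclasses

import pytest
import yaml

import odxcea as ox
from odxcea.parameters import (
    ALL_STRATEGIES,
    GROUPS,
    AoCategory,
    OdxCategory,
    ParameterError,
    RiskGroup,
    StrategyCode,
)


@pytest.mark.parametrize(
    "bcsm,expected",
    [
        (0.0, "low"),
        (0.05, "low"),
        (0.0899, "low"),
        (0.09, "intermediate"),
        (0.1699, "intermediate"),
        (0.17, "high"),
        (1.0, "high"),
    ],
)
def test_classify_ao_boundaries(bcsm, expected):
    """Thresholds at 9% and 17% belong to the upper category."""
    assert ox.classify_ao(bcsm).name == expected


@pytest.mark.parametrize(
    "rs,expected",
    [(0, "low"), (17, "low"), (18, "intermediate"), (29.9, "intermediate"), (30, "high"), (100, "high")],
)
def test_classify_odx_boundaries(rs, expected):
    assert ox.classify_odx(rs).name == expected


@pytest.mark.parametrize("fn,bad", [(ox.classify_ao, -0.01), (ox.classify_ao, 1.01), (ox.classify_odx, -1), (ox.classify_odx, 101)])
def test_classify_rejects_out_of_range(fn, bad):
    with pytest.raises(ParameterError):
        fn(bad)


def test_classification_is_monotone():
    """Both classifiers are non-decreasing step functions of the score."""
    grid = [i / 200 for i in range(201)]
    cats = [ox.classify_ao(x) for x in grid]
    assert cats == sorted(cats)
    cats = [ox.classify_odx(x * 100) for x in grid]
    assert cats == sorted(cats)


def test_strategy_codes_are_a_bijection():
    assert len(ALL_STRATEGIES) == 8
    names = {s.name for s in ALL_STRATEGIES}
    assert names == {"NNN", "NNY", "NYN", "NYY", "YNN", "YNY", "YYN", "YYY"}
    for s in ALL_STRATEGIES:
        assert StrategyCode.from_name(s.name) == s


def test_strategy_requires_test():
    nyn = StrategyCode.from_name("NYN")
    assert ox.strategy_requires_test(nyn, AoCategory.intermediate)
    assert not ox.strategy_requires_test(nyn, AoCategory.low)
    for ao in AoCategory:
        assert not ox.strategy_requires_test(StrategyCode.from_name("NNN"), ao)
        assert ox.strategy_requires_test(StrategyCode.from_name("YYY"), ao)


def test_invalid_strategy_codes_rejected():
    for bad in ("NN", "NYNY", "ABC", ""):
        with pytest.raises(ParameterError):
            StrategyCode.from_name(bad)


def test_chemo_probability_rows(params):
    """Tested patients use the joint-group row, untested the stratum row."""
    int_high = RiskGroup(AoCategory.intermediate, OdxCategory.high)
    int_low = RiskGroup(AoCategory.intermediate, OdxCategory.low)
    assert ox.chemo_probability(int_high, True, params.pattern) == pytest.approx(0.9861)
    assert ox.chemo_probability(int_high, False, params.pattern) == pytest.approx(0.5506)
    t2 = params.with_pattern("T2").pattern
    assert ox.chemo_probability(int_low, True, t2) == 0.0
    assert ox.chemo_probability(int_low, True, params.pattern) == pytest.approx(0.1373)
    # untested row unaffected by the pattern switch
    assert ox.chemo_probability(int_low, False, t2) == pytest.approx(0.5506)


def test_group_proportions_sum_to_one(params):
    assert sum(params.group_proportions.values()) == pytest.approx(1.0, abs=1e-4)


def test_ao_row_proportions_match_printed_marginals(params):
    printed = {"low": 0.5299, "intermediate": 0.1871, "high": 0.2829}
    for ao in AoCategory:
        assert params.ao_proportion(ao) == pytest.approx(printed[ao.name], abs=1e-3)


@pytest.mark.parametrize("arm", ["no_chemo", "chemo"])
def test_recurrence_marginals_consistent_with_joint_table(params, arm):
    """Proportion-weighted joint 10-y risks reproduce the stratum rows to 0.1 pp."""
    joint = params.risks.p10_no_chemo if arm == "no_chemo" else params.risks.p10_chemo
    marg = (
        params.risks.marginal_no_chemo if arm == "no_chemo" else params.risks.marginal_chemo
    )
    for ao in AoCategory:
        w = {g: params.group_proportions[g] for g in GROUPS if g.ao == ao}
        total = sum(w.values())
        weighted = sum(w[g] * joint[g] for g in w) / total
        assert weighted == pytest.approx(marg[ao], abs=1e-3)


def test_default_parameters_base_case_values(params):
    assert params.costs.odx_test == 3180.0
    assert params.costs.chemo_total == pytest.approx(11372.96)
    assert params.utilities.first_year_chemo == pytest.approx(0.620)
    assert params.econ.discount_rate == pytest.approx(0.05)
    assert params.toxicity.p_costed_visit == pytest.approx(0.7273, abs=1e-6)


def _base_raw():
    from importlib.resources import files

    return yaml.safe_load(files("odxcea.data").joinpath("base_case.yaml").read_text())


def test_load_parameters_percent_units_equivalent(params):
    raw = _base_raw()
    raw["units"] = "percent"
    for ao in raw["group_proportions"]:
        raw["group_proportions"][ao] = {
            k: v * 100 for k, v in raw["group_proportions"][ao].items()
        }
    # leave everything else in fraction scale -> mismatch must be caught by
    # the validation of proportions staying probabilities; so scale all
    # probability blocks
    def scale_map(m):
        return {k: (scale_map(v) if isinstance(v, dict) else v * 100) for k, v in m.items()}

    raw["chemo_provision"]["by_ao"] = scale_map(raw["chemo_provision"]["by_ao"])
    raw["chemo_provision"]["by_group"] = scale_map(raw["chemo_provision"]["by_group"])
    raw["chemo_provision"]["t2_overrides"] = scale_map(raw["chemo_provision"]["t2_overrides"])
    raw["recurrence"] = scale_map(raw["recurrence"])
    raw["toxicity"]["p_hospital_visit"] *= 100
    raw["toxicity"]["cause_probs"] = scale_map(raw["toxicity"]["cause_probs"])
    raw["toxicity"]["p_fatal"] *= 100
    raw["utilities"] = scale_map(raw["utilities"])
    raw["economics"]["discount_rate"] *= 100
    loaded = ox.load_parameters(raw)
    for g, v in params.group_proportions.items():
        assert loaded.group_proportions[g] == pytest.approx(v)
    for f in ("first_year_hormone", "first_year_chemo", "pre_recurrence", "post_recurrence"):
        assert getattr(loaded.utilities, f) == pytest.approx(getattr(params.utilities, f))
    assert loaded.econ.discount_rate == pytest.approx(0.05)


@pytest.mark.parametrize(
    "mutate,message",
    [
        (lambda r: r["costs"].__setitem__("odx_test", -1.0), "odx_test"),
        (lambda r: r["costs"].pop("odx_test"), "missing"),
        (lambda r: r.__setitem__("surprise", 1), "unknown"),
        (lambda r: r["utilities"].__setitem__("pre_recurrence", 1.2), "pre_recurrence"),
        (lambda r: r["group_proportions"]["low"].__setitem__("low", 0.9), "sum to 1"),
    ],
)
def test_load_parameters_validation_errors(mutate, message):
    raw = _base_raw()
    mutate(raw)
    with pytest.raises(ParameterError, match=message):
        ox.load_parameters(raw)


def test_parameter_export_roundtrip(params):
    df = params.to_frame()
    assert set(df.columns) == {"block", "parameter", "value"}
    row = df[(df.block == "cost") & (df.parameter == "odx_test")]
    assert row.value.iloc[0] == 3180.0
    # every joint group appears in the proportion block
    assert (df.block == "group_proportion").sum() == 9


def test_with_pattern_only_changes_the_flagged_cell(params):
    t2 = params.with_pattern("T2")
    for g in GROUPS:
        expected = params.pattern.by_group[g]
        if g == RiskGroup(AoCategory.intermediate, OdxCategory.low):
            expected = 0.0
        assert t2.pattern.by_group[g] == expected
    assert dataclasses.replace(t2, pattern=params.pattern) == params
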