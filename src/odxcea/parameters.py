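"""Parameter model for the two-test adjuvant-chemotherapy decision problem.

The decision problem: women with ER/PR-positive, HER2-negative, node-negative
early breast cancer are stratified by a clinicopathologic risk tool
(breast-cancer-specific mortality, BCSM, categorised low / intermediate /
high at 9% and 17%) and, optionally, by a 21-gene expression assay
(recurrence score 0-100, categorised at 18 and 30).  A test-treatment
strategy is a three-letter Y/N mask saying which of the three
clinicopathologic strata are sent for genomic testing before the
chemotherapy decision.  Every patient carries a latent joint risk group
(3 x 3 = 9 cells); testing only changes which chemotherapy-provision row
applies and whether the assay cost is charged, never the underlying
recurrence hazard.

All quantities live in a validated, serialisable :class:`ParameterSet`,
loadable from a YAML file (the bundled base case reflects the Austrian
societal perspective, costs in 2011 euros).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Mapping, NamedTuple

import pandas as pd
import yaml

__all__ = [
    "AoCategory",
    "OdxCategory",
    "RiskGroup",
    "GROUPS",
    "StrategyCode",
    "ALL_STRATEGIES",
    "TreatmentPattern",
    "RecurrenceRiskTable",
    "ToxicityModel",
    "CostSchedule",
    "UtilitySet",
    "EconomicSettings",
    "ParameterSet",
    "ParameterError",
    "classify_ao",
    "classify_odx",
    "strategy_requires_test",
    "chemo_probability",
    "load_parameters",
    "default_parameters",
]


class ParameterError(ValueError):
    """Raised when an input parameter fails validation."""


class AoCategory(IntEnum):
    """Clinicopathologic (BCSM) risk category; ordered low < intermediate < high."""

    low = 0
    intermediate = 1
    high = 2


class OdxCategory(IntEnum):
    """21-gene recurrence-score category; ordered low < intermediate < high."""

    low = 0
    intermediate = 1
    high = 2


class RiskGroup(NamedTuple):
    """Joint latent risk class: clinicopathologic stratum x genomic stratum."""

    ao: AoCategory
    odx: OdxCategory


#: The nine joint risk groups in row-major (ao, odx) order.
GROUPS: tuple[RiskGroup, ...] = tuple(
    RiskGroup(a, o) for a in AoCategory for o in OdxCategory
)

_CAT_NAMES = ("low", "intermediate", "high")


def classify_ao(bcsm: float) -> AoCategory:
    """Categorise a breast-cancer-specific mortality risk.

    Half-open intervals [0, 0.09) -> low, [0.09, 0.17) -> intermediate,
    [0.17, 1] -> high; the threshold belongs to the upper category.
    """
    if not 0.0 <= bcsm <= 1.0:
        raise ParameterError(f"BCSM risk must be in [0, 1], got {bcsm}")
    if bcsm < 0.09:
        return AoCategory.low
    if bcsm < 0.17:
        return AoCategory.intermediate
    return AoCategory.high


def classify_odx(rs: float) -> OdxCategory:
    """Categorise a 21-gene recurrence score (0-100 scale).

    [0, 18) -> low, [18, 30) -> intermediate, [30, 100] -> high.
    """
    if not 0.0 <= rs <= 100.0:
        raise ParameterError(f"recurrence score must be in [0, 100], got {rs}")
    if rs < 18:
        return OdxCategory.low
    if rs < 30:
        return OdxCategory.intermediate
    return OdxCategory.high


@dataclass(frozen=True, order=True)
class StrategyCode:
    """Three-letter Y/N mask: test the low / intermediate / high stratum?

    E.g. ``NYN`` tests only patients in the intermediate clinicopathologic
    stratum with the genomic assay.
    """

    mask: tuple[bool, bool, bool]

    @classmethod
    def from_name(cls, name: str) -> "StrategyCode":
        name = name.strip().upper()
        if len(name) != 3 or set(name) - {"Y", "N"}:
            raise ParameterError(f"strategy code must be 3 chars over Y/N, got {name!r}")
        return cls(tuple(c == "Y" for c in name))

    @property
    def name(self) -> str:
        return "".join("Y" if m else "N" for m in self.mask)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


#: All eight strategies, in binary (N=0, Y=1) order.
ALL_STRATEGIES: tuple[StrategyCode, ...] = tuple(
    StrategyCode.from_name(f"{a}{b}{c}")
    for a in "NY"
    for b in "NY"
    for c in "NY"
)


def strategy_requires_test(code: StrategyCode, ao: AoCategory) -> bool:
    """Whether patients in clinicopathologic stratum *ao* get the genomic assay."""
    return code.mask[int(ao)]


def _check_prob(value: float, name: str) -> float:
    if not 0.0 <= value <= 1.0:
        raise ParameterError(f"{name} must be a probability in [0, 1], got {value}")
    return float(value)


def _check_nonneg(value: float, name: str) -> float:
    if value < 0:
        raise ParameterError(f"{name} must be non-negative, got {value}")
    return float(value)


@dataclass(frozen=True)
class TreatmentPattern:
    """Chemotherapy-provision probabilities.

    Tested patients draw from the joint-group row ``by_group``; untested
    patients from the marginal ``by_ao`` row (taken from observed practice,
    not re-derived from the joint table).  Pattern ``T2`` differs from the
    base-case ``T1`` only in the intermediate/genomic-low cell (0 instead of
    0.1373), i.e. genomic-low patients in the intermediate stratum receive
    no chemotherapy.
    """

    id: str
    by_group_t1: Mapping[RiskGroup, float]
    by_group_t2: Mapping[RiskGroup, float]
    by_ao: Mapping[AoCategory, float]

    def __post_init__(self) -> None:
        if self.id not in ("T1", "T2"):
            raise ParameterError(f"treatment pattern id must be T1 or T2, got {self.id!r}")
        for m, label in ((self.by_group_t1, "T1"), (self.by_group_t2, "T2")):
            if set(m) != set(GROUPS):
                raise ParameterError(f"chemo provision ({label}) must cover all 9 groups")
            for g, p in m.items():
                _check_prob(p, f"chemo provision {label}[{g.ao.name}/{g.odx.name}]")
        if set(self.by_ao) != set(AoCategory):
            raise ParameterError("chemo provision by_ao must cover the 3 strata")
        for a, p in self.by_ao.items():
            _check_prob(p, f"chemo provision by_ao[{a.name}]")

    @property
    def by_group(self) -> Mapping[RiskGroup, float]:
        return self.by_group_t1 if self.id == "T1" else self.by_group_t2


def chemo_probability(
    group: RiskGroup, tested: bool, pattern: TreatmentPattern
) -> float:
    """Probability of receiving adjuvant chemotherapy.

    Tested patients are treated according to the joint risk group; untested
    patients according to the clinicopathologic stratum alone.
    """
    if tested:
        return pattern.by_group[group]
    return pattern.by_ao[group.ao]


@dataclass(frozen=True)
class RecurrenceRiskTable:
    """10-year distant-recurrence risks per joint group, with and without chemo.

    The stratum marginals (used nowhere in simulation, but kept for the
    consistency check) must equal the proportion-weighted joint values.
    """

    p10_no_chemo: Mapping[RiskGroup, float]
    p10_chemo: Mapping[RiskGroup, float]
    marginal_no_chemo: Mapping[AoCategory, float]
    marginal_chemo: Mapping[AoCategory, float]

    def __post_init__(self) -> None:
        for m, label in (
            (self.p10_no_chemo, "no_chemo"),
            (self.p10_chemo, "chemo"),
        ):
            if set(m) != set(GROUPS):
                raise ParameterError(f"recurrence risks ({label}) must cover all 9 groups")
            for g, p in m.items():
                p = _check_prob(p, f"10y recurrence risk {label}[{g.ao.name}/{g.odx.name}]")
                if p >= 1.0:
                    raise ParameterError("10y recurrence risk must be < 1")

    def p10(self, group: RiskGroup, chemo: bool) -> float:
        return (self.p10_chemo if chemo else self.p10_no_chemo)[group]


@dataclass(frozen=True)
class ToxicityModel:
    """Chemotherapy toxicity: hospital visits, their causes/costs, fatal toxicity.

    The four costed causes sum to 0.7273 of visits; the remainder is an
    uncosted visit that does not count as an adverse drug event.
    """

    p_hospital_visit: float
    cause_probs: Mapping[str, float]
    cost_by_cause: Mapping[str, float]
    p_fatal: float
    cost_fatal: float

    def __post_init__(self) -> None:
        _check_prob(self.p_hospital_visit, "p_hospital_visit")
        _check_prob(self.p_fatal, "p_fatal")
        _check_nonneg(self.cost_fatal, "cost_fatal")
        if set(self.cause_probs) != set(self.cost_by_cause):
            raise ParameterError("toxicity causes and their costs must match")
        total = 0.0
        for c, p in self.cause_probs.items():
            total += _check_prob(p, f"cause_probs[{c}]")
            _check_nonneg(self.cost_by_cause[c], f"cost_by_cause[{c}]")
        if total > 1.0 + 1e-9:
            raise ParameterError("toxicity cause probabilities exceed 1")

    @property
    def p_costed_visit(self) -> float:
        """Probability, given a visit, that it is one of the costed causes."""
        return sum(self.cause_probs.values())


@dataclass(frozen=True)
class CostSchedule:
    """Direct costs (EUR 2011)."""

    odx_test: float
    chemo_total: float
    other_treatment_5y_total: float
    followup_per_month_first5y: float
    followup_per_month_after5y: float
    recurrence_diagnosis: float
    recurrence_treatment_total: float
    recurrence_treatment_months: float

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            _check_nonneg(getattr(self, f.name), f.name)
        if self.recurrence_treatment_months <= 0:
            raise ParameterError("recurrence_treatment_months must be positive")


@dataclass(frozen=True)
class UtilitySet:
    """Health-state utility weights (EQ-5D based)."""

    first_year_hormone: float
    first_year_chemo: float
    pre_recurrence: float
    post_recurrence: float
    dead: float = 0.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            _check_prob(getattr(self, f.name), f.name)
        if self.dead != 0.0:
            raise ParameterError("utility of death must be 0")

    @property
    def minimum_alive(self) -> float:
        return min(
            self.first_year_hormone,
            self.first_year_chemo,
            self.pre_recurrence,
            self.post_recurrence,
        )


@dataclass(frozen=True)
class EconomicSettings:
    """Cohort and discounting settings."""

    discount_rate: float = 0.05
    cohort_age: float = 50.0
    n_patients: int = 100_000
    median_survival_recurrence_months: float = 25.8
    chemo_duration_months: float = 6.0
    followup_switch_months: float = 60.0

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ParameterError("discount rate must be >= 0")
        if self.n_patients < 1:
            raise ParameterError("n_patients must be >= 1")
        if self.median_survival_recurrence_months <= 0:
            raise ParameterError("median survival after recurrence must be > 0")
        if self.cohort_age < 0:
            raise ParameterError("cohort age must be >= 0")


@dataclass(frozen=True)
class ParameterSet:
    """Everything the simulator needs, validated."""

    group_proportions: Mapping[RiskGroup, float]
    pattern: TreatmentPattern
    risks: RecurrenceRiskTable
    toxicity: ToxicityModel
    costs: CostSchedule
    utilities: UtilitySet
    econ: EconomicSettings = field(default_factory=EconomicSettings)

    def __post_init__(self) -> None:
        if set(self.group_proportions) != set(GROUPS):
            raise ParameterError("group_proportions must cover all 9 joint groups")
        total = 0.0
        for g, p in self.group_proportions.items():
            total += _check_prob(p, f"group_proportions[{g.ao.name}/{g.odx.name}]")
        if abs(total - 1.0) > 1e-4:
            raise ParameterError(
                f"joint group proportions must sum to 1 (got {total:.6f})"
            )

    def ao_proportion(self, ao: AoCategory) -> float:
        return sum(p for g, p in self.group_proportions.items() if g.ao == ao)

    def with_pattern(self, pattern_id: str) -> "ParameterSet":
        """Return a copy using treatment pattern ``T1`` or ``T2``."""
        return dataclasses.replace(
            self, pattern=dataclasses.replace(self.pattern, id=pattern_id)
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format audit export of every resolved parameter."""
        rows: list[tuple[str, str, float]] = []
        for g in GROUPS:
            key = f"{g.ao.name}/{g.odx.name}"
            rows.append(("group_proportion", key, self.group_proportions[g]))
        for a in AoCategory:
            rows.append(("chemo_provision_untested", a.name, self.pattern.by_ao[a]))
        for g in GROUPS:
            key = f"{g.ao.name}/{g.odx.name}"
            rows.append(("chemo_provision_tested", key, self.pattern.by_group[g]))
            rows.append(("p10_recurrence_no_chemo", key, self.risks.p10_no_chemo[g]))
            rows.append(("p10_recurrence_chemo", key, self.risks.p10_chemo[g]))
        tox = self.toxicity
        rows.append(("toxicity", "p_hospital_visit", tox.p_hospital_visit))
        for c, p in tox.cause_probs.items():
            rows.append(("toxicity_cause_prob", c, p))
            rows.append(("toxicity_cause_cost", c, tox.cost_by_cause[c]))
        rows.append(("toxicity", "p_fatal", tox.p_fatal))
        rows.append(("toxicity", "cost_fatal", tox.cost_fatal))
        for f in dataclasses.fields(self.costs):
            rows.append(("cost", f.name, getattr(self.costs, f.name)))
        for f in dataclasses.fields(self.utilities):
            rows.append(("utility", f.name, getattr(self.utilities, f.name)))
        for f in dataclasses.fields(self.econ):
            rows.append(("economics", f.name, getattr(self.econ, f.name)))
        return pd.DataFrame(rows, columns=["block", "parameter", "value"])


# ---------------------------------------------------------------------------
# YAML loading


def _require_keys(mapping: Mapping, expected: set[str], where: str) -> None:
    keys = set(mapping)
    missing = expected - keys
    unknown = keys - expected
    if missing:
        raise ParameterError(f"missing key(s) {sorted(missing)} in {where}")
    if unknown:
        raise ParameterError(f"unknown key(s) {sorted(unknown)} in {where}")


def _cat_map(raw: Mapping, where: str, scale: float) -> dict[AoCategory, float]:
    _require_keys(raw, set(_CAT_NAMES), where)
    return {AoCategory[k]: float(raw[k]) * scale for k in _CAT_NAMES}


def _group_map(raw: Mapping, where: str, scale: float) -> dict[RiskGroup, float]:
    _require_keys(raw, set(_CAT_NAMES), where)
    out: dict[RiskGroup, float] = {}
    for ao_name in _CAT_NAMES:
        inner = raw[ao_name]
        _require_keys(inner, set(_CAT_NAMES), f"{where}.{ao_name}")
        for odx_name in _CAT_NAMES:
            out[RiskGroup(AoCategory[ao_name], OdxCategory[odx_name])] = (
                float(inner[odx_name]) * scale
            )
    return out


def load_parameters(
    source: str | Path | Mapping, pattern: str | None = None
) -> ParameterSet:
    """Build a validated :class:`ParameterSet` from YAML text, a path, or a dict.

    The file declares ``units: fraction`` or ``units: percent`` for all
    probability and utility entries; costs and ages are never rescaled.
    ``pattern`` (``"T1"``/``"T2"``) overrides the pattern named in the file.
    """
    if isinstance(source, Mapping):
        raw = dict(source)
    else:
        path = Path(source)
        if path.exists():
            text = path.read_text()
        elif isinstance(source, str) and "\n" in source:
            text = source
        else:
            raise ParameterError(f"parameter file not found: {source}")
        raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ParameterError("parameter source must be a mapping")

    _require_keys(
        raw,
        {
            "units",
            "group_proportions",
            "chemo_provision",
            "recurrence",
            "toxicity",
            "costs",
            "utilities",
            "economics",
        },
        "top level",
    )
    units = raw["units"]
    if units not in ("fraction", "percent"):
        raise ParameterError("units must be 'fraction' or 'percent'")
    scale = 0.01 if units == "percent" else 1.0

    props = _group_map(raw["group_proportions"], "group_proportions", scale)

    cp = raw["chemo_provision"]
    _require_keys(cp, {"pattern", "by_ao", "by_group", "t2_overrides"}, "chemo_provision")
    by_group_t1 = _group_map(cp["by_group"], "chemo_provision.by_group", scale)
    by_group_t2 = dict(by_group_t1)
    for ao_name, inner in cp["t2_overrides"].items():
        if ao_name not in _CAT_NAMES:
            raise ParameterError(f"unknown key(s) [{ao_name!r}] in chemo_provision.t2_overrides")
        for odx_name, v in inner.items():
            if odx_name not in _CAT_NAMES:
                raise ParameterError(
                    f"unknown key(s) [{odx_name!r}] in chemo_provision.t2_overrides.{ao_name}"
                )
            g = RiskGroup(AoCategory[ao_name], OdxCategory[odx_name])
            by_group_t2[g] = float(v) * scale
    pattern_id = pattern if pattern is not None else cp["pattern"]
    treatment = TreatmentPattern(
        id=pattern_id,
        by_group_t1=by_group_t1,
        by_group_t2=by_group_t2,
        by_ao=_cat_map(cp["by_ao"], "chemo_provision.by_ao", scale),
    )

    rec = raw["recurrence"]
    _require_keys(rec, {"no_chemo", "chemo"}, "recurrence")
    tables = {}
    marginals = {}
    for arm in ("no_chemo", "chemo"):
        _require_keys(rec[arm], {"by_ao", "by_group"}, f"recurrence.{arm}")
        tables[arm] = _group_map(rec[arm]["by_group"], f"recurrence.{arm}.by_group", scale)
        marginals[arm] = _cat_map(rec[arm]["by_ao"], f"recurrence.{arm}.by_ao", scale)
    risks = RecurrenceRiskTable(
        p10_no_chemo=tables["no_chemo"],
        p10_chemo=tables["chemo"],
        marginal_no_chemo=marginals["no_chemo"],
        marginal_chemo=marginals["chemo"],
    )

    tox = raw["toxicity"]
    _require_keys(
        tox,
        {"p_hospital_visit", "cause_probs", "cost_by_cause", "p_fatal", "cost_fatal"},
        "toxicity",
    )
    if set(tox["cause_probs"]) != set(tox["cost_by_cause"]):
        raise ParameterError("toxicity cause_probs and cost_by_cause keys must match")
    toxicity = ToxicityModel(
        p_hospital_visit=float(tox["p_hospital_visit"]) * scale,
        cause_probs={k: float(v) * scale for k, v in tox["cause_probs"].items()},
        cost_by_cause={k: float(v) for k, v in tox["cost_by_cause"].items()},
        p_fatal=float(tox["p_fatal"]) * scale,
        cost_fatal=float(tox["cost_fatal"]),
    )

    cost_fields = {f.name for f in dataclasses.fields(CostSchedule)}
    _require_keys(raw["costs"], cost_fields, "costs")
    costs = CostSchedule(**{k: float(v) for k, v in raw["costs"].items()})

    util_fields = {f.name for f in dataclasses.fields(UtilitySet)}
    _require_keys(raw["utilities"], util_fields, "utilities")
    utilities = UtilitySet(**{k: float(v) * scale for k, v in raw["utilities"].items()})

    econ_fields = {f.name for f in dataclasses.fields(EconomicSettings)}
    _require_keys(raw["economics"], econ_fields, "economics")
    econ_raw = dict(raw["economics"])
    econ = EconomicSettings(
        discount_rate=float(econ_raw["discount_rate"]) * scale,
        cohort_age=float(econ_raw["cohort_age"]),
        n_patients=int(econ_raw["n_patients"]),
        median_survival_recurrence_months=float(
            econ_raw["median_survival_recurrence_months"]
        ),
        chemo_duration_months=float(econ_raw["chemo_duration_months"]),
        followup_switch_months=float(econ_raw["followup_switch_months"]),
    )

    return ParameterSet(
        group_proportions=props,
        pattern=treatment,
        risks=risks,
        toxicity=toxicity,
        costs=costs,
        utilities=utilities,
        econ=econ,
    )


def default_parameters(pattern: str = "T1") -> ParameterSet:
    """The bundled Austrian base case (costs in 2011 euros)."""
    from importlib.resources import files

    return load_parameters(
        yaml.safe_load(files("odxcea.data").joinpath("base_case.yaml").read_text()),
        pattern=pattern,
    )
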