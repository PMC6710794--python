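"""Model parameterization: types, loading, validation, provenance.

The whole evaluation is driven by one structured configuration document
(YAML or an equivalent mapping). The shipped base case reproduces the
published Swiss evaluation of adding sFlt-1/PlGF ratio testing to standard
of care for suspected preeclampsia: a cohort of 6084 pregnancies (7% of the
86,919 Swiss births in 2015) distributed over management branches with
per-branch occupancies and total costs, an uptake schedule for the budget
impact projection, and deterministic sensitivity specifications.

Monetary values are carried as :class:`decimal.Decimal` (cent precision,
see :mod:`preecon.money`); probabilities and fractional expected counts are
floats. Every numeric field of the shipped base case is traceable to its
real-world source through the ``provenance`` block, and
:func:`provenance_coverage` verifies that the block covers 100% of numeric
leaves.
"""

from __future__ import annotations

import fnmatch
import math
from dataclasses import dataclass, field
from decimal import Decimal
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .money import cents, eur

__all__ = [
    "STRATUM_LABELS",
    "STRATEGIES",
    "MANAGEMENT_BRANCHES",
    "HOSPITALIZED_UNTIL_BIRTH_BRANCHES",
    "ParameterError",
    "ConfigurationError",
    "RatioStratum",
    "BranchSpec",
    "CascadeParams",
    "BirthParams",
    "UptakeSchedule",
    "ValidationReport",
    "ModelConfig",
    "base_case_path",
    "derive_cohort_size",
    "load_config",
    "serialize_config",
    "validate",
    "iter_numeric_paths",
    "provenance_coverage",
]

STRATUM_LABELS = ("ratio_le_38", "ratio_38_85", "ratio_ge_85")
STRATEGIES = ("no_test", "test")

#: Branch ids of the decision tree, in reporting order. ``initial_consultation``
#: applies to every patient and sits outside cohort conservation.
MANAGEMENT_BRANCHES = (
    "low",
    "intermediate",
    "intermediate_after_hosp",
    "suspected_pe_birth",
    "pe_after_ambulatory",
)

#: Branches whose patients are hospitalized until birth (the headline
#: hospitalization counts 1160 vs 822 are sums over these two).
HOSPITALIZED_UNTIL_BIRTH_BRANCHES = ("suspected_pe_birth", "pe_after_ambulatory")

COST_COMPONENTS = ("outpatient_care", "hospitalization", "birth")


class ParameterError(ValueError):
    """An operation received an out-of-domain argument."""


class ConfigurationError(ValueError):
    """The configuration document is missing or malformed; names the path."""

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"{path}: {message}")


@dataclass(frozen=True)
class RatioStratum:
    """One sFlt-1/PlGF ratio stratum of the test strategy."""

    label: str
    prevalence: float
    p_hospitalized: float


@dataclass(frozen=True)
class BranchSpec:
    """A management pathway: occupancy, total cost, and cost decomposition.

    ``n_patients`` may be fractional (expected counts); integers appear only
    at display time. ``total_cost`` is exact; the per-patient cost is the
    exact quotient total/n. ``cost_components`` decompose the per-patient
    cost into outpatient_care / hospitalization / birth and must sum to it
    within one cent when given.
    """

    branch_id: str
    label: str
    n_patients: float
    total_cost: Decimal | None = None
    cost_components: dict[str, Decimal] = field(default_factory=dict)
    applies_to_all: bool = False

    @property
    def per_patient_cost(self) -> Decimal:
        if self.total_cost is not None:
            if self.n_patients == 0:
                return Decimal(0)
            return self.total_cost / eur(self.n_patients)
        if self.cost_components:
            return sum(self.cost_components.values(), Decimal(0))
        raise ConfigurationError(self.branch_id, "branch has neither total cost nor components")


@dataclass(frozen=True)
class CascadeParams:
    """Conditional probabilities for the probability-mode cascade of one arm.

    ``p_hospitalized`` is the arm-level admission rate for the no-test arm;
    the test arm derives admission from the strata instead and leaves it None.
    """

    p_hospitalized: float | None
    p_pe_given_hospitalized: float
    p_pe_after_ambulatory: float
    p_low_given_ambulatory: float


@dataclass(frozen=True)
class BirthParams:
    """No-preeclampsia delivery costs and the national C-section share."""

    csection_share: float
    vaginal_cost_no_pe: Decimal
    csection_cost_no_pe: Decimal
    blended_cost_no_pe: Decimal


@dataclass(frozen=True)
class UptakeSchedule:
    """Projected number of tested patients per year, plus the discount rate."""

    years: tuple[tuple[int, int], ...]  # (year_index starting at 1, n_test)
    discount_rate: float


@dataclass
class ValidationReport:
    """Outcome of :func:`validate`: ok iff no message has severity 'error'."""

    messages: list[tuple[str, str, str]] = field(default_factory=list)  # (severity, path, text)

    @property
    def ok(self) -> bool:
        return not any(sev == "error" for sev, _, _ in self.messages)

    def add(self, severity: str, path: str, text: str) -> None:
        self.messages.append((severity, path, text))

    def errors(self) -> list[tuple[str, str, str]]:
        return [m for m in self.messages if m[0] == "error"]


@dataclass
class ModelConfig:
    """Complete parameter set for one evaluation."""

    births_per_year: int
    suspicion_rate: float
    cohort_size: int
    test_unit_cost: Decimal
    exchange_rate: float
    strata: tuple[RatioStratum, ...]
    cascades: dict[str, CascadeParams]
    birth: BirthParams
    strategies: dict[str, dict[str, BranchSpec]]
    uptake: UptakeSchedule
    discount_rate: float
    costing_mode: str
    outpatient_schedules: dict[str, dict[str, int]]
    visit_total_overrides: dict[str, Decimal]
    weeks_after_discharge: dict[str, int]
    sensitivity_one_way: list[dict[str, Any]]
    sensitivity_scenarios: list[dict[str, Any]]
    provenance: dict[str, str]
    raw: dict[str, Any]

    def stratum(self, label: str) -> RatioStratum:
        for s in self.strata:
            if s.label == label:
                return s
        raise ParameterError(f"unknown stratum {label!r}")

    def branch(self, strategy: str, branch_id: str) -> BranchSpec:
        try:
            return self.strategies[strategy][branch_id]
        except KeyError as exc:
            raise ParameterError(f"unknown branch {strategy}/{branch_id}") from exc


def base_case_path() -> Path:
    """Path of the shipped base-case configuration."""
    return Path(resources.files("preecon").joinpath("data/base_case.yaml"))


def derive_cohort_size(births: int, rate: float) -> int:
    """Suspected-preeclampsia cohort: integer part of births x suspicion rate.

    86,919 births at a 7% suspicion rate gives the base-case cohort of 6084.
    """
    if births <= 0:
        raise ParameterError(f"births must be positive, got {births}")
    if not 0 < rate < 1:
        raise ParameterError(f"suspicion rate must lie in (0, 1), got {rate}")
    return int(births * rate)


def _require(mapping: Mapping, key: str, path: str):
    if not isinstance(mapping, Mapping) or key not in mapping:
        raise ConfigurationError(f"{path}.{key}" if path else key, "missing required key")
    return mapping[key]


def _number(mapping: Mapping, key: str, path: str) -> float:
    value = _require(mapping, key, path)
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigurationError(f"{path}.{key}", f"expected a number, got {value!r}")
    return value


def _money(mapping: Mapping, key: str, path: str) -> Decimal:
    return eur(_number(mapping, key, path))


def load_config(source: str | Path | Mapping[str, Any]) -> ModelConfig:
    """Load and structure a configuration document.

    ``source`` may be a path to a YAML file, a YAML string, or an
    already-parsed mapping. Derived fields (cohort size) are computed here;
    monetary values are converted to exact decimals.
    """
    if isinstance(source, Mapping):
        doc = dict(source)
    else:
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise ConfigurationError("<root>", "document is not a mapping")

    cohort = _require(doc, "cohort", "")
    births = int(_number(cohort, "births_per_year", "cohort"))
    rate = _number(cohort, "suspicion_rate", "cohort")
    try:
        cohort_size = derive_cohort_size(births, rate)
    except ParameterError as exc:
        raise ConfigurationError("cohort", str(exc)) from exc

    test_cfg = _require(doc, "test", "")
    test_unit_cost = _money(test_cfg, "unit_cost_eur", "test")
    exchange_rate = _number(doc, "exchange_rate_eur_per_chf", "")
    costing_mode = doc.get("costing_mode", "implied")
    if costing_mode not in ("implied", "bottom_up"):
        raise ConfigurationError("costing_mode", f"unknown mode {costing_mode!r}")

    strata_cfg = _require(doc, "strata", "")
    strata = []
    for label in strata_cfg:
        entry = strata_cfg[label]
        strata.append(
            RatioStratum(
                label=label,
                prevalence=_number(entry, "prevalence", f"strata.{label}"),
                p_hospitalized=_number(entry, "p_hospitalized", f"strata.{label}"),
            )
        )

    cascades = {}
    for arm, entry in (doc.get("cascades") or {}).items():
        cascades[arm] = CascadeParams(
            p_hospitalized=(
                _number(entry, "p_hospitalized", f"cascades.{arm}") if "p_hospitalized" in entry else None
            ),
            p_pe_given_hospitalized=_number(entry, "p_pe_given_hospitalized", f"cascades.{arm}"),
            p_pe_after_ambulatory=_number(entry, "p_pe_after_ambulatory", f"cascades.{arm}"),
            p_low_given_ambulatory=_number(entry, "p_low_given_ambulatory", f"cascades.{arm}"),
        )

    birth_cfg = _require(doc, "birth", "")
    birth = BirthParams(
        csection_share=_number(birth_cfg, "csection_share", "birth"),
        vaginal_cost_no_pe=_money(birth_cfg, "vaginal_cost_no_pe_eur", "birth"),
        csection_cost_no_pe=_money(birth_cfg, "csection_cost_no_pe_eur", "birth"),
        blended_cost_no_pe=_money(birth_cfg, "blended_cost_no_pe_eur", "birth"),
    )

    strategies: dict[str, dict[str, BranchSpec]] = {}
    for strategy, entry in _require(doc, "strategies", "").items():
        branches = {}
        for branch_id, bcfg in _require(entry, "branches", f"strategies.{strategy}").items():
            bpath = f"strategies.{strategy}.branches.{branch_id}"
            components = {
                name: eur(value)
                for name, value in (bcfg.get("cost_components") or {}).items()
            }
            total = (
                _money(bcfg, "total_cost_eur", bpath) if "total_cost_eur" in bcfg else None
            )
            branches[branch_id] = BranchSpec(
                branch_id=branch_id,
                label=str(bcfg.get("label", branch_id)),
                n_patients=_number(bcfg, "n_patients", bpath),
                total_cost=total,
                cost_components=components,
                applies_to_all=bool(bcfg.get("applies_to_all", False)),
            )
        strategies[strategy] = branches

    bia = _require(doc, "budget_impact", "")
    discount_rate = _number(bia, "discount_rate", "budget_impact")
    uptake_cfg = _require(bia, "uptake", "budget_impact")
    uptake = UptakeSchedule(
        years=tuple(sorted((int(y), int(n)) for y, n in uptake_cfg.items())),
        discount_rate=discount_rate,
    )

    costs_cfg = doc.get("costs", {})
    out_cfg = costs_cfg.get("outpatient", {})
    schedules = {
        setting: {k: int(v) for k, v in entry.items()}
        for setting, entry in out_cfg.get("schedules", {}).items()
    }
    overrides = {
        setting: eur(value) for setting, value in out_cfg.get("visit_total_overrides", {}).items()
    }
    weeks_after_discharge = {
        arm: int(v) for arm, v in costs_cfg.get("inpatient", {}).get("weeks_after_discharge", {}).items()
    }

    sens_cfg = doc.get("sensitivity", {}) or {}

    return ModelConfig(
        births_per_year=births,
        suspicion_rate=rate,
        cohort_size=cohort_size,
        test_unit_cost=test_unit_cost,
        exchange_rate=exchange_rate,
        strata=tuple(strata),
        cascades=cascades,
        birth=birth,
        strategies=strategies,
        uptake=uptake,
        discount_rate=discount_rate,
        costing_mode=costing_mode,
        outpatient_schedules=schedules,
        visit_total_overrides=overrides,
        weeks_after_discharge=weeks_after_discharge,
        sensitivity_one_way=list(sens_cfg.get("one_way", []) or []),
        sensitivity_scenarios=list(sens_cfg.get("scenarios", []) or []),
        provenance=dict(doc.get("provenance", {}) or {}),
        raw=doc,
    )


def _num_out(value):
    """Emit a Decimal back into a plain YAML-safe number."""
    if isinstance(value, Decimal):
        as_float = float(value)
        return int(as_float) if as_float == int(as_float) else as_float
    return value


def serialize_config(config: ModelConfig) -> dict[str, Any]:
    """Dump a ModelConfig back into the document structure of :func:`load_config`.

    load(serialize(load(doc))) is field-by-field identical to load(doc); EUR
    values survive at cent precision.
    """
    doc: dict[str, Any] = {
        "cohort": {
            "births_per_year": config.births_per_year,
            "suspicion_rate": config.suspicion_rate,
        },
        "test": {"unit_cost_eur": _num_out(config.test_unit_cost)},
        "exchange_rate_eur_per_chf": config.exchange_rate,
        "costing_mode": config.costing_mode,
        "strata": {
            s.label: {"prevalence": s.prevalence, "p_hospitalized": s.p_hospitalized}
            for s in config.strata
        },
        "cascades": {},
        "birth": {
            "csection_share": config.birth.csection_share,
            "vaginal_cost_no_pe_eur": _num_out(config.birth.vaginal_cost_no_pe),
            "csection_cost_no_pe_eur": _num_out(config.birth.csection_cost_no_pe),
            "blended_cost_no_pe_eur": _num_out(config.birth.blended_cost_no_pe),
        },
        "strategies": {},
        "budget_impact": {
            "discount_rate": config.discount_rate,
            "uptake": {y: n for y, n in config.uptake.years},
        },
        "costs": {
            "outpatient": {
                "schedules": {k: dict(v) for k, v in config.outpatient_schedules.items()},
                "visit_total_overrides": {
                    k: _num_out(v) for k, v in config.visit_total_overrides.items()
                },
            },
            "inpatient": {"weeks_after_discharge": dict(config.weeks_after_discharge)},
        },
        "sensitivity": {
            "one_way": list(config.sensitivity_one_way),
            "scenarios": list(config.sensitivity_scenarios),
        },
        "provenance": dict(config.provenance),
    }
    for arm, cascade in config.cascades.items():
        entry: dict[str, float] = {}
        if cascade.p_hospitalized is not None:
            entry["p_hospitalized"] = cascade.p_hospitalized
        entry["p_pe_given_hospitalized"] = cascade.p_pe_given_hospitalized
        entry["p_pe_after_ambulatory"] = cascade.p_pe_after_ambulatory
        entry["p_low_given_ambulatory"] = cascade.p_low_given_ambulatory
        doc["cascades"][arm] = entry
    for strategy, branches in config.strategies.items():
        out = {}
        for branch_id, b in branches.items():
            bdoc: dict[str, Any] = {"label": b.label}
            if b.applies_to_all:
                bdoc["applies_to_all"] = True
            bdoc["n_patients"] = b.n_patients
            if b.total_cost is not None:
                bdoc["total_cost_eur"] = _num_out(b.total_cost)
            if b.cost_components:
                bdoc["cost_components"] = {k: _num_out(v) for k, v in b.cost_components.items()}
            out[branch_id] = bdoc
        doc["strategies"][strategy] = {"branches": out}
    return doc


def validate(config: ModelConfig) -> ValidationReport:
    """Check every structural invariant; reports problems instead of raising."""
    report = ValidationReport()

    if not 0 < config.suspicion_rate < 1:
        report.add("error", "cohort.suspicion_rate", f"must lie in (0, 1), got {config.suspicion_rate}")
    if config.cohort_size != int(config.births_per_year * config.suspicion_rate):
        report.add("error", "cohort.cohort_size", "not the integer part of births x rate")

    if len(config.strata) != 3:
        report.add("error", "strata", f"expected exactly three strata, got {len(config.strata)}")
    prev_sum = sum(s.prevalence for s in config.strata)
    if not math.isclose(prev_sum, 1.0, abs_tol=1e-9):
        report.add("error", "strata", f"prevalences sum to {prev_sum}, expected 1")
    for s in config.strata:
        if not 0 <= s.p_hospitalized <= 1:
            report.add("error", f"strata.{s.label}.p_hospitalized", f"outside [0, 1]: {s.p_hospitalized}")

    if config.test_unit_cost < 0:
        report.add("error", "test.unit_cost_eur", "negative test cost")

    blended = (
        eur(1 - config.birth.csection_share) * config.birth.vaginal_cost_no_pe
        + eur(config.birth.csection_share) * config.birth.csection_cost_no_pe
    )
    if abs(blended - config.birth.blended_cost_no_pe) > Decimal("0.01"):
        report.add(
            "warning",
            "birth.blended_cost_no_pe_eur",
            f"stored blend {config.birth.blended_cost_no_pe} differs from share-weighted {cents(blended)}",
        )

    for strategy, branches in config.strategies.items():
        conserved = 0.0
        for branch_id, b in branches.items():
            bpath = f"strategies.{strategy}.branches.{branch_id}"
            if b.n_patients < 0:
                report.add("error", bpath, f"negative n_patients {b.n_patients}")
            try:
                pp = b.per_patient_cost
            except ConfigurationError:
                report.add("error", bpath, "no cost information")
                continue
            if pp < 0:
                report.add("error", bpath, f"negative per-patient cost {pp}")
            if b.cost_components:
                for name, value in b.cost_components.items():
                    if value < 0:
                        report.add("error", f"{bpath}.cost_components.{name}", f"negative component {value}")
                comp_sum = sum(b.cost_components.values(), Decimal(0))
                if b.total_cost is not None and abs(comp_sum - pp) > Decimal("0.01"):
                    report.add(
                        "error",
                        f"{bpath}.cost_components",
                        f"components sum to {comp_sum}, per-patient cost is {cents(pp)}",
                    )
            if not b.applies_to_all:
                conserved += b.n_patients
        if abs(conserved - config.cohort_size) > 1:
            report.add(
                "error",
                f"strategies.{strategy}",
                f"branch occupancies sum to {conserved}, cohort is {config.cohort_size}",
            )

    years = [y for y, _ in config.uptake.years]
    if years != list(range(1, len(years) + 1)):
        report.add("error", "budget_impact.uptake", f"year indices not consecutive from 1: {years}")
    for y, n in config.uptake.years:
        if not 0 <= n <= config.cohort_size:
            report.add("error", f"budget_impact.uptake.{y}", f"n_test {n} outside [0, cohort]")
    if config.discount_rate < 0:
        report.add("error", "budget_impact.discount_rate", "negative discount rate")

    return report


def iter_numeric_paths(doc: Mapping[str, Any], prefix: str = "") -> list[str]:
    """Dotted paths of every numeric leaf in a config document.

    The ``provenance`` block itself is excluded, as are booleans.
    """
    paths: list[str] = []
    for key, value in doc.items():
        path = f"{prefix}.{key}" if prefix else str(key)
        if not prefix and key == "provenance":
            continue
        if isinstance(value, Mapping):
            paths.extend(iter_numeric_paths(value, path))
        elif isinstance(value, (list, tuple)):
            for i, item in enumerate(value):
                if isinstance(item, Mapping):
                    paths.extend(iter_numeric_paths(item, f"{path}.{i}"))
                elif isinstance(item, (int, float)) and not isinstance(item, bool):
                    paths.append(f"{path}.{i}")
        elif isinstance(value, (int, float)) and not isinstance(value, bool):
            paths.append(path)
    return paths


def provenance_coverage(doc: Mapping[str, Any]) -> tuple[list[str], list[str]]:
    """Split a document's numeric leaf paths into (covered, uncovered).

    A path is covered when it matches any pattern of the ``provenance``
    block (fnmatch semantics, so ``strata.*.prevalence`` covers all strata).
    """
    patterns = list((doc.get("provenance") or {}).keys())
    covered, uncovered = [], []
    for path in iter_numeric_paths(doc):
        if any(fnmatch.fnmatch(path, pattern) for pattern in patterns):
            covered.append(path)
        else:
            uncovered.append(path)
    return covered, uncovered
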