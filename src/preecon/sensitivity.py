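"""One-way deterministic sensitivity analysis and named scenarios.

Each one-way entry perturbs a single addressed parameter (relative scaling
or absolute replacement), re-runs the strategy comparison, and records the
per-patient saving — the tornado-ready output. Cost parameters re-enter the
tree directly; stratum admission probabilities act through an expected-count
reallocation in the test arm: patients whose admission decision flips move
between their stratum's outpatient follow-up branch (low for a ratio <=38,
intermediate above) and the admission-with-discharge branch, carrying the
destination branch's per-patient cost. Preeclampsia incidence — and with it
the two hospitalized-until-birth branches — is deliberately unaffected by
that dial: the admission threshold governs precautionary admissions, not
disease.

Scenarios cover the exclusion of delivery costs from every branch and
retest policies that add test volume (retests are test-cost-only by
default; management-shift effects are not modelled).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from typing import Any, Iterable, Mapping

from .cohort_tree import compare
from .money import cents, eur
from .parameters import (
    ConfigurationError,
    ModelConfig,
    ParameterError,
    load_config,
    serialize_config,
)

__all__ = [
    "SensitivitySpec",
    "ScenarioSpec",
    "TornadoEntry",
    "specs_from_config",
    "scenarios_from_config",
    "apply_modifier",
    "one_way",
    "run_scenario",
    "run_all",
]


@dataclass(frozen=True)
class SensitivitySpec:
    """One parameter variation: address, modifier, and how to apply it."""

    label: str
    parameter_path: str
    modifier: float
    mode: str = "relative"  # or "absolute"

    def __post_init__(self):
        if self.mode not in ("relative", "absolute"):
            raise ParameterError(f"unknown modifier mode {self.mode!r}")
        if self.mode == "relative" and self.modifier <= -1:
            raise ParameterError(f"relative modifier must exceed -1, got {self.modifier}")


@dataclass(frozen=True)
class ScenarioSpec:
    """A named scenario: birth-cost exclusion or a retest policy."""

    name: str  # "exclude_birth_costs" or "retest"
    label: str
    retest_fraction: float = 0.0
    retest_population: str = "all"  # low_setting | intermediate | all
    tests_per_retested_patient: int = 1

    def __post_init__(self):
        if self.name not in ("exclude_birth_costs", "retest"):
            raise ParameterError(f"unknown scenario {self.name!r}")
        if not 0.0 <= self.retest_fraction <= 1.0:
            raise ParameterError(f"retest fraction outside [0, 1]: {self.retest_fraction}")
        if self.retest_population not in ("low_setting", "intermediate", "all"):
            raise ParameterError(f"unknown retest population {self.retest_population!r}")


@dataclass(frozen=True)
class TornadoEntry:
    """Per-patient saving under one variation, and its shift from base."""

    label: str
    per_patient_saving: float
    delta_vs_base: float


def specs_from_config(config: ModelConfig) -> list[SensitivitySpec]:
    return [
        SensitivitySpec(
            label=entry["label"],
            parameter_path=entry["path"],
            modifier=float(entry["modifier"]),
            mode=entry.get("mode", "relative"),
        )
        for entry in config.sensitivity_one_way
    ]


def scenarios_from_config(config: ModelConfig) -> list[ScenarioSpec]:
    out = []
    for entry in config.sensitivity_scenarios:
        out.append(
            ScenarioSpec(
                name=entry["name"],
                label=entry.get("label", entry["name"]),
                retest_fraction=float(entry.get("retest_fraction", 0.0)),
                retest_population=entry.get("retest_population", "all"),
                tests_per_retested_patient=int(entry.get("tests_per_retested_patient", 1)),
            )
        )
    return out


def _transform(value: Decimal, spec: SensitivitySpec, *, money: bool) -> Decimal:
    if spec.mode == "relative":
        new = value * (Decimal(1) + eur(spec.modifier))
    else:
        new = eur(spec.modifier)
    return cents(new) if money else new


def _walk(doc: dict, dotted: str):
    """Return (container, final key) for a dotted path into the document."""
    parts = dotted.split(".")
    node: Any = doc
    for part in parts[:-1]:
        if isinstance(node, Mapping) and part in node:
            node = node[part]
        else:
            raise ConfigurationError(dotted, "path does not resolve")
    key = parts[-1]
    if not (isinstance(node, Mapping) and key in node):
        raise ConfigurationError(dotted, "path does not resolve")
    return node, key


def apply_modifier(config: ModelConfig, spec: SensitivitySpec) -> ModelConfig:
    """Pure parameter perturbation: returns a new config, original untouched.

    Supported addresses: any numeric leaf by dotted path (e.g.
    ``test.unit_cost_eur``, ``strata.ratio_le_38.p_hospitalized``) and the
    virtual path ``components.<name>`` which scales that cost component in
    every branch of both strategies, keeping branch totals consistent.
    """
    doc = serialize_config(config)
    if spec.parameter_path.startswith("components."):
        component = spec.parameter_path.split(".", 1)[1]
        touched = False
        for strategy in doc["strategies"].values():
            for branch in strategy["branches"].values():
                components = branch.get("cost_components") or {}
                if component not in components:
                    continue
                old = eur(components[component])
                if old == 0:
                    continue
                new = _transform(old, spec, money=True)
                n = eur(branch["n_patients"])
                if "total_cost_eur" in branch:
                    branch["total_cost_eur"] = float(eur(branch["total_cost_eur"]) + n * (new - old))
                components[component] = float(new)
                touched = True
        if not touched:
            raise ConfigurationError(
                spec.parameter_path, "no branch carries this cost component"
            )
        return load_config(doc)

    node, key = _walk(doc, spec.parameter_path)
    value = node[key]
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigurationError(spec.parameter_path, f"not a numeric leaf: {value!r}")
    money = "cost" in spec.parameter_path or spec.parameter_path.endswith("_eur")
    node[key] = float(_transform(eur(value), spec, money=money))
    return load_config(doc)


def _reallocate_admissions(base: ModelConfig, modified: ModelConfig) -> ModelConfig:
    """Shift expected test-arm occupancies for changed admission rates.

    For each stratum, cohort x prevalence x (p_new - p_old) expected
    patients move between the stratum's outpatient branch and
    ``intermediate_after_hosp``; moved patients cost what their destination
    branch costs per patient.
    """
    doc = serialize_config(modified)
    branches = doc["strategies"]["test"]["branches"]
    shifts: dict[str, float] = {}
    for stratum in base.strata:
        p_new = modified.stratum(stratum.label).p_hospitalized
        delta_p = p_new - stratum.p_hospitalized
        if delta_p == 0:
            continue
        moved = base.cohort_size * stratum.prevalence * delta_p
        source = "low" if stratum.label == "ratio_le_38" else "intermediate"
        shifts[source] = shifts.get(source, 0.0) - moved
        shifts["intermediate_after_hosp"] = shifts.get("intermediate_after_hosp", 0.0) + moved
    for branch_id, delta_n in shifts.items():
        branch = branches[branch_id]
        per_patient = eur(branch["total_cost_eur"]) / eur(branch["n_patients"])
        branch["n_patients"] = float(branch["n_patients"]) + delta_n
        branch["total_cost_eur"] = float(
            eur(branch["total_cost_eur"]) + cents(eur(delta_n) * per_patient)
        )
    return load_config(doc)


def one_way(config: ModelConfig, specs: Iterable[SensitivitySpec]) -> list[TornadoEntry]:
    """Tornado entries for a list of variations, largest |effect| first."""
    base_saving = float(compare(config).per_patient_saving)
    entries = []
    for spec in specs:
        modified = apply_modifier(config, spec)
        if ".p_hospitalized" in spec.parameter_path:
            cmp = compare(_reallocate_admissions(config, modified))
        else:
            cmp = compare(modified)
        saving = float(cmp.per_patient_saving)
        entries.append(TornadoEntry(spec.label, saving, saving - base_saving))
    return sorted(entries, key=lambda e: (-abs(e.delta_vs_base), e.label))


def _excluding_birth_costs(config: ModelConfig) -> ModelConfig:
    doc = serialize_config(config)
    any_components = False
    for strategy in doc["strategies"].values():
        for branch in strategy["branches"].values():
            components = branch.get("cost_components") or {}
            if components:
                any_components = True
            birth = eur(components.get("birth", 0))
            if birth == 0:
                continue
            n = eur(branch["n_patients"])
            if "total_cost_eur" in branch:
                branch["total_cost_eur"] = float(eur(branch["total_cost_eur"]) - n * birth)
            components["birth"] = 0.0
    if not any_components:
        raise ConfigurationError(
            "strategies", "no cost components configured; use bottom_up costing mode to expose them"
        )
    return load_config(doc)


def run_scenario(config: ModelConfig, scenario: ScenarioSpec) -> TornadoEntry:
    """Evaluate one named scenario against the base comparison."""
    base = compare(config)
    base_saving = float(base.per_patient_saving)
    if scenario.name == "exclude_birth_costs":
        cmp = compare(_excluding_birth_costs(config))
        saving = float(cmp.per_patient_saving)
        return TornadoEntry(scenario.label, saving, saving - base_saving)

    # retest: extra test volume billed to the test strategy
    if scenario.retest_population == "all":
        population = float(config.cohort_size)
    elif scenario.retest_population == "low_setting":
        population = config.branch("test", "low").n_patients
    else:
        population = config.branch("test", "intermediate").n_patients
    extra_tests = scenario.retest_fraction * population * scenario.tests_per_retested_patient
    extra_cost = cents(eur(extra_tests) * config.test_unit_cost)
    delta_total = base.delta_total + extra_cost
    saving = float(-(delta_total / eur(config.cohort_size)))
    return TornadoEntry(scenario.label, saving, saving - base_saving)


def run_all(config: ModelConfig) -> list[TornadoEntry]:
    """The configured one-way set plus all configured scenarios."""
    entries = one_way(config, specs_from_config(config))
    entries.extend(run_scenario(config, s) for s in scenarios_from_config(config))
    return entries
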