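"""Patient-level synthetic cohorts and a synthetic inpatient registry.

The deterministic tree is an expected-value model; this module draws the
individual pregnancies it averages over, for convergence checks (law of
large numbers against the probability-mode expectation), parameter
recovery, and a synthetic stand-in for the hospital cost registry.

Draws follow the same cascade as probability-mode allocation: ratio stratum
(test arm only) -> initial hospitalization -> preeclampsia -> branch, with
the severe-blood-pressure flag in the <=38 stratum identified with that
stratum's admission rule (admission there is triggered by blood pressure
above 160/110 mmHg). Registry lengths of stay and episode costs are
log-normal per group, with the location parameter fixed by the group median
and the scale parameter by the mean/median ratio — strictly positive,
right-skewed, and pinned to exactly the two published moments.

One explicit numpy Generator per simulation; no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .cohort_tree import strategy_cost
from .costing import InpatientGroup
from .parameters import (
    ConfigurationError,
    ModelConfig,
    ParameterError,
    STRATUM_LABELS,
)

__all__ = [
    "RECORD_COLUMNS",
    "SimulationSummary",
    "ParameterEstimate",
    "simulate_patients",
    "summarize",
    "expected_cost_per_patient",
    "simulate_registry",
    "recover_parameters",
]

#: Stable column order of a patient-record frame (one row per PatientRecord).
RECORD_COLUMNS = (
    "patient_id",
    "stratum",
    "severe_bp",
    "initially_hospitalized",
    "developed_pe",
    "birth_mode",
    "branch_id",
    "pathway_cost",
)


@dataclass(frozen=True)
class SimulationSummary:
    n: int
    mean_cost_per_patient: float
    se_mean: float  # NaN when undefined (single record)
    hospitalized_fraction: float
    stratum_counts: dict[str, int]
    scaled_total: float


@dataclass(frozen=True)
class ParameterEstimate:
    estimate: float
    ci_low: float
    ci_high: float
    n_obs: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.estimate)

    def covers(self, value: float) -> bool:
        return self.defined and self.ci_low <= value <= self.ci_high


def simulate_patients(config: ModelConfig, arm: str, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` synthetic pregnancies for one arm.

    Returns a DataFrame with :data:`RECORD_COLUMNS`; identical
    (config, arm, n, seed) yield identical frames. ``pathway_cost`` is the
    configured per-patient cost of the assigned branch plus the initial
    consultation everyone receives (the per-test cost is not a pathway cost
    and is accounted at strategy level).
    """
    if n <= 0:
        raise ParameterError(f"n must be positive, got {n}")
    if arm not in config.strategies:
        raise ParameterError(f"unknown arm {arm!r}")
    cascade = config.cascades.get(arm)
    if cascade is None:
        raise ConfigurationError(f"cascades.{arm}", "simulation requires probability-mode parameters")

    rng = np.random.default_rng(seed)
    branches = config.strategies[arm]
    per_patient = {b_id: float(b.per_patient_cost) for b_id, b in branches.items()}
    initial_cost = per_patient.get("initial_consultation", 0.0)

    if arm == "test":
        prevalences = np.array([config.stratum(lbl).prevalence for lbl in STRATUM_LABELS])
        p_hosp_by_stratum = np.array([config.stratum(lbl).p_hospitalized for lbl in STRATUM_LABELS])
        stratum_idx = rng.choice(len(STRATUM_LABELS), size=n, p=prevalences / prevalences.sum())
        hospitalized = rng.random(n) < p_hosp_by_stratum[stratum_idx]
        severe_bp = hospitalized & (stratum_idx == 0)
        stratum = np.array(STRATUM_LABELS, dtype=object)[stratum_idx]
    else:
        if cascade.p_hospitalized is None:
            raise ConfigurationError(f"cascades.{arm}.p_hospitalized", "required for this arm")
        hospitalized = rng.random(n) < cascade.p_hospitalized
        severe_bp = np.zeros(n, dtype=bool)
        stratum = np.full(n, None, dtype=object)

    pe_draw = rng.random(n)
    developed_pe = np.where(
        hospitalized,
        pe_draw < cascade.p_pe_given_hospitalized,
        pe_draw < cascade.p_pe_after_ambulatory,
    )
    low_draw = rng.random(n) < cascade.p_low_given_ambulatory
    csection = rng.random(n) < config.birth.csection_share

    branch_id = np.empty(n, dtype=object)
    branch_id[hospitalized & developed_pe] = "suspected_pe_birth"
    branch_id[hospitalized & ~developed_pe] = "intermediate_after_hosp"
    branch_id[~hospitalized & developed_pe] = "pe_after_ambulatory"
    ambulatory_no_pe = ~hospitalized & ~developed_pe
    branch_id[ambulatory_no_pe & low_draw] = "low"
    branch_id[ambulatory_no_pe & ~low_draw] = "intermediate"

    cost = np.vectorize(per_patient.__getitem__, otypes=[float])(branch_id) + initial_cost

    return pd.DataFrame(
        {
            "patient_id": [f"{arm}-{i:07d}" for i in range(n)],
            "stratum": stratum,
            "severe_bp": severe_bp,
            "initially_hospitalized": hospitalized,
            "developed_pe": developed_pe,
            "birth_mode": np.where(csection, "csection", "vaginal"),
            "branch_id": branch_id,
            "pathway_cost": cost,
        },
        columns=list(RECORD_COLUMNS),
    )


def summarize(records: pd.DataFrame, cohort_scale: int) -> SimulationSummary:
    """Mean pathway cost, its Monte-Carlo standard error, and scaled totals."""
    if records is None or len(records) == 0:
        raise ParameterError("no records to summarize")
    costs = records["pathway_cost"].to_numpy(dtype=float)
    n = len(costs)
    mean = float(costs.mean())
    se = float(costs.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    strata = records["stratum"].dropna()
    return SimulationSummary(
        n=n,
        mean_cost_per_patient=mean,
        se_mean=se,
        hospitalized_fraction=float(records["initially_hospitalized"].mean()),
        stratum_counts={k: int(v) for k, v in strata.value_counts().items()},
        scaled_total=mean * cohort_scale,
    )


def expected_cost_per_patient(config: ModelConfig, arm: str) -> float:
    """Deterministic probability-mode expectation of the medical pathway cost."""
    result = strategy_cost(config, arm, mode="probability")
    return float(result.medical_cost_total) / config.cohort_size


def _lognormal_params(median: float, mean: float, what: str) -> tuple[float, float]:
    """(mu, sigma) with exp(mu) = median and mean/median fixing sigma."""
    if median <= 0 or mean <= 0:
        raise ConfigurationError(what, "median and mean must be positive")
    if mean <= median:
        raise ConfigurationError(
            what, f"mean {mean} must exceed median {median} for a log-normal family"
        )
    return math.log(median), math.sqrt(2.0 * math.log(mean / median))


def simulate_registry(groups: list[InpatientGroup], n: int, seed: int) -> pd.DataFrame:
    """Synthetic inpatient registry records (group, length of stay, cost).

    Group membership is multinomial in the published group sizes; within a
    group, stay and cost are drawn from log-normals whose sample median and
    mean converge to the published pair as n grows.
    """
    if n <= 0:
        raise ParameterError(f"n must be positive, got {n}")
    if not groups:
        raise ParameterError("no inpatient groups given")
    rng = np.random.default_rng(seed)
    sizes = np.array([g.n for g in groups], dtype=float)
    membership = rng.choice(len(groups), size=n, p=sizes / sizes.sum())
    los = np.empty(n)
    cost = np.empty(n)
    for idx, group in enumerate(groups):
        mask = membership == idx
        k = int(mask.sum())
        if k == 0:
            continue
        mu_l, sig_l = _lognormal_params(group.los_median_days, group.los_mean_days, f"{group.label}.los")
        mu_c, sig_c = _lognormal_params(float(group.cost_median), float(group.cost_mean), f"{group.label}.cost")
        los[mask] = rng.lognormal(mu_l, sig_l, size=k)
        cost[mask] = rng.lognormal(mu_c, sig_c, size=k)
    labels = np.array([g.label for g in groups], dtype=object)
    return pd.DataFrame({"group": labels[membership], "los_days": los, "cost": cost})


def recover_parameters(records: pd.DataFrame, alpha: float = 0.05) -> dict[str, ParameterEstimate]:
    """Maximum-likelihood recovery of stratum prevalences and admission rates.

    Point estimates are sample proportions; intervals are exact
    (Clopper-Pearson) binomial intervals, so nominal coverage is guaranteed
    from below. A stratum with zero observations yields an undefined (NaN)
    admission-rate estimate.
    """
    strata = records["stratum"]
    if strata.isna().all():
        raise ParameterError("records carry no stratum information (no-test arm?)")
    n = len(records)
    out: dict[str, ParameterEstimate] = {}
    for label in STRATUM_LABELS:
        in_stratum = strata == label
        k = int(in_stratum.sum())
        low, high = proportion_confint(k, n, alpha=alpha, method="beta")
        out[f"prevalence_{label}"] = ParameterEstimate(k / n, float(low), float(high), n)
        if k == 0:
            out[f"p_hospitalized_{label}"] = ParameterEstimate(float("nan"), float("nan"), float("nan"), 0)
            continue
        admitted = int(records.loc[in_stratum, "initially_hospitalized"].sum())
        low, high = proportion_confint(admitted, k, alpha=alpha, method="beta")
        out[f"p_hospitalized_{label}"] = ParameterEstimate(admitted / k, float(low), float(high), k)
    return out
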