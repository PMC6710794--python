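"""Five-year budget impact of growing test uptake, with discounting.

Each projection year mixes tested and untested patients at the scheduled
uptake; yearly cash flows are discounted at (1+r)^-(y-1), i.e. the first
year is undiscounted — the convention that reproduces the published
projection. Differences are computed from the unrounded per-patient costs
of the two strategies, so the yearly difference equals
n_test x (per-patient delta) x discount factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort_tree import strategy_cost
from .parameters import ModelConfig, ParameterError, UptakeSchedule

__all__ = ["YearRow", "BudgetImpactResult", "discount_factor", "run_budget_impact", "run_budget_impact_from_config"]


@dataclass(frozen=True)
class YearRow:
    year: int
    n_no_test: int
    cost_no_test_patients: float
    n_test: int
    cost_test_patients: float
    mixed_total: float
    counterfactual_no_test_total: float
    difference: float


@dataclass(frozen=True)
class BudgetImpactResult:
    per_year: tuple[YearRow, ...]
    cumulative_difference: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(row) for row in self.per_year])


def discount_factor(rate: float, year: int) -> float:
    """(1+rate)^-(year-1); year is 1-based and year 1 is undiscounted."""
    if year < 1:
        raise ParameterError(f"year index must be >= 1, got {year}")
    if rate < 0:
        raise ParameterError(f"discount rate must be >= 0, got {rate}")
    return (1.0 + rate) ** (-(year - 1))


def run_budget_impact(
    per_patient_no_test: float,
    per_patient_test: float,
    cohort_size: int,
    schedule: UptakeSchedule,
) -> BudgetImpactResult:
    """Project mixed-cohort costs year by year under an uptake schedule.

    For year y with n tested patients: the mixed total is
    n x c_test + (cohort - n) x c_no_test, discounted; the counterfactual is
    the whole cohort at c_no_test, discounted; their difference accumulates
    into the headline cumulative saving.
    """
    rows = []
    cumulative = 0.0
    for year, n_test in schedule.years:
        if not 0 <= n_test <= cohort_size:
            raise ParameterError(f"year {year}: n_test {n_test} outside [0, {cohort_size}]")
        factor = discount_factor(schedule.discount_rate, year)
        n_no = cohort_size - n_test
        cost_no = n_no * per_patient_no_test * factor
        cost_test = n_test * per_patient_test * factor
        counterfactual = cohort_size * per_patient_no_test * factor
        difference = (cost_no + cost_test) - counterfactual
        cumulative += difference
        rows.append(
            YearRow(
                year=year,
                n_no_test=n_no,
                cost_no_test_patients=cost_no,
                n_test=n_test,
                cost_test_patients=cost_test,
                mixed_total=cost_no + cost_test,
                counterfactual_no_test_total=counterfactual,
                difference=difference,
            )
        )
    return BudgetImpactResult(per_year=tuple(rows), cumulative_difference=cumulative)


def run_budget_impact_from_config(config: ModelConfig, mode: str = "counts") -> BudgetImpactResult:
    """Budget impact at the per-patient costs of the configured strategies."""
    no_test = strategy_cost(config, "no_test", mode)
    test = strategy_cost(config, "test", mode)
    return run_budget_impact(
        float(no_test.per_patient), float(test.per_patient), config.cohort_size, config.uptake
    )
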