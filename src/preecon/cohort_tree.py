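"""Decision-tree evaluation: branch allocation, strategy costs, comparison.

The model is a single-pass expected-cost decision tree. A cohort of
pregnancies with suspected preeclampsia is distributed over mutually
exclusive management branches (low / intermediate outpatient follow-up,
admission with later discharge, hospitalization until birth); each branch
carries a per-patient cost, and strategies differ only in how the cohort is
allocated (standard of care vs. allocation informed by the sFlt-1/PlGF
ratio) plus the per-test cost in the test arm.

Two allocation modes exist because the published branch occupancies and the
published rate cascade are not mutually consistent:

``counts``
    the configured base-case occupancies, reproducing the published cost
    table cell-for-cell (the default);
``probability``
    expected occupancies from the rate cascade (stratum prevalences x
    per-stratum admission rates in the test arm, the 36%/27% admission
    cascade under standard of care), used by the sensitivity and
    microsimulation machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal

from .money import cents, eur, round_eur
from .parameters import (
    HOSPITALIZED_UNTIL_BIRTH_BRANCHES,
    ConfigurationError,
    ModelConfig,
    ParameterError,
)

__all__ = [
    "StrategyResult",
    "ComparisonResult",
    "branch_shares",
    "allocate_cohort",
    "strategy_cost",
    "compare",
    "hospitalized_count",
]

MODES = ("counts", "probability")


@dataclass(frozen=True)
class StrategyResult:
    """Evaluated totals of one strategy."""

    strategy: str
    branch_results: tuple[tuple[str, float, Decimal], ...]  # (branch_id, n, total cost)
    medical_cost_total: Decimal
    test_cost_total: Decimal
    overall_total: Decimal
    per_patient: Decimal
    hospitalized_with_birth: float


@dataclass(frozen=True)
class ComparisonResult:
    """Test-minus-no-test deltas; negative numbers are savings."""

    per_branch_delta: tuple[tuple[str, Decimal], ...]
    delta_medical: Decimal
    delta_total: Decimal
    delta_per_patient: Decimal

    @property
    def per_patient_saving(self) -> Decimal:
        """Positive per-patient saving of the test strategy (display sign)."""
        return -self.delta_per_patient


def _check_strategy(config: ModelConfig, strategy: str) -> None:
    if strategy not in config.strategies:
        raise ParameterError(f"unknown strategy {strategy!r}")


def branch_shares(config: ModelConfig, strategy: str) -> dict[str, float]:
    """Management-branch probabilities from the rate cascade of one arm.

    In the test arm the admission probability is the prevalence-weighted
    per-stratum admission rate; under standard of care it is the configured
    arm-level rate. Admitted patients progress to preeclampsia (remaining
    hospitalized until birth) or are discharged to intermediate follow-up;
    ambulatory patients may still develop preeclampsia, otherwise they split
    between low and intermediate follow-up.
    """
    _check_strategy(config, strategy)
    cascade = config.cascades.get(strategy)
    if cascade is None:
        raise ConfigurationError(f"cascades.{strategy}", "probability mode requires cascade parameters")
    if strategy == "test":
        p_hosp = sum(s.prevalence * s.p_hospitalized for s in config.strata)
    else:
        if cascade.p_hospitalized is None:
            raise ConfigurationError(
                f"cascades.{strategy}.p_hospitalized", "required for the no-test cascade"
            )
        p_hosp = cascade.p_hospitalized
    ambulatory = 1.0 - p_hosp
    p_pe_amb = cascade.p_pe_after_ambulatory
    non_pe_amb = ambulatory * (1.0 - p_pe_amb)
    return {
        "low": non_pe_amb * cascade.p_low_given_ambulatory,
        "intermediate": non_pe_amb * (1.0 - cascade.p_low_given_ambulatory),
        "intermediate_after_hosp": p_hosp * (1.0 - cascade.p_pe_given_hospitalized),
        "suspected_pe_birth": p_hosp * cascade.p_pe_given_hospitalized,
        "pe_after_ambulatory": ambulatory * p_pe_amb,
    }


def allocate_cohort(config: ModelConfig, strategy: str, mode: str = "counts") -> list[tuple[str, float]]:
    """Branch occupancies for one strategy, in configured branch order.

    The branch applying to every patient (initial consultation) always
    carries the full cohort; the management branches carry the configured
    counts or the cascade expectations depending on ``mode``.
    """
    _check_strategy(config, strategy)
    if mode not in MODES:
        raise ParameterError(f"unknown allocation mode {mode!r}")
    branches = config.strategies[strategy]
    if mode == "counts":
        return [(b.branch_id, b.n_patients) for b in branches.values()]
    shares = branch_shares(config, strategy)
    allocation = []
    for b in branches.values():
        if b.applies_to_all:
            allocation.append((b.branch_id, float(config.cohort_size)))
        else:
            allocation.append((b.branch_id, config.cohort_size * shares[b.branch_id]))
    return allocation


def strategy_cost(config: ModelConfig, strategy: str, mode: str = "counts") -> StrategyResult:
    """Evaluate one strategy: per-branch totals and the accounting identity.

    In counts mode a branch with a stored total cost contributes it exactly
    (column-sum arithmetic); otherwise the total is occupancy x per-patient
    cost at cent precision. The test strategy additionally pays cohort x
    test unit cost.
    """
    allocation = dict(allocate_cohort(config, strategy, mode))
    branches = config.strategies[strategy]
    branch_results = []
    medical = Decimal(0)
    hospitalized_birth = 0.0
    for branch_id, branch in branches.items():
        n = allocation[branch_id]
        if mode == "counts" and branch.total_cost is not None:
            total = branch.total_cost
        else:
            total = cents(eur(n) * branch.per_patient_cost)
        branch_results.append((branch_id, n, total))
        medical += total
        if branch_id in HOSPITALIZED_UNTIL_BIRTH_BRANCHES:
            hospitalized_birth += n
    if strategy == "test":
        test_cost = cents(eur(config.cohort_size) * config.test_unit_cost)
    else:
        test_cost = Decimal(0)
    overall = medical + test_cost
    per_patient = overall / eur(config.cohort_size)
    return StrategyResult(
        strategy=strategy,
        branch_results=tuple(branch_results),
        medical_cost_total=medical,
        test_cost_total=test_cost,
        overall_total=overall,
        per_patient=per_patient,
        hospitalized_with_birth=hospitalized_birth,
    )


def compare(config: ModelConfig, mode: str = "counts") -> ComparisonResult:
    """Test-strategy minus no-test-strategy cost deltas."""
    no_test = strategy_cost(config, "no_test", mode)
    test = strategy_cost(config, "test", mode)
    totals_no = dict((b, t) for b, _, t in no_test.branch_results)
    totals_t = dict((b, t) for b, _, t in test.branch_results)
    per_branch = tuple(
        (branch_id, totals_t.get(branch_id, Decimal(0)) - totals_no.get(branch_id, Decimal(0)))
        for branch_id in {**totals_no, **totals_t}
    )
    delta_total = test.overall_total - no_test.overall_total
    return ComparisonResult(
        per_branch_delta=per_branch,
        delta_medical=test.medical_cost_total - no_test.medical_cost_total,
        delta_total=delta_total,
        delta_per_patient=delta_total / eur(config.cohort_size),
    )


def hospitalized_count(result: StrategyResult) -> int:
    """Patients hospitalized until birth (display integer, rounded half-up)."""
    return round_eur(result.hospitalized_with_birth)
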