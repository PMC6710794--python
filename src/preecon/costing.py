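"""Tariff-level cost composition.

Outpatient consultation costs are composed from an itemized service catalog
(Tarmed-style positions in EUR); inpatient episodes carry DRG-style flat
costs per registry group; delivery without preeclampsia is a C-section-share
blend of two DRG rates.

Two billing subtleties drive this module's design and both are encoded in
the shipped catalog rather than in code:

* the venipuncture fee is administered in every setting but is not billable
  within the per-consultation total (lab analyses carry it), so each item
  has a per-setting ``billable`` flag;
* the intermediate per-consultation total cannot be reconstructed from its
  itemized positions, so the published total is stored as an override and
  used wherever the intermediate per-visit cost is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .money import cents, eur
from .parameters import ModelConfig, ParameterError

__all__ = [
    "SETTINGS",
    "ServiceItem",
    "OutpatientSchedule",
    "InpatientGroup",
    "BirthCostModel",
    "load_service_catalog",
    "load_inpatient_groups",
    "visit_cost",
    "weekly_cost",
    "inpatient_total",
    "blended_birth_cost",
    "bottom_up_branch_cost",
    "reconcile_branch_costs",
]

SETTINGS = ("initial", "low", "intermediate")


@dataclass(frozen=True)
class ServiceItem:
    """One tariff position; a cost of None means not performed in the setting."""

    name: str
    cost_initial: Decimal | None
    cost_low: Decimal | None
    cost_intermediate: Decimal | None
    billable_initial: bool
    billable_low: bool
    billable_intermediate: bool

    def cost(self, setting: str) -> Decimal | None:
        _check_setting(setting)
        return getattr(self, f"cost_{setting}")

    def billable(self, setting: str) -> bool:
        _check_setting(setting)
        return getattr(self, f"billable_{setting}")


@dataclass(frozen=True)
class OutpatientSchedule:
    """Visit frequency of a follow-up setting (e.g. 6 visits in 8 weeks)."""

    setting: str
    duration_weeks: int
    visits_in_duration: int


@dataclass(frozen=True)
class InpatientGroup:
    """One registry group: size, length of stay, DRG-based episode cost."""

    label: str
    n: int
    los_median_days: float
    los_mean_days: float
    cost_median: Decimal
    cost_mean: Decimal


@dataclass(frozen=True)
class BirthCostModel:
    """Delivery without preeclampsia: vaginal/C-section costs and the share."""

    csection_share: float
    vaginal_cost_no_pe: Decimal
    csection_cost_no_pe: Decimal


def _check_setting(setting: str) -> None:
    if setting not in SETTINGS:
        raise ParameterError(f"unknown outpatient setting {setting!r}")


def _data_path(name: str) -> Path:
    return Path(resources.files("preecon").joinpath(f"data/{name}"))


def load_service_catalog(path: str | Path | None = None) -> list[ServiceItem]:
    """Read the outpatient service catalog (shipped catalog by default)."""
    frame = pd.read_csv(path or _data_path("outpatient_services.csv"))
    items = []
    for row in frame.itertuples(index=False):
        def _cost(value):
            return None if pd.isna(value) else eur(value)

        def _flag(value):
            return bool(int(value)) if not pd.isna(value) else False

        items.append(
            ServiceItem(
                name=row.name,
                cost_initial=_cost(row.cost_initial),
                cost_low=_cost(row.cost_low),
                cost_intermediate=_cost(row.cost_intermediate),
                billable_initial=_flag(row.billable_initial),
                billable_low=_flag(row.billable_low),
                billable_intermediate=_flag(row.billable_intermediate),
            )
        )
    return items


def load_inpatient_groups(path: str | Path | None = None) -> list[InpatientGroup]:
    """Read the inpatient registry groups (shipped groups by default)."""
    frame = pd.read_csv(path or _data_path("inpatient_groups.csv"))
    return [
        InpatientGroup(
            label=row.label,
            n=int(row.n),
            los_median_days=float(row.los_median_days),
            los_mean_days=float(row.los_mean_days),
            cost_median=eur(row.cost_median_eur),
            cost_mean=eur(row.cost_mean_eur),
        )
        for row in frame.itertuples(index=False)
    ]


def visit_cost(
    catalog: Sequence[ServiceItem],
    setting: str,
    *,
    billable_only: bool = True,
    overrides: Mapping[str, Decimal] | None = None,
) -> Decimal:
    """Cost of one consultation in a setting.

    With ``billable_only`` (the default) only items flagged billable within
    the per-consultation total are summed — this reproduces the published
    totals (e.g. 259.64 for the low setting). With ``billable_only=False``
    every administered service counts (266.06 for low), which is the basis
    for weekly costs. A published override, when present for the setting,
    takes precedence.
    """
    _check_setting(setting)
    if overrides and setting in overrides:
        return eur(overrides[setting])
    total = Decimal(0)
    for item in catalog:
        cost = item.cost(setting)
        if cost is None:
            continue
        if billable_only and not item.billable(setting):
            continue
        total += cost
    return cents(total)


def weekly_cost(
    catalog: Sequence[ServiceItem],
    schedule: OutpatientSchedule,
    *,
    overrides: Mapping[str, Decimal] | None = None,
) -> Decimal:
    """Average weekly cost of a follow-up setting.

    Per-visit cost (including every administered service, or the published
    override) times visits per duration, divided by the duration in weeks;
    rounded to cents at the final step. Low: 266.06 x 6 / 8 = 199.54.
    """
    if schedule.duration_weeks <= 0:
        raise ParameterError(f"duration must be positive, got {schedule.duration_weeks} weeks")
    per_visit = visit_cost(catalog, schedule.setting, billable_only=False, overrides=overrides)
    return cents(per_visit * schedule.visits_in_duration / schedule.duration_weeks)


def inpatient_total(groups: Iterable[InpatientGroup]) -> Decimal:
    """Total registry cost: sum of group size x mean episode cost."""
    groups = list(groups)
    if not groups:
        raise ParameterError("no inpatient groups given")
    return cents(sum((g.cost_mean * g.n for g in groups), Decimal(0)))


def blended_birth_cost(model: BirthCostModel) -> Decimal:
    """Expected no-preeclampsia delivery cost at the configured C-section share."""
    share = model.csection_share
    if not 0 <= share <= 1:
        raise ParameterError(f"C-section share outside [0, 1]: {share}")
    blended = eur(1 - share) * model.vaginal_cost_no_pe + eur(share) * model.csection_cost_no_pe
    return cents(blended)


def _pe_birth_mean(groups: Sequence[InpatientGroup]) -> Decimal:
    """Size-weighted mean episode cost over the preeclamptic delivery groups."""
    birth_groups = [g for g in groups if g.label in ("vaginal_with_pe", "csection_with_pe")]
    if not birth_groups:
        raise ParameterError("no preeclamptic delivery groups in registry")
    total_n = sum(g.n for g in birth_groups)
    return cents(sum((g.cost_mean * g.n for g in birth_groups), Decimal(0)) / total_n)


def bottom_up_branch_cost(
    branch_id: str,
    catalog: Sequence[ServiceItem],
    schedules: Mapping[str, OutpatientSchedule],
    groups: Sequence[InpatientGroup],
    birth: BirthCostModel,
    *,
    weeks_outpatient: int = 8,
    weeks_after_discharge: int = 2,
    overrides: Mapping[str, Decimal] | None = None,
) -> Decimal:
    """Per-patient branch cost composed from tariff atoms.

    The alternative to the implied (branch-total / occupancy) costing mode:
    outpatient weeks x weekly cost, plus the inpatient episode mean where the
    pathway includes an admission, plus the delivery cost (blended no-PE cost
    for outpatient-managed pathways, registry PE-delivery mean otherwise).
    """
    blended = blended_birth_cost(birth)
    suspected = {g.label: g for g in groups}.get("suspected_no_birth")
    if branch_id == "initial_consultation":
        return visit_cost(catalog, "initial", billable_only=False, overrides=overrides)
    if branch_id == "low":
        return cents(weeks_outpatient * weekly_cost(catalog, schedules["low"], overrides=overrides) + blended)
    if branch_id == "intermediate":
        return cents(
            weeks_outpatient * weekly_cost(catalog, schedules["intermediate"], overrides=overrides) + blended
        )
    if branch_id == "intermediate_after_hosp":
        if suspected is None:
            raise ParameterError("registry lacks the suspected_no_birth group")
        follow_up = weeks_after_discharge * weekly_cost(
            catalog, schedules["intermediate"], overrides=overrides
        )
        return cents(suspected.cost_mean + follow_up + blended)
    if branch_id == "suspected_pe_birth":
        return _pe_birth_mean(groups)
    if branch_id == "pe_after_ambulatory":
        follow_up = weeks_outpatient * weekly_cost(catalog, schedules["low"], overrides=overrides)
        return cents(follow_up + _pe_birth_mean(groups))
    raise ParameterError(f"unknown branch {branch_id!r}")


def reconcile_branch_costs(
    config: ModelConfig,
    catalog: Sequence[ServiceItem] | None = None,
    groups: Sequence[InpatientGroup] | None = None,
) -> pd.DataFrame:
    """Implied vs bottom-up per-patient costs, per strategy and branch.

    Branches where the two modes disagree are *listed* with their relative
    gap, not forced into agreement: the implied costs stay the base case.
    """
    catalog = catalog if catalog is not None else load_service_catalog()
    groups = groups if groups is not None else load_inpatient_groups()
    schedules = {
        setting: OutpatientSchedule(setting, entry["duration_weeks"], entry["visits_in_duration"])
        for setting, entry in config.outpatient_schedules.items()
    }
    birth = BirthCostModel(
        csection_share=config.birth.csection_share,
        vaginal_cost_no_pe=config.birth.vaginal_cost_no_pe,
        csection_cost_no_pe=config.birth.csection_cost_no_pe,
    )
    rows = []
    for strategy, branches in config.strategies.items():
        weeks_post = config.weeks_after_discharge.get(strategy, 2)
        for branch_id, branch in branches.items():
            implied = branch.per_patient_cost
            bottom_up = bottom_up_branch_cost(
                branch_id,
                catalog,
                schedules,
                groups,
                birth,
                weeks_after_discharge=weeks_post,
                overrides=config.visit_total_overrides,
            )
            rel_gap = float((bottom_up - implied) / implied) if implied else float("nan")
            rows.append(
                {
                    "strategy": strategy,
                    "branch_id": branch_id,
                    "implied_per_patient": float(cents(implied)),
                    "bottom_up_per_patient": float(bottom_up),
                    "relative_gap": rel_gap,
                    "reconcilable_within_0.5pct": abs(rel_gap) <= 0.005,
                }
            )
    return pd.DataFrame(rows)
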