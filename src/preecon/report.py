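"""Report writers: comparison and budget-impact tables, tornado CSV, manifests.

Monetary CSV cells carry two decimals; the human-readable summary rounds to
whole euros, matching how the headline figures are conventionally printed.
Every CSV written here reads back with :func:`read_csv` (plain pandas), and
each command writes a run manifest so that any reported number is
reproducible from (config digest, command, seed).
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Iterable

import pandas as pd
import yaml

from .budget_impact import BudgetImpactResult
from .cohort_tree import ComparisonResult, StrategyResult, hospitalized_count
from .money import round_eur
from .parameters import ModelConfig
from .sensitivity import TornadoEntry

__all__ = [
    "config_digest",
    "comparison_frame",
    "budget_impact_frame",
    "tornado_frame",
    "write_csv",
    "read_csv",
    "comparison_summary",
    "write_manifest",
]


def config_digest(config: ModelConfig) -> str:
    """SHA-256 over the canonicalized configuration document."""
    canonical = yaml.safe_dump(config.raw, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _money_cell(value) -> float:
    return round(float(value), 2)


def comparison_frame(
    no_test: StrategyResult, test: StrategyResult, cmp: ComparisonResult
) -> pd.DataFrame:
    """Branch-by-branch comparison table (rows = branches plus totals)."""
    deltas = dict(cmp.per_branch_delta)
    totals_no = {b: (n, t) for b, n, t in no_test.branch_results}
    rows = []
    for branch_id, n_t, total_t in test.branch_results:
        n_no, total_no = totals_no.get(branch_id, (0.0, 0))
        rows.append(
            {
                "row": branch_id,
                "n_no_test": n_no,
                "cost_no_test_eur": _money_cell(total_no),
                "n_test": n_t,
                "cost_test_eur": _money_cell(total_t),
                "difference_eur": _money_cell(deltas.get(branch_id, 0)),
            }
        )
    rows.append(
        {
            "row": "total_medical_costs",
            "n_no_test": no_test.branch_results[0][1],
            "cost_no_test_eur": _money_cell(no_test.medical_cost_total),
            "n_test": test.branch_results[0][1],
            "cost_test_eur": _money_cell(test.medical_cost_total),
            "difference_eur": _money_cell(cmp.delta_medical),
        }
    )
    rows.append(
        {
            "row": "test_evaluation",
            "n_no_test": 0,
            "cost_no_test_eur": 0.0,
            "n_test": test.branch_results[0][1],
            "cost_test_eur": _money_cell(test.test_cost_total),
            "difference_eur": _money_cell(test.test_cost_total),
        }
    )
    rows.append(
        {
            "row": "overall_total",
            "n_no_test": no_test.branch_results[0][1],
            "cost_no_test_eur": _money_cell(no_test.overall_total),
            "n_test": test.branch_results[0][1],
            "cost_test_eur": _money_cell(test.overall_total),
            "difference_eur": _money_cell(cmp.delta_total),
        }
    )
    rows.append(
        {
            "row": "per_patient",
            "n_no_test": no_test.branch_results[0][1],
            "cost_no_test_eur": _money_cell(no_test.per_patient),
            "n_test": test.branch_results[0][1],
            "cost_test_eur": _money_cell(test.per_patient),
            "difference_eur": _money_cell(cmp.delta_per_patient),
        }
    )
    return pd.DataFrame(rows)


def budget_impact_frame(result: BudgetImpactResult) -> pd.DataFrame:
    """Per-year projection plus the cumulative row."""
    frame = result.to_frame()
    for column in frame.columns:
        if column.startswith(("cost_", "mixed", "counterfactual")) or column == "difference":
            frame[column] = frame[column].round(2)
    total = {
        "year": "total",
        "n_no_test": int(frame["n_no_test"].sum()),
        "cost_no_test_patients": round(float(frame["cost_no_test_patients"].sum()), 2),
        "n_test": int(frame["n_test"].sum()),
        "cost_test_patients": round(float(frame["cost_test_patients"].sum()), 2),
        "mixed_total": round(float(frame["mixed_total"].sum()), 2),
        "counterfactual_no_test_total": round(float(frame["counterfactual_no_test_total"].sum()), 2),
        "difference": round(result.cumulative_difference, 2),
    }
    return pd.concat([frame, pd.DataFrame([total])], ignore_index=True)


def tornado_frame(entries: Iterable[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label": e.label,
                "per_patient_saving_eur": round(e.per_patient_saving, 2),
                "delta_vs_base_eur": round(e.delta_vs_base, 2),
            }
            for e in entries
        ]
    )


def write_csv(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return path


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def comparison_summary(
    no_test: StrategyResult, test: StrategyResult, cmp: ComparisonResult
) -> str:
    """Whole-euro human summary of the strategy comparison."""
    lines = [
        f"Cohort: {round_eur(no_test.branch_results[0][1])} pregnancies with suspected preeclampsia",
        f"No-test strategy total: EUR {round_eur(no_test.overall_total):,}",
        f"Test strategy total:    EUR {round_eur(test.overall_total):,} "
        f"(incl. EUR {round_eur(test.test_cost_total):,} for sFlt-1/PlGF testing)",
        f"Hospitalized until birth: {hospitalized_count(no_test)} (no-test) vs {hospitalized_count(test)} (test)",
        f"Difference: EUR {round_eur(cmp.delta_total):,} "
        f"({round_eur(cmp.delta_per_patient):,} per patient)",
        f"Per-patient saving of the test strategy: EUR {round_eur(cmp.per_patient_saving):,}",
    ]
    return "\n".join(lines)


def write_manifest(
    outdir: str | Path,
    command: str,
    config: ModelConfig,
    outputs: Iterable[str | Path],
    seed: int | None = None,
) -> Path:
    """Write the run manifest (digest, command, timestamp, seed, outputs)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "command": command,
        "config_digest": config_digest(config),
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "outputs": [str(Path(p)) for p in outputs],
    }
    path = outdir / f"manifest_{command}.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
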