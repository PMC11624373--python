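"""Result tables, serialisation, and run manifests.

CSV output mirrors the published layout (cost categories as rows, device
labels as columns, difference columns per comparator) with values rounded
half-up to whole 2023 USD; JSON output carries full unrounded precision.
Every CLI run appends a :class:`RunManifest` line (timestamp, package
version, input digests, argv, outputs) to a JSON-lines log so results can
be traced back to their inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Any, Sequence

import pandas as pd

from .engine import COST_CATEGORIES, compare_devices, per_patient_costs
from .parameters import ModelParameters
from .population import population_summary
from .sensitivity import TornadoTable

__all__ = [
    "round_usd",
    "CATEGORY_LABELS",
    "per_patient_frame",
    "per_patient_json",
    "population_frame",
    "population_json",
    "dsa_frame",
    "plot_tornado",
    "RunManifest",
    "append_manifest",
    "file_digest",
]

#: Human-readable row labels, in published-table order. All amounts 2023 USD.
CATEGORY_LABELS: dict[str, str] = {
    "initial_procedure": "Initial implant: procedure",
    "initial_complications": "Initial implant: complications",
    "initial_followups": "Initial implant: postprocedure follow-ups",
    "initial_total": "Initial implant: total",
    "replacement_procedures": "Replacements: procedures",
    "replacement_complications": "Replacements: complications",
    "replacement_followups": "Replacements: postprocedure follow-ups",
    "replacement_total": "Replacements: total",
    "routine_followups": "Routine follow-ups",
    "total": "Total",
}


def round_usd(x: float) -> int:
    """Round to whole dollars, half away from zero (presentation only)."""
    return int(Decimal(repr(float(x))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def per_patient_frame(params: ModelParameters, reference: str | None = None,
                      rounded: bool = True) -> pd.DataFrame:
    """Per-patient cost table: one row per category, one column per device,
    plus absolute/percent difference columns versus the reference device
    (first device by default)."""
    labels = params.device_labels
    reference = reference if reference is not None else labels[0]
    breakdowns = {label: per_patient_costs(params, label).as_dict() for label in labels}

    data: dict[str, list] = {"category": [CATEGORY_LABELS[c] for c in COST_CATEGORIES]}
    for label in labels:
        col = [breakdowns[label][c] for c in COST_CATEGORIES]
        data[f"{label} (USD)"] = [round_usd(v) for v in col] if rounded else col
    for label in labels:
        if label == reference:
            continue
        cmp = compare_devices(params, reference, label)
        diffs = [cmp.absolute[c] for c in COST_CATEGORIES]
        pcts = [cmp.percent[c] for c in COST_CATEGORIES]
        data[f"{label} - {reference} (USD)"] = (
            [round_usd(v) for v in diffs] if rounded else diffs)
        data[f"{label} - {reference} (%)"] = [
            (round(p) if rounded else p) if p is not None else None for p in pcts]
    return pd.DataFrame(data)


def per_patient_json(params: ModelParameters, reference: str | None = None) -> dict[str, Any]:
    """Unrounded per-patient results keyed by device, plus differences."""
    labels = params.device_labels
    reference = reference if reference is not None else labels[0]
    out: dict[str, Any] = {
        "units": "2023 USD",
        "reference": reference,
        "devices": {label: per_patient_costs(params, label).as_dict() for label in labels},
        "differences": {},
    }
    for label in labels:
        if label == reference:
            continue
        cmp = compare_devices(params, reference, label)
        out["differences"][label] = {"absolute": cmp.absolute, "percent": cmp.percent}
    return out


def population_frame(params: ModelParameters, reference: str | None = None,
                     rounded: bool = True) -> pd.DataFrame:
    """Cumulative population replacement costs, one row per device plus
    difference rows versus the reference."""
    result = population_summary(params, reference)
    rows = [
        {"row": label, "cumulative_replacement_cost_usd":
            round_usd(v) if rounded else v, "percent_vs_reference": None}
        for label, v in result.cumulative_replacement_cost.items()
    ]
    for (ref, comp), (money, pct) in result.cumulative_differences.items():
        rows.append({
            "row": f"{comp} - {ref}",
            "cumulative_replacement_cost_usd": round_usd(money) if rounded else money,
            "percent_vs_reference": (round(pct) if rounded else pct) if pct is not None else None,
        })
    return pd.DataFrame(rows)


def population_json(params: ModelParameters, reference: str | None = None) -> dict[str, Any]:
    result = population_summary(params, reference)
    return {
        "units": "2023 USD",
        "annual_implants": result.annual_implants,
        "cohort_entry_years": result.cohort_entry_years,
        "total_patients": result.total_patients,
        "cumulative_replacement_cost": dict(result.cumulative_replacement_cost),
        "cumulative_differences": {
            f"{comp} - {ref}": {"absolute": money, "percent": pct}
            for (ref, comp), (money, pct) in result.cumulative_differences.items()
        },
    }


def dsa_frame(table: TornadoTable, rounded: bool = True) -> pd.DataFrame:
    frame = table.to_frame()
    if rounded:
        for col in frame.columns:
            if col != "scenario":
                frame[col] = frame[col].map(
                    lambda v: round_usd(v) if pd.notna(v) else None)
    return frame


def plot_tornado(table: TornadoTable, path: str | Path) -> Path:
    """Horizontal-bar tornado of reference-device totals by scenario swing.

    Requires matplotlib (optional dependency)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    base_total = table.base.totals[table.reference_label]
    names = [row.scenario_name for row in table.rows][::-1]
    deltas = [row.totals[table.reference_label] - base_total for row in table.rows][::-1]
    fig, ax = plt.subplots(figsize=(7, 0.5 * max(len(names), 2) + 1.5))
    ax.barh(names, deltas, left=base_total, color="#4878d0")
    ax.axvline(base_total, color="black", lw=1)
    ax.set_xlabel(f"Per-patient total, {table.reference_label} (2023 USD)")
    ax.set_title(f"Univariate sensitivity of {table.reference_label} total "
                 f"(base {round_usd(base_total):,} USD)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------

def file_digest(path: str | Path) -> str:
    return "sha256:" + hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass(frozen=True)
class RunManifest:
    """Provenance record for one CLI run."""

    timestamp: str
    version: str
    subcommand: str
    argv: tuple[str, ...]
    input_digests: dict[str, str] = field(default_factory=dict)
    outputs: tuple[str, ...] = ()

    @classmethod
    def create(cls, subcommand: str, argv: Sequence[str],
               inputs: Sequence[str | Path] = (),
               outputs: Sequence[str | Path] = ()) -> "RunManifest":
        from . import __version__

        return cls(
            timestamp=datetime.now(timezone.utc).isoformat(),
            version=__version__,
            subcommand=subcommand,
            argv=tuple(str(a) for a in argv),
            input_digests={str(p): file_digest(p) for p in inputs},
            outputs=tuple(str(p) for p in outputs),
        )


def append_manifest(log_path: str | Path, manifest: RunManifest) -> None:
    log_path = Path(log_path)
    log_path.parent.mkdir(parents=True, exist_ok=True)
    with log_path.open("a") as fh:
        fh.write(json.dumps(dataclasses.asdict(manifest)) + "\n")
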