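"""Population roll-up: cumulative replacement costs across annual entry cohorts.

Annual cohorts of ``population_annual_implants`` patients receive initial
implants in each of ``population_cohort_years`` consecutive entry years.
A cohort entering at year ``e`` is followed only to the end of the window,
i.e. for ``(C - 1) - e`` years, so the earliest cohort gets the full
horizon and the latest gets none. Cumulative population cost accumulates
the replacement-category costs by default (matching the published
cumulative-replacement row); ``include_all_categories=True`` accumulates
full per-patient totals instead. Each cohort's costs are discounted
internally to its own entry year and summed nominally across cohorts
(no cross-cohort discounting).
"""

from __future__ import annotations

from dataclasses import dataclass

from .engine import CostBreakdown, per_patient_costs
from .parameters import ModelParameters

__all__ = [
    "PopulationResult",
    "cohort_truncated_cost",
    "cumulative_population_cost",
    "cumulative_difference",
    "population_summary",
]


@dataclass(frozen=True)
class PopulationResult:
    """Cumulative population-level costs for every device and device pair."""

    annual_implants: int
    cohort_entry_years: int
    total_patients: int
    cumulative_replacement_cost: dict[str, float]
    cumulative_differences: dict[tuple[str, str], tuple[float, float | None]]


def cohort_truncated_cost(params: ModelParameters, device_label: str,
                          horizon: int) -> CostBreakdown:
    """Per-patient costs for a cohort followed only ``horizon`` years.

    Identical to the full per-patient computation with every sum truncated
    at ``horizon``; horizon 0 leaves only initial-implant costs.
    """
    if not 0 <= horizon <= params.settings.horizon_years:
        raise ValueError(
            f"horizon must be in [0, {params.settings.horizon_years}], got {horizon}")
    return per_patient_costs(params, device_label, horizon=horizon)


def cumulative_population_cost(params: ModelParameters, device_label: str,
                               include_all_categories: bool = False) -> float:
    """Cumulative cost across all entry cohorts for one device (2023 USD).

    ``annual_implants x sum over entry years e of the truncated per-patient
    replacement total at horizon (C - 1) - e`` (or the full total when
    ``include_all_categories``).
    """
    C = params.population_cohort_years
    total = 0.0
    for entry_year in range(C):
        bd = cohort_truncated_cost(params, device_label, horizon=(C - 1) - entry_year)
        total += bd.total if include_all_categories else bd.replacement_total
    return params.population_annual_implants * total


def cumulative_difference(params: ModelParameters, reference_label: str,
                          comparator_label: str,
                          include_all_categories: bool = False) -> tuple[float, float | None]:
    """Comparator-minus-reference cumulative cost, absolute and percent.

    Percent is relative to the reference; ``None`` if the reference
    cumulative cost is zero.
    """
    ref = cumulative_population_cost(params, reference_label, include_all_categories)
    comp = cumulative_population_cost(params, comparator_label, include_all_categories)
    diff = comp - ref
    return diff, (100.0 * diff / ref) if ref != 0 else None


def population_summary(params: ModelParameters, reference_label: str | None = None,
                       include_all_categories: bool = False) -> PopulationResult:
    """Roll-up for every device plus pairwise differences vs the reference
    (first device by default)."""
    labels = params.device_labels
    reference = reference_label if reference_label is not None else labels[0]
    params.device(reference)  # raise on unknown label
    cumulative = {
        label: cumulative_population_cost(params, label, include_all_categories)
        for label in labels
    }
    differences = {
        (reference, label): cumulative_difference(params, reference, label,
                                                  include_all_categories)
        for label in labels if label != reference
    }
    return PopulationResult(
        annual_implants=params.population_annual_implants,
        cohort_entry_years=params.population_cohort_years,
        total_patients=params.population_annual_implants * params.population_cohort_years,
        cumulative_replacement_cost=cumulative,
        cumulative_differences=differences,
    )
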