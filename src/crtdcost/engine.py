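"""Cohort decision-tree engine: replacement renewal process and discounted costs.

A patient receives a device at year 0 and is followed to the model horizon
``H``. The original battery's end of service is governed by the device's
event-free battery-survival curve ``S_b(a)`` by device age ``a``; a
replacement restarts an identical battery at age 0 (replacements occur only
for battery depletion, never device malfunction). Patient survival
``S_p(t)`` is device-independent, and a replacement at calendar year ``t``
requires the patient to be alive at ``t``. At most ``max_replacements``
replacements are performed per patient.

Writing ``f(a) = S_b(a-1) - S_b(a)`` for the first-depletion mass, the mass
of the k-th replacement at calendar year ``t`` is the k-fold discrete
renewal convolution

    g_1(t) = f(t),      g_k(t) = sum_{tau < t} g_{k-1}(tau) * f(t - tau),

truncated at ``t <= H`` and ``k <= max_replacements``. Expected alive-
weighted replacements are ``R(t) = S_p(t) * sum_k g_k(t)``. All year-``t``
costs are discounted by ``(1 + r)^-t`` (end-of-year convention, no
half-cycle correction); year-0 costs are undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .parameters import AnnualCurve, ComplicationModel, ModelParameters, ValidationError

__all__ = [
    "CostBreakdown",
    "ReplacementDistribution",
    "DeviceComparison",
    "COST_CATEGORIES",
    "discount_factor",
    "battery_event_density",
    "renewal_distribution",
    "expected_replacement_events",
    "replacement_distribution",
    "expected_complication_cost",
    "per_patient_costs",
    "compare_devices",
]

#: Reporting order of cost categories; the three totals are derived.
COST_CATEGORIES: tuple[str, ...] = (
    "initial_procedure",
    "initial_complications",
    "initial_followups",
    "initial_total",
    "replacement_procedures",
    "replacement_complications",
    "replacement_followups",
    "replacement_total",
    "routine_followups",
    "total",
)


@dataclass(frozen=True)
class CostBreakdown:
    """Discounted per-patient costs (2023 USD) by category.

    Holds the six leaf categories; the three totals are derived properties
    so additivity holds by construction.
    """

    initial_procedure: float
    initial_complications: float
    initial_followups: float
    replacement_procedures: float
    replacement_complications: float
    replacement_followups: float
    routine_followups: float

    @property
    def initial_total(self) -> float:
        return self.initial_procedure + self.initial_complications + self.initial_followups

    @property
    def replacement_total(self) -> float:
        return (self.replacement_procedures + self.replacement_complications
                + self.replacement_followups)

    @property
    def total(self) -> float:
        return self.initial_total + self.replacement_total + self.routine_followups

    def as_dict(self) -> dict[str, float]:
        """All categories including derived totals, in reporting order."""
        return {name: getattr(self, name) for name in COST_CATEGORIES}


@dataclass(frozen=True)
class ReplacementDistribution:
    """Replacement probability mass by ordinal and calendar year.

    ``mass[k-1, t]`` is the probability the k-th replacement falls at year
    ``t`` (ignoring patient death); ``alive_weighted_mass`` multiplies each
    entry by patient survival ``S_p(t)``.
    """

    mass: np.ndarray
    alive_weighted_mass: np.ndarray

    @property
    def expected_events_by_year(self) -> np.ndarray:
        """Alive-weighted expected replacements R(t) summed over ordinals."""
        return self.alive_weighted_mass.sum(axis=0)


@dataclass(frozen=True)
class DeviceComparison:
    """Category-wise cost differences between two devices.

    ``absolute[cat]`` is comparator minus reference (USD); ``percent[cat]``
    is the same difference as a percentage of the reference, ``None``
    where the reference category is zero.
    """

    reference_label: str
    comparator_label: str
    absolute: dict[str, float]
    percent: dict[str, float | None]


def discount_factor(rate: float, year: int) -> float:
    """Present-value factor ``(1 + rate)^-year`` for an end-of-year cost."""
    if year < 0:
        raise ValueError(f"year must be non-negative, got {year}")
    if rate < 0:
        raise ValueError(f"rate must be non-negative, got {rate}")
    return (1.0 + rate) ** (-year)


def battery_event_density(curve: AnnualCurve, horizon: int) -> np.ndarray:
    """First-depletion mass ``f(a) = S_b(a-1) - S_b(a)`` for ages 0..horizon.

    ``f(0) = 0`` (a battery cannot end service in its implant year) and
    ``sum_a f(a) = 1 - S_b(horizon)``, the mass still un-depleted at the
    horizon being censored.
    """
    if curve.horizon < horizon:
        raise ValidationError(
            f"battery curve covers {curve.horizon} years, need {horizon}")
    s = np.asarray(curve.values[: horizon + 1], dtype=float)
    f = np.zeros(horizon + 1)
    f[1:] = s[:-1] - s[1:]
    if np.any(f < 0):  # unreachable for a validated AnnualCurve
        raise ValidationError("battery curve is not non-increasing (negative event mass)")
    return f


def renewal_distribution(f: np.ndarray, horizon: int, max_replacements: int) -> np.ndarray:
    """Renewal masses ``g_k(t)``, shape ``(max_replacements, horizon + 1)``.

    Row ``k-1`` holds the distribution of the k-th replacement year; each
    replaced battery restarts the same depletion density at age 0. Rows
    sum to at most 1 (the remainder is censored beyond the horizon).
    """
    f = np.asarray(f, dtype=float)[: horizon + 1]
    g = np.zeros((max_replacements, horizon + 1))
    g[0, : f.size] = f
    for k in range(1, max_replacements):
        # g_k(t) = sum_{tau < t} g_{k-1}(tau) f(t - tau); f(0) = 0 makes the
        # full convolution equivalent, truncated to the horizon.
        g[k] = np.convolve(g[k - 1], f)[: horizon + 1]
    return g


def expected_replacement_events(g: np.ndarray, patient_survival: AnnualCurve) -> np.ndarray:
    """Alive-weighted expected replacement mass ``R(t) = S_p(t) * sum_k g_k(t)``.

    Replacements are credited only to patients alive at year ``t``; death
    and battery depletion are independent.
    """
    g = np.atleast_2d(np.asarray(g, dtype=float))
    horizon = g.shape[1] - 1
    if patient_survival.horizon < horizon:
        raise ValidationError(
            f"patient curve covers {patient_survival.horizon} years, need {horizon}")
    s_p = np.asarray(patient_survival.values[: horizon + 1], dtype=float)
    return s_p * g.sum(axis=0)


def replacement_distribution(params: ModelParameters, device_label: str,
                             horizon: int | None = None) -> ReplacementDistribution:
    """Full replacement distribution for one device under ``params``."""
    H = params.settings.horizon_years if horizon is None else horizon
    dev = params.device(device_label)
    f = battery_event_density(dev.battery_survival, H)
    g = renewal_distribution(f, H, params.settings.max_replacements)
    s_p = np.asarray(params.patient_survival.values[: H + 1], dtype=float)
    return ReplacementDistribution(mass=g, alive_weighted_mass=s_p[None, :] * g)


def expected_complication_cost(context: Literal["primary", "replacement"],
                               cm: ComplicationModel) -> float:
    """Expected complication + infection cost per procedure (undiscounted).

    For the base case, ``primary`` gives 0.04 x $1,112 + 0.02 x $29,550 =
    $635.48 per initial implant.
    """
    if context == "primary":
        return (cm.p_complication_primary * cm.cost_complication
                + cm.p_infection_primary * cm.cost_infection)
    if context == "replacement":
        return (cm.p_complication_replacement * cm.cost_complication
                + cm.p_infection_replacement * cm.cost_infection)
    raise ValueError(f"context must be 'primary' or 'replacement', got {context!r}")


def per_patient_costs(params: ModelParameters, device_label: str,
                      horizon: int | None = None) -> CostBreakdown:
    """Discounted expected per-patient costs for one device.

    ``horizon`` truncates follow-up short of ``settings.horizon_years``
    (used by the population roll-up for late entry cohorts); horizon 0
    leaves only the year-0 initial-implant costs.
    """
    settings = params.settings
    if horizon is None:
        horizon = settings.horizon_years
    if not 0 <= horizon <= settings.horizon_years:
        raise ValueError(
            f"horizon must be in [0, {settings.horizon_years}], got {horizon}")

    costs, cm = params.costs, params.complications
    r = settings.discount_rate
    lag = settings.complication_lag_years
    t = np.arange(horizon + 1)
    disc = (1.0 + r) ** (-t.astype(float))
    disc_lag = (1.0 + r) ** (-(t + lag).astype(float))

    R = replacement_distribution(params, device_label, horizon).expected_events_by_year

    ec_primary = expected_complication_cost("primary", cm)
    ec_replacement = expected_complication_cost("replacement", cm)
    postproc_cost = costs.postprocedure_visits * costs.cost_followup_visit

    s_p = np.asarray(params.patient_survival.values[: horizon + 1], dtype=float)
    routine = float(np.sum(
        costs.routine_visits_per_year * costs.cost_followup_visit * s_p[1:] * disc[1:]))

    return CostBreakdown(
        initial_procedure=costs.cost_initial_implant,
        initial_complications=ec_primary * float(disc_lag[0]),
        initial_followups=postproc_cost,
        replacement_procedures=float(np.sum(R * costs.cost_replacement * disc)),
        replacement_complications=float(np.sum(R * ec_replacement * disc_lag)),
        replacement_followups=float(np.sum(R * postproc_cost * disc)),
        routine_followups=routine,
    )


def compare_devices(params: ModelParameters, reference: str,
                    comparator: str) -> DeviceComparison:
    """Category-wise absolute and percent cost differences between devices.

    Percent differences are ``100 * (comparator - reference) / reference``;
    a category with zero reference cost is reported as ``None`` (not
    applicable), never as an error.
    """
    ref = per_patient_costs(params, reference).as_dict()
    comp = per_patient_costs(params, comparator).as_dict()
    absolute = {cat: comp[cat] - ref[cat] for cat in COST_CATEGORIES}
    percent: dict[str, float | None] = {
        cat: (100.0 * absolute[cat] / ref[cat]) if ref[cat] != 0 else None
        for cat in COST_CATEGORIES
    }
    return DeviceComparison(reference_label=reference, comparator_label=comparator,
                            absolute=absolute, percent=percent)
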