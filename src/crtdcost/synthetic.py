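"""Synthetic inputs and a patient-level Monte-Carlo validation oracle.

``generate_parameters`` draws random but structurally valid input bundles
with the same shape as the built-in base case: a non-increasing patient
survival curve built from independent annual death probabilities, and
per-device battery curves that are 100% through the two-year grace period
and then fall along a discretised Weibull tail whose scale grows with
battery capacity (higher Ah is pointwise safer by construction).

``microsimulate`` re-states the cohort model at the individual patient
level: annual death and depletion hazards derived from the same curves,
Bernoulli complication draws, per-event discounting. Its sample means are
unbiased estimators of the cohort engine's expected cost categories, which
is what makes it an independent oracle: agreement within Monte-Carlo error
validates the renewal/discounting algebra.

RNG discipline: all draws come from numpy's PCG64 seeded with the supplied
seed; the microsimulation fills one fixed-shape ``(n, H + 1, 4)`` uniform
tensor in C order, so patient ``i`` always consumes the same draws
regardless of ``n`` (growing the simulation appends patients without
reshuffling earlier ones).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import CostBreakdown
from .parameters import (AnnualCurve, ComplicationModel, CostSchedule,
                         DeviceProfile, ModelParameters, ModelSettings)

__all__ = [
    "GeneratorConfig",
    "MicrosimResult",
    "generate_parameters",
    "microsimulate",
]

#: Years after implant/replacement during which a battery cannot deplete.
GRACE_YEARS = 2


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the random-parameter generator.

    Default ranges bracket the base-case magnitudes: ~4-9% annual
    mortality, Weibull battery tails calibrated so a ~2-Ah device retains
    most of its survival at 6 years while a ~1-Ah device is mostly
    depleted, costs and incidences within the same order as the Medicare
    reimbursement and complication inputs.
    """

    seed: int = 0
    n_devices: int = 3
    capacity_range_ah: tuple[float, float] = (1.0, 2.2)
    horizon: int = 6
    depletion_shape: float = 2.0
    scale_per_ah_range: tuple[float, float] = (3.0, 5.0)
    mortality_range: tuple[float, float] = (0.04, 0.09)
    cost_initial_range: tuple[float, float] = (25_000.0, 45_000.0)
    cost_replacement_range: tuple[float, float] = (20_000.0, 40_000.0)
    cost_visit_range: tuple[float, float] = (50.0, 150.0)
    cost_complication_range: tuple[float, float] = (500.0, 5_000.0)
    cost_infection_range: tuple[float, float] = (15_000.0, 40_000.0)
    incidence_range: tuple[float, float] = (0.01, 0.06)
    discount_rate: float = 0.03
    max_replacements: int = 3

    def __post_init__(self) -> None:
        for name in ("mortality_range", "incidence_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name} must lie within [0, 1], got {(lo, hi)}")
        for name in ("capacity_range_ah", "scale_per_ah_range", "cost_initial_range",
                     "cost_replacement_range", "cost_visit_range",
                     "cost_complication_range", "cost_infection_range"):
            lo, hi = getattr(self, name)
            if not (0.0 < lo <= hi):
                raise ValueError(f"{name} must be a positive interval, got {(lo, hi)}")
        if self.n_devices < 1 or self.horizon < 1:
            raise ValueError("n_devices and horizon must be >= 1")


@dataclass(frozen=True)
class MicrosimResult:
    """Monte-Carlo summary: per-category means, standard errors, and the
    replacement-count histogram (index = number of replacements)."""

    n_patients: int
    mean: CostBreakdown
    se: dict[str, float]
    replacement_histogram: tuple[int, ...] = field(default=())


def _battery_curve(capacity_ah: float, scale_per_ah: float, shape: float,
                   horizon: int) -> AnnualCurve:
    # Discretised Weibull tail after the grace period: S(a) = 1 for a <= 1,
    # else exp(-((a - 1) / (scale_per_ah * Ah))**shape). Pointwise
    # monotone-increasing in Ah for a shared scale_per_ah draw.
    scale = scale_per_ah * capacity_ah
    values = [
        1.0 if a < GRACE_YEARS else float(np.exp(-(((a - 1) / scale) ** shape)))
        for a in range(horizon + 1)
    ]
    return AnnualCurve(values)


def generate_parameters(config: GeneratorConfig) -> ModelParameters:
    """Draw a random, fully valid :class:`ModelParameters` bundle.

    Deterministic for a fixed config (including its seed). The Weibull
    scale multiplier is drawn once per bundle and shared across devices so
    higher-capacity batteries are pointwise at least as durable.
    """
    rng = np.random.default_rng(config.seed)
    H = config.horizon

    q = rng.uniform(*config.mortality_range, size=H)
    survival = np.concatenate([[1.0], np.cumprod(1.0 - q)])
    patient = AnnualCurve(survival.tolist())

    capacities = np.sort(rng.uniform(*config.capacity_range_ah, size=config.n_devices))
    scale_per_ah = rng.uniform(*config.scale_per_ah_range)
    devices = tuple(
        DeviceProfile(
            label=f"device-{i + 1} ({cap:.2f} Ah)",
            capacity_ah=float(cap),
            battery_survival=_battery_curve(float(cap), scale_per_ah,
                                            config.depletion_shape, H),
        )
        for i, cap in enumerate(capacities)
    )

    complications = ComplicationModel(
        p_complication_primary=float(rng.uniform(*config.incidence_range)),
        p_complication_replacement=float(rng.uniform(*config.incidence_range)),
        p_infection_primary=float(rng.uniform(*config.incidence_range)),
        p_infection_replacement=float(rng.uniform(*config.incidence_range)),
        cost_complication=float(np.round(rng.uniform(*config.cost_complication_range))),
        cost_infection=float(np.round(rng.uniform(*config.cost_infection_range))),
    )
    costs = CostSchedule(
        cost_initial_implant=float(np.round(rng.uniform(*config.cost_initial_range))),
        cost_replacement=float(np.round(rng.uniform(*config.cost_replacement_range))),
        cost_followup_visit=float(np.round(rng.uniform(*config.cost_visit_range))),
        routine_visits_per_year=4,
        postprocedure_visits=1,
    )
    settings = ModelSettings(horizon_years=H, discount_rate=config.discount_rate,
                             max_replacements=config.max_replacements)
    return ModelParameters(patient_survival=patient, devices=devices,
                           complications=complications, costs=costs, settings=settings)


def _conditional_hazard(curve: np.ndarray) -> np.ndarray:
    """Annual hazard h(t) = 1 - S(t)/S(t-1); 1 where the curve already hit 0."""
    prev = curve[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(prev > 0, 1.0 - curve[1:] / np.where(prev > 0, prev, 1.0), 1.0)
    return np.concatenate([[0.0], h])  # index by year/age, h(0) = 0


def microsimulate(params: ModelParameters, device_label: str, n_patients: int,
                  seed: int) -> MicrosimResult:
    """Patient-level Monte-Carlo estimate of the per-patient cost breakdown.

    Each patient is simulated year by year: death first (hazard from the
    patient curve); survivors accrue routine visits, then face battery
    depletion at the current device age (hazard from the battery curve).
    A depletion triggers a replacement — procedure cost, independent
    Bernoulli complication and infection draws, and the post-procedure
    visit, all discounted to that year — and resets device age, up to
    ``max_replacements``; further depletions are uncosted. Year-0 implant
    costs include Bernoulli primary-complication draws.
    """
    if n_patients < 1:
        raise ValueError(f"n_patients must be >= 1, got {n_patients}")
    settings, costs, cm = params.settings, params.costs, params.complications
    H = settings.horizon_years
    r, lag = settings.discount_rate, settings.complication_lag_years
    disc = (1.0 + r) ** (-np.arange(H + lag + 1, dtype=float))

    s_p = np.asarray(params.patient_survival.values[: H + 1], dtype=float)
    s_b = np.asarray(params.device(device_label).battery_survival.values[: H + 1],
                     dtype=float)
    death_hazard = _conditional_hazard(s_p)
    depletion_hazard = _conditional_hazard(s_b)

    # u[:, t, 0] death, u[:, t, 1] depletion, u[:, t, 2]/[:, t, 3]
    # complication/infection draws for the procedure (if any) at year t.
    u = np.random.default_rng(seed).random((n_patients, H + 1, 4))

    n = n_patients
    postproc_cost = costs.postprocedure_visits * costs.cost_followup_visit
    routine_cost = costs.routine_visits_per_year * costs.cost_followup_visit

    initial_procedure = np.full(n, float(costs.cost_initial_implant))
    initial_complications = (
        (u[:, 0, 2] < cm.p_complication_primary) * cm.cost_complication
        + (u[:, 0, 3] < cm.p_infection_primary) * cm.cost_infection
    ) * disc[lag]
    initial_followups = np.full(n, float(postproc_cost))
    repl_proc = np.zeros(n)
    repl_comp = np.zeros(n)
    repl_fu = np.zeros(n)
    routine = np.zeros(n)

    alive = np.ones(n, dtype=bool)
    age = np.zeros(n, dtype=np.int64)
    n_repl = np.zeros(n, dtype=np.int64)
    exhausted = np.zeros(n, dtype=bool)  # depleted past the replacement cap

    for t in range(1, H + 1):
        alive &= ~(u[:, t, 0] < death_hazard[t])
        age += 1
        # Ages only exceed the curve for devices already depleted past the
        # replacement cap; clamp so the (unused) hazard lookup stays in range.
        np.minimum(age, H, out=age)
        routine[alive] += routine_cost * disc[t]
        depletes = alive & ~exhausted & (u[:, t, 1] < depletion_hazard[age])
        replaced = depletes & (n_repl < settings.max_replacements)
        exhausted |= depletes & ~replaced
        if replaced.any():
            n_repl[replaced] += 1
            age[replaced] = 0
            repl_proc[replaced] += costs.cost_replacement * disc[t]
            repl_fu[replaced] += postproc_cost * disc[t]
            repl_comp[replaced] += (
                (u[replaced, t, 2] < cm.p_complication_replacement) * cm.cost_complication
                + (u[replaced, t, 3] < cm.p_infection_replacement) * cm.cost_infection
            ) * disc[t + lag]

    leaves = {
        "initial_procedure": initial_procedure,
        "initial_complications": initial_complications,
        "initial_followups": initial_followups,
        "replacement_procedures": repl_proc,
        "replacement_complications": repl_comp,
        "replacement_followups": repl_fu,
        "routine_followups": routine,
    }
    derived = {
        "initial_total": initial_procedure + initial_complications + initial_followups,
        "replacement_total": repl_proc + repl_comp + repl_fu,
    }
    derived["total"] = derived["initial_total"] + derived["replacement_total"] + routine

    mean = CostBreakdown(**{name: float(arr.mean()) for name, arr in leaves.items()})
    se = {
        name: float(arr.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        for name, arr in {**leaves, **derived}.items()
    }
    hist = np.bincount(n_repl, minlength=settings.max_replacements + 1)
    return MicrosimResult(n_patients=n, mean=mean, se=se,
                          replacement_histogram=tuple(int(c) for c in hist))
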