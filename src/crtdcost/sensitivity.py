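"""Univariate deterministic sensitivity analysis (DSA) and tornado tables.

Each scenario applies exactly one declarative edit to the base parameters
(replace a survival curve, scale a procedure cost, swap the complication
model, or extend the horizon), re-runs the cohort engine for every device,
and records totals and savings versus comparator devices. Horizon
extension beyond the observed curves uses a geometric conditional-survival
tail by default: each added year multiplies the last value by the final
observed annual ratio ``values[H] / values[H-1]``; explicit user tails are
also accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from pathlib import Path
from typing import Any, Mapping, Sequence, Union

import yaml

from .engine import per_patient_costs
from .parameters import (AnnualCurve, ComplicationModel, DeviceProfile,
                         ModelParameters, ValidationError)

__all__ = [
    "ReplaceCurve",
    "ScaleCost",
    "SetComplications",
    "SetHorizon",
    "ScenarioSpec",
    "TornadoRow",
    "TornadoTable",
    "apply_scenario",
    "extend_horizon",
    "run_dsa",
    "procedure_cost_scenarios",
    "scenarios_from_config",
]


@dataclass(frozen=True)
class ReplaceCurve:
    """Replace the patient curve (``target='patient'``) or a device's
    battery curve (``target=<device label>``)."""

    target: str
    curve: AnnualCurve


@dataclass(frozen=True)
class ScaleCost:
    """Scale the initial-implant or replacement procedure cost by a
    positive factor (e.g. 0.8 / 1.2 for the +/-20% scenarios)."""

    target: str  # "initial" | "replacement"
    factor: float

    def __post_init__(self) -> None:
        if self.target not in ("initial", "replacement"):
            raise ValidationError(
                f"scale_cost.target: must be 'initial' or 'replacement', got {self.target!r}")
        if not self.factor > 0:
            raise ValidationError(f"scale_cost.factor: must be > 0, got {self.factor!r}")


@dataclass(frozen=True)
class SetComplications:
    """Install an alternative complication model (e.g. upper-bound
    incidences and costs supplied from user config)."""

    model: ComplicationModel


@dataclass(frozen=True)
class SetHorizon:
    """Extend the follow-up horizon, extrapolating curves by ``rule``
    ('geometric') or explicit per-curve tails."""

    years: int
    rule: str = "geometric"
    tails: Mapping[str, Sequence[float]] | None = None  # target -> tail values


Transform = Union[ReplaceCurve, ScaleCost, SetComplications, SetHorizon]


@dataclass(frozen=True)
class ScenarioSpec:
    """One named univariate scenario: exactly one transform."""

    name: str
    transform: Transform


@dataclass(frozen=True)
class TornadoRow:
    """Per-scenario totals and savings.

    ``totals[label]`` is the per-patient total under the scenario;
    ``savings[comp]`` is ``(money, percent)`` with money = comparator minus
    reference total (positive when the reference device is cheaper) and
    percent relative to the reference total.
    """

    scenario_name: str
    totals: dict[str, float]
    savings: dict[str, tuple[float, float | None]]


@dataclass(frozen=True)
class TornadoTable:
    """Base-case row plus scenario rows, ordered for a tornado diagram:
    descending swing ``|total - base total|`` of the reference device,
    ties broken by scenario name."""

    reference_label: str
    comparator_labels: tuple[str, ...]
    base: TornadoRow
    rows: tuple[TornadoRow, ...]

    @property
    def reference_total_range(self) -> tuple[float, float]:
        """(min, max) reference-device total across base + all scenarios."""
        totals = [self.base.totals[self.reference_label]] + [
            row.totals[self.reference_label] for row in self.rows]
        return min(totals), max(totals)

    def to_frame(self):
        import pandas as pd

        records = []
        for row in (self.base, *self.rows):
            rec: dict[str, Any] = {"scenario": row.scenario_name}
            for label, tot in row.totals.items():
                rec[f"total[{label}]"] = tot
            for comp, (money, pct) in row.savings.items():
                rec[f"savings_vs[{comp}]"] = money
                rec[f"savings_vs[{comp}]_pct"] = pct
            records.append(rec)
        return pd.DataFrame.from_records(records)


def _replace_device_curve(params: ModelParameters, label: str,
                          curve: AnnualCurve) -> ModelParameters:
    devices = tuple(
        DeviceProfile(d.label, d.capacity_ah, curve) if d.label == label else d
        for d in params.devices)
    return dc_replace(params, devices=devices)


def apply_scenario(params: ModelParameters, spec: ScenarioSpec) -> ModelParameters:
    """Return new parameters with the scenario's single edit applied.

    The original is never mutated; the edited bundle is re-validated, so
    an edit that breaks an invariant (survival above 1, negative cost)
    raises :class:`ValidationError`.
    """
    tr = spec.transform
    if isinstance(tr, ReplaceCurve):
        if tr.target == "patient":
            return dc_replace(params, patient_survival=tr.curve)
        if tr.target in params.device_labels:
            return _replace_device_curve(params, tr.target, tr.curve)
        raise ValidationError(
            f"scenario {spec.name!r}: replace_curve target {tr.target!r} not found "
            f"(expected 'patient' or one of {list(params.device_labels)})")
    if isinstance(tr, ScaleCost):
        costs = params.costs
        if tr.target == "initial":
            costs = dc_replace(costs, cost_initial_implant=costs.cost_initial_implant * tr.factor)
        else:
            costs = dc_replace(costs, cost_replacement=costs.cost_replacement * tr.factor)
        return dc_replace(params, costs=costs)
    if isinstance(tr, SetComplications):
        return dc_replace(params, complications=tr.model)
    if isinstance(tr, SetHorizon):
        return extend_horizon(params, tr.years, rule=tr.rule, tails=tr.tails)
    raise ValidationError(f"scenario {spec.name!r}: unknown transform {type(tr).__name__}")


def _extend_curve(curve: AnnualCurve, target_years: int,
                  tail: Sequence[float] | None = None) -> AnnualCurve:
    values = list(curve.values)
    H = len(values) - 1
    if tail is not None:
        needed = target_years - H
        if len(tail) < needed:
            raise ValidationError(
                f"explicit tail has {len(tail)} values, need {needed}")
        values.extend(float(v) for v in tail[:needed])
        return AnnualCurve(values)
    # Geometric rule: repeat the last observed annual conditional survival
    # ratio; a curve that has hit zero (or has no year-over-year history)
    # stays at zero.
    if H >= 1 and values[H - 1] > 0:
        ratio = values[H] / values[H - 1]
    else:
        ratio = 0.0
    while len(values) - 1 < target_years:
        values.append(max(values[-1] * ratio, 0.0))
    return AnnualCurve(values)


def extend_horizon(params: ModelParameters, target_years: int, rule: str = "geometric",
                   tails: Mapping[str, Sequence[float]] | None = None) -> ModelParameters:
    """Extend the model horizon, extrapolating every curve to ``target_years``.

    Default rule ``'geometric'``: each added year multiplies the previous
    value by the last observed annual conditional survival ratio. Explicit
    ``tails`` (keyed ``'patient'`` or device label) override the rule per
    curve. The returned settings carry the new horizon.
    """
    H = params.settings.horizon_years
    if target_years <= H:
        raise ValueError(f"target_years must exceed current horizon {H}, got {target_years}")
    if rule != "geometric":
        raise ValidationError(f"unknown horizon-extension rule {rule!r}")
    tails = tails or {}
    patient = _extend_curve(params.patient_survival, target_years, tails.get("patient"))
    devices = tuple(
        DeviceProfile(d.label, d.capacity_ah,
                      _extend_curve(d.battery_survival, target_years, tails.get(d.label)))
        for d in params.devices)
    settings = dc_replace(params.settings, horizon_years=target_years)
    return dc_replace(params, patient_survival=patient, devices=devices,
                      settings=settings)


def run_dsa(params: ModelParameters, scenarios: Sequence[ScenarioSpec],
            reference_label: str, comparator_labels: Sequence[str]) -> TornadoTable:
    """Run every scenario and assemble the tornado table.

    Any scenario failure aborts with an error naming the scenario.
    """
    params.device(reference_label)
    for comp in comparator_labels:
        params.device(comp)

    def _row(name: str, p: ModelParameters) -> TornadoRow:
        totals = {label: per_patient_costs(p, label).total for label in p.device_labels}
        ref_total = totals[reference_label]
        savings: dict[str, tuple[float, float | None]] = {}
        for comp in comparator_labels:
            money = totals[comp] - ref_total
            savings[comp] = (money, 100.0 * money / ref_total if ref_total != 0 else None)
        return TornadoRow(scenario_name=name, totals=totals, savings=savings)

    base = _row("base case", params)
    rows = []
    for spec in scenarios:
        try:
            rows.append(_row(spec.name, apply_scenario(params, spec)))
        except Exception as exc:
            raise RuntimeError(f"scenario {spec.name!r} failed: {exc}") from exc

    base_total = base.totals[reference_label]
    rows.sort(key=lambda row: (-abs(row.totals[reference_label] - base_total),
                               row.scenario_name))
    return TornadoTable(reference_label=reference_label,
                        comparator_labels=tuple(comparator_labels),
                        base=base, rows=tuple(rows))


def procedure_cost_scenarios(factors: Sequence[float] = (0.8, 1.2)) -> list[ScenarioSpec]:
    """The +/-20%-style procedure-cost scenario families: one scenario per
    (cost target, factor) pair."""
    specs = []
    for target in ("initial", "replacement"):
        for factor in factors:
            specs.append(ScenarioSpec(
                name=f"{target} cost x{factor:g}",
                transform=ScaleCost(target=target, factor=factor)))
    return specs


def _transform_from_config(node: Mapping[str, Any], name: str) -> Transform:
    kind = node.get("type")
    if kind == "scale_cost":
        return ScaleCost(target=str(node["target"]), factor=float(node["factor"]))
    if kind == "replace_curve":
        curve_node = node["curve"]
        div = 100.0 if curve_node.get("percent", False) else 1.0
        curve = AnnualCurve([float(v) / div for v in curve_node["values"]],
                            path=f"scenario[{name!r}].curve")
        return ReplaceCurve(target=str(node["target"]), curve=curve)
    if kind == "set_complications":
        div = 100.0 if node.get("percent", False) else 1.0
        return SetComplications(ComplicationModel(
            p_complication_primary=float(node["complication_primary"]) / div,
            p_complication_replacement=float(node["complication_replacement"]) / div,
            p_infection_primary=float(node["infection_primary"]) / div,
            p_infection_replacement=float(node["infection_replacement"]) / div,
            cost_complication=float(node["cost_complication"]),
            cost_infection=float(node["cost_infection"]),
        ))
    if kind == "set_horizon":
        return SetHorizon(years=int(node["years"]), rule=str(node.get("rule", "geometric")),
                          tails=node.get("tails"))
    raise ValidationError(f"scenario[{name!r}].type: unknown transform {kind!r}")


def scenarios_from_config(source: str | Path | Sequence[Mapping[str, Any]]) -> list[ScenarioSpec]:
    """Load a scenario list from a YAML/JSON file or parsed sequence.

    Each entry is ``{name: ..., transform: {type: scale_cost | replace_curve
    | set_complications | set_horizon, ...}}``.
    """
    if isinstance(source, (str, Path)):
        doc = yaml.safe_load(Path(source).read_text())
    else:
        doc = source
    if isinstance(doc, Mapping) and "scenarios" in doc:
        doc = doc["scenarios"]
    if not isinstance(doc, Sequence):
        raise ValidationError("scenarios: expected a list of scenario entries")
    specs = []
    for i, node in enumerate(doc):
        if not isinstance(node, Mapping) or "name" not in node or "transform" not in node:
            raise ValidationError(f"scenarios[{i}]: entry needs 'name' and 'transform'")
        name = str(node["name"])
        specs.append(ScenarioSpec(name=name,
                                  transform=_transform_from_config(node["transform"], name)))
    return specs
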