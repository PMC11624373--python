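"""Model inputs: domain types, validation, and (de)serialisation.

The model is driven entirely by a small bundle of inputs: an annual
patient-survival curve, one event-free battery-survival curve per device
profile, complication incidences and unit costs, procedure and visit
reimbursements, and run settings (horizon, discount rate, replacement cap).
All of these are bundled in :class:`ModelParameters`, which can be loaded
from a YAML/JSON document or a directory of CSV tables, and round-trips
losslessly through :func:`save_parameters` / :func:`load_parameters`.

Probabilities are stored internally as fractions in ``[0, 1]``; config
documents may declare ``percent: true`` on a table to supply them as
printed percentages instead. Monetary amounts are whole 2023 USD on input;
arithmetic is done in floating point and rounding happens only at the
reporting layer.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterator, Mapping, Sequence

import yaml

logger = logging.getLogger("crtdcost")

SCHEMA_VERSION = 1

__all__ = [
    "ValidationError",
    "AnnualCurve",
    "DeviceProfile",
    "ComplicationModel",
    "CostSchedule",
    "ModelSettings",
    "ModelParameters",
    "builtin_base_case",
    "load_parameters",
    "save_parameters",
    "load_parameters_csv",
    "save_parameters_csv",
]


class ValidationError(ValueError):
    """An input violates a model invariant; the message names the field."""


def _check(condition: bool, path: str, rule: str) -> None:
    if not condition:
        raise ValidationError(f"{path}: {rule}")


@dataclass(frozen=True)
class AnnualCurve:
    """A survival function sampled at integer years.

    ``values[t]`` is the probability of still being event-free at year
    ``t`` (patient alive, or battery not yet at end of service at device
    age ``t``). Curves start at 1.0 and are non-increasing.
    """

    values: tuple[float, ...]

    def __init__(self, values: Sequence[float], *, path: str = "curve") -> None:
        vals = tuple(float(v) for v in values)
        _check(len(vals) >= 1, path, "curve must have at least one value (year 0)")
        _check(vals[0] == 1.0, path + ".values[0]",
               f"curve must start at 1.0 (100%), got {vals[0]!r}")
        for t, v in enumerate(vals):
            _check(0.0 <= v <= 1.0, f"{path}.values[{t}]",
                   f"probability out of [0, 1]: {v!r}")
            if t > 0:
                _check(v <= vals[t - 1], f"{path}.values[{t}]",
                       f"non-increasing violated ({vals[t-1]!r} -> {v!r} at year {t})")
        object.__setattr__(self, "values", vals)

    @property
    def horizon(self) -> int:
        """Last year covered by the curve."""
        return len(self.values) - 1

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, year: int) -> float:
        return self.values[year]

    def __iter__(self) -> Iterator[float]:
        return iter(self.values)


@dataclass(frozen=True)
class DeviceProfile:
    """One device model: a label, battery capacity in ampere-hours, and
    its event-free battery-survival curve by device age."""

    label: str
    capacity_ah: float
    battery_survival: AnnualCurve

    def __post_init__(self) -> None:
        path = f"devices[{self.label!r}]"
        _check(bool(self.label), path + ".label", "label must be non-empty")
        _check(self.capacity_ah > 0, path + ".capacity_ah",
               f"capacity must be positive, got {self.capacity_ah!r}")


@dataclass(frozen=True)
class ComplicationModel:
    """Procedure-related complication and infection incidences (first year
    after the procedure) and their per-event Medicare costs (2023 USD)."""

    p_complication_primary: float
    p_complication_replacement: float
    p_infection_primary: float
    p_infection_replacement: float
    cost_complication: float
    cost_infection: float

    def __post_init__(self) -> None:
        for name in ("p_complication_primary", "p_complication_replacement",
                     "p_infection_primary", "p_infection_replacement"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, f"complications.{name}",
                   f"probability out of [0, 1]: {v!r}")
        for name in ("cost_complication", "cost_infection"):
            v = getattr(self, name)
            _check(v >= 0, f"complications.{name}", f"cost must be >= 0, got {v!r}")


@dataclass(frozen=True)
class CostSchedule:
    """Medicare reimbursements (2023 USD) and visit schedule."""

    cost_initial_implant: float
    cost_replacement: float
    cost_followup_visit: float
    routine_visits_per_year: int = 4
    postprocedure_visits: int = 1

    def __post_init__(self) -> None:
        for name in ("cost_initial_implant", "cost_replacement", "cost_followup_visit"):
            v = getattr(self, name)
            _check(v >= 0, f"costs.{name}", f"cost must be >= 0, got {v!r}")
        for name in ("routine_visits_per_year", "postprocedure_visits"):
            v = getattr(self, name)
            _check(int(v) == v and v >= 0, f"costs.{name}",
                   f"must be a non-negative integer, got {v!r}")


@dataclass(frozen=True)
class ModelSettings:
    """Run settings: follow-up horizon, annual discount rate, the cap on
    replacements per patient, and the year offset at which procedure
    complications are costed (0 = the procedure year itself)."""

    horizon_years: int = 6
    discount_rate: float = 0.03
    max_replacements: int = 3
    complication_lag_years: int = 0

    def __post_init__(self) -> None:
        _check(int(self.horizon_years) == self.horizon_years and self.horizon_years >= 1,
               "settings.horizon_years", f"must be an integer >= 1, got {self.horizon_years!r}")
        _check(self.discount_rate >= 0, "settings.discount_rate",
               f"must be >= 0, got {self.discount_rate!r}")
        _check(int(self.max_replacements) == self.max_replacements and self.max_replacements >= 1,
               "settings.max_replacements", f"must be an integer >= 1, got {self.max_replacements!r}")
        _check(int(self.complication_lag_years) == self.complication_lag_years
               and self.complication_lag_years >= 0,
               "settings.complication_lag_years",
               f"must be a non-negative integer, got {self.complication_lag_years!r}")


@dataclass(frozen=True)
class ModelParameters:
    """The complete input bundle for one model run."""

    patient_survival: AnnualCurve
    devices: tuple[DeviceProfile, ...]
    complications: ComplicationModel
    costs: CostSchedule
    settings: ModelSettings = field(default_factory=ModelSettings)
    population_annual_implants: int = 15577
    population_cohort_years: int = 7

    def __post_init__(self) -> None:
        object.__setattr__(self, "devices", tuple(self.devices))
        _check(len(self.devices) >= 1, "devices", "at least one device profile required")
        labels = [d.label for d in self.devices]
        _check(len(set(labels)) == len(labels), "devices",
               f"device labels must be unique, got {labels}")
        H = self.settings.horizon_years
        _check(self.patient_survival.horizon >= H, "patient_survival",
               f"curve covers {self.patient_survival.horizon} years, horizon is {H}")
        for d in self.devices:
            _check(d.battery_survival.horizon >= H,
                   f"devices[{d.label!r}].battery_survival",
                   f"curve covers {d.battery_survival.horizon} years, horizon is {H}")
        _check(self.population_annual_implants >= 0, "population.annual_implants",
               f"must be >= 0, got {self.population_annual_implants!r}")
        _check(self.population_cohort_years >= 1, "population.cohort_entry_years",
               f"must be >= 1, got {self.population_cohort_years!r}")

    @property
    def device_labels(self) -> tuple[str, ...]:
        return tuple(d.label for d in self.devices)

    def device(self, label: str) -> DeviceProfile:
        for d in self.devices:
            if d.label == label:
                return d
        raise KeyError(f"unknown device label {label!r}; known: {list(self.device_labels)}")


# ---------------------------------------------------------------------------
# Structured-config (YAML/JSON) loading and saving
# ---------------------------------------------------------------------------

def _as_fraction_table(node: Mapping[str, Any], path: str) -> tuple[Mapping[str, Any], float]:
    """Return the table node and its probability divisor (100 if percent)."""
    if not isinstance(node, Mapping):
        raise ValidationError(f"{path}: expected a mapping, got {type(node).__name__}")
    percent = node.get("percent", False)
    if not isinstance(percent, bool):
        raise ValidationError(f"{path}.percent: expected true/false, got {percent!r}")
    return node, 100.0 if percent else 1.0


def _curve_from_config(node: Any, path: str) -> AnnualCurve:
    table, div = _as_fraction_table(node, path)
    values = table.get("values")
    if not isinstance(values, Sequence) or isinstance(values, (str, bytes)):
        raise ValidationError(f"{path}.values: expected a list of probabilities")
    return AnnualCurve([float(v) / div for v in values], path=path)


def _get(node: Mapping[str, Any], key: str, path: str) -> Any:
    if key not in node:
        raise ValidationError(f"{path}.{key}: required field missing")
    return node[key]


def _defaulted(node: Mapping[str, Any], key: str, default: Any, path: str) -> Any:
    if key not in node:
        logger.info("%s.%s not supplied; using default %r", path, key, default)
        return default
    return node[key]


def load_parameters(source: str | Path | Mapping[str, Any]) -> ModelParameters:
    """Load and validate :class:`ModelParameters` from a config document.

    ``source`` may be a path to a YAML or JSON file, or an already-parsed
    mapping with the same structure. Missing settings fall back to
    documented defaults (3% discount, 6-year horizon, 3 replacements max,
    4 routine visits/year, 1 post-procedure visit) with a logged notice.

    Raises
    ------
    ValidationError
        Naming the offending field and the violated rule.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        try:
            text = path.read_text()
        except OSError as exc:
            raise ValidationError(f"cannot read parameter file {path}: {exc}") from exc
        try:
            doc = yaml.safe_load(text)  # YAML is a superset of JSON
        except yaml.YAMLError as exc:
            raise ValidationError(f"{path}: malformed document: {exc}") from exc
    else:
        doc = source
    if not isinstance(doc, Mapping):
        raise ValidationError("document: expected a mapping at top level")

    version = doc.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValidationError(
            f"schema_version: unsupported version {version!r} (this release reads {SCHEMA_VERSION})")

    s = doc.get("settings", {})
    settings = ModelSettings(
        horizon_years=int(_defaulted(s, "horizon_years", 6, "settings")),
        discount_rate=float(_defaulted(s, "discount_rate", 0.03, "settings")),
        max_replacements=int(_defaulted(s, "max_replacements", 3, "settings")),
        complication_lag_years=int(_defaulted(s, "complication_lag_years", 0, "settings")),
    )

    pop = doc.get("population", {})
    annual = int(_defaulted(pop, "annual_implants", 15577, "population"))
    cohort_years = int(_defaulted(pop, "cohort_entry_years", 7, "population"))

    patient = _curve_from_config(_get(doc, "patient_survival", "document"),
                                 "patient_survival")

    dev_nodes = _get(doc, "devices", "document")
    if not isinstance(dev_nodes, Sequence):
        raise ValidationError("devices: expected a list of device profiles")
    devices = []
    for i, node in enumerate(dev_nodes):
        dpath = f"devices[{i}]"
        if not isinstance(node, Mapping):
            raise ValidationError(f"{dpath}: expected a mapping")
        devices.append(DeviceProfile(
            label=str(_get(node, "label", dpath)),
            capacity_ah=float(_get(node, "capacity_ah", dpath)),
            battery_survival=_curve_from_config(
                _get(node, "battery_survival", dpath), f"{dpath}.battery_survival"),
        ))

    comp_node, div = _as_fraction_table(_get(doc, "complications", "document"),
                                        "complications")
    complications = ComplicationModel(
        p_complication_primary=float(_get(comp_node, "complication_primary", "complications")) / div,
        p_complication_replacement=float(_get(comp_node, "complication_replacement", "complications")) / div,
        p_infection_primary=float(_get(comp_node, "infection_primary", "complications")) / div,
        p_infection_replacement=float(_get(comp_node, "infection_replacement", "complications")) / div,
        cost_complication=float(_get(comp_node, "cost_complication", "complications")),
        cost_infection=float(_get(comp_node, "cost_infection", "complications")),
    )

    cost_node = _get(doc, "costs", "document")
    costs = CostSchedule(
        cost_initial_implant=float(_get(cost_node, "initial_implant", "costs")),
        cost_replacement=float(_get(cost_node, "replacement", "costs")),
        cost_followup_visit=float(_get(cost_node, "followup_visit", "costs")),
        routine_visits_per_year=int(_defaulted(cost_node, "routine_visits_per_year", 4, "costs")),
        postprocedure_visits=int(_defaulted(cost_node, "postprocedure_visits", 1, "costs")),
    )

    return ModelParameters(
        patient_survival=patient,
        devices=tuple(devices),
        complications=complications,
        costs=costs,
        settings=settings,
        population_annual_implants=annual,
        population_cohort_years=cohort_years,
    )


def save_parameters(params: ModelParameters, path: str | Path | None = None) -> dict[str, Any]:
    """Serialise ``params`` to a config mapping; optionally write it out.

    Probabilities are written as fractions (``percent: false``) at full
    precision so that ``load_parameters(save_parameters(p)) == p`` exactly.
    A ``path`` ending in ``.json`` is written as JSON, anything else as YAML.
    """
    doc: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "settings": {
            "horizon_years": params.settings.horizon_years,
            "discount_rate": params.settings.discount_rate,
            "max_replacements": params.settings.max_replacements,
            "complication_lag_years": params.settings.complication_lag_years,
        },
        "population": {
            "annual_implants": params.population_annual_implants,
            "cohort_entry_years": params.population_cohort_years,
        },
        "patient_survival": {"percent": False, "values": list(params.patient_survival.values)},
        "devices": [
            {
                "label": d.label,
                "capacity_ah": d.capacity_ah,
                "battery_survival": {"percent": False,
                                     "values": list(d.battery_survival.values)},
            }
            for d in params.devices
        ],
        "complications": {
            "percent": False,
            "complication_primary": params.complications.p_complication_primary,
            "complication_replacement": params.complications.p_complication_replacement,
            "infection_primary": params.complications.p_infection_primary,
            "infection_replacement": params.complications.p_infection_replacement,
            "cost_complication": params.complications.cost_complication,
            "cost_infection": params.complications.cost_infection,
        },
        "costs": {
            "initial_implant": params.costs.cost_initial_implant,
            "replacement": params.costs.cost_replacement,
            "followup_visit": params.costs.cost_followup_visit,
            "routine_visits_per_year": params.costs.routine_visits_per_year,
            "postprocedure_visits": params.costs.postprocedure_visits,
        },
    }
    if path is not None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(doc, indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return doc


def builtin_base_case() -> ModelParameters:
    """The built-in base case: every input of the 6-year, 3%-discount
    Medicare analysis of the 2.1/1.0/1.6-Ah device profiles, shipped as a
    packaged fixture (``data/base_case.yaml``)."""
    ref = resources.files("crtdcost").joinpath("data/base_case.yaml")
    doc = yaml.safe_load(ref.read_text())
    return load_parameters(doc)


# ---------------------------------------------------------------------------
# CSV-table loading and saving
# ---------------------------------------------------------------------------
# One file per input block, mirroring the printed input table:
#   survival.csv       year,survival
#   battery.csv        label,capacity_ah,year,survival
#   complications.csv  parameter,value
#   costs.csv          parameter,value
#   settings.csv       parameter,value      (includes population fields)
# Survival columns hold fractions in [0, 1].

_CSV_FILES = ("survival.csv", "battery.csv", "complications.csv", "costs.csv",
              "settings.csv")


def save_parameters_csv(params: ModelParameters, directory: str | Path) -> list[Path]:
    import pandas as pd

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(name: str, frame: "pd.DataFrame") -> None:
        out = directory / name
        frame.to_csv(out, index=False)
        written.append(out)

    _write("survival.csv", pd.DataFrame({
        "year": range(len(params.patient_survival)),
        "survival": list(params.patient_survival.values),
    }))
    rows = [
        {"label": d.label, "capacity_ah": d.capacity_ah, "year": t, "survival": v}
        for d in params.devices for t, v in enumerate(d.battery_survival)
    ]
    _write("battery.csv", pd.DataFrame(rows))
    c = params.complications
    _write("complications.csv", pd.DataFrame(
        {"parameter": ["complication_primary", "complication_replacement",
                       "infection_primary", "infection_replacement",
                       "cost_complication", "cost_infection"],
         "value": [c.p_complication_primary, c.p_complication_replacement,
                   c.p_infection_primary, c.p_infection_replacement,
                   c.cost_complication, c.cost_infection]}))
    k = params.costs
    _write("costs.csv", pd.DataFrame(
        {"parameter": ["initial_implant", "replacement", "followup_visit",
                       "routine_visits_per_year", "postprocedure_visits"],
         "value": [k.cost_initial_implant, k.cost_replacement, k.cost_followup_visit,
                   k.routine_visits_per_year, k.postprocedure_visits]}))
    s = params.settings
    _write("settings.csv", pd.DataFrame(
        {"parameter": ["horizon_years", "discount_rate", "max_replacements",
                       "complication_lag_years", "annual_implants", "cohort_entry_years"],
         "value": [s.horizon_years, s.discount_rate, s.max_replacements,
                   s.complication_lag_years, params.population_annual_implants,
                   params.population_cohort_years]}))
    return written


def load_parameters_csv(directory: str | Path) -> ModelParameters:
    """Load :class:`ModelParameters` from a directory of CSV tables written
    by :func:`save_parameters_csv`."""
    import pandas as pd

    directory = Path(directory)
    for name in _CSV_FILES:
        if not (directory / name).exists():
            raise ValidationError(f"{directory / name}: required table missing")

    def _kv(name: str) -> dict[str, float]:
        frame = pd.read_csv(directory / name)
        return dict(zip(frame["parameter"].astype(str), frame["value"].astype(float)))

    surv = pd.read_csv(directory / "survival.csv").sort_values("year")
    _check(list(surv["year"]) == list(range(len(surv))), "survival.csv.year",
           "years must be contiguous integers starting at 0")
    patient = AnnualCurve(surv["survival"].tolist(), path="survival.csv")

    bat = pd.read_csv(directory / "battery.csv")
    devices = []
    for label, grp in bat.groupby("label", sort=False):
        grp = grp.sort_values("year")
        _check(list(grp["year"]) == list(range(len(grp))),
               f"battery.csv[{label!r}].year",
               "years must be contiguous integers starting at 0")
        devices.append(DeviceProfile(
            label=str(label),
            capacity_ah=float(grp["capacity_ah"].iloc[0]),
            battery_survival=AnnualCurve(grp["survival"].tolist(),
                                         path=f"battery.csv[{label!r}]"),
        ))

    comp = _kv("complications.csv")
    cost = _kv("costs.csv")
    sett = _kv("settings.csv")
    return ModelParameters(
        patient_survival=patient,
        devices=tuple(devices),
        complications=ComplicationModel(
            p_complication_primary=comp["complication_primary"],
            p_complication_replacement=comp["complication_replacement"],
            p_infection_primary=comp["infection_primary"],
            p_infection_replacement=comp["infection_replacement"],
            cost_complication=comp["cost_complication"],
            cost_infection=comp["cost_infection"],
        ),
        costs=CostSchedule(
            cost_initial_implant=cost["initial_implant"],
            cost_replacement=cost["replacement"],
            cost_followup_visit=cost["followup_visit"],
            routine_visits_per_year=int(cost["routine_visits_per_year"]),
            postprocedure_visits=int(cost["postprocedure_visits"]),
        ),
        settings=ModelSettings(
            horizon_years=int(sett["horizon_years"]),
            discount_rate=float(sett["discount_rate"]),
            max_replacements=int(sett["max_replacements"]),
            complication_lag_years=int(sett.get("complication_lag_years", 0)),
        ),
        population_annual_implants=int(sett["annual_implants"]),
        population_cohort_years=int(sett["cohort_entry_years"]),
    )
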