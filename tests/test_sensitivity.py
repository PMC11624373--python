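"""Univariate sensitivity analysis: scenario transforms, horizon
extrapolation, and tornado-table assembly."""

import dataclasses

import pytest

from crtdcost import (AnnualCurve, ComplicationModel, ReplaceCurve, ScaleCost,
                      ScenarioSpec, SetComplications, SetHorizon, ValidationError,
                      apply_scenario, extend_horizon, per_patient_costs,
                      procedure_cost_scenarios, run_dsa, scenarios_from_config)


class TestApplyScenario:
    def test_scale_initial_cost(self, base_case):
        out = apply_scenario(base_case, ScenarioSpec(
            "initial +20%", ScaleCost("initial", 1.2)))
        assert out.costs.cost_initial_implant == pytest.approx(41323.2)
        # univariate: nothing else moved
        assert out.costs.cost_replacement == base_case.costs.cost_replacement
        assert out.patient_survival == base_case.patient_survival
        # original untouched
        assert base_case.costs.cost_initial_implant == 34436

    def test_identity_factor_is_noop(self, base_case):
        out = apply_scenario(base_case, ScenarioSpec("x1", ScaleCost("replacement", 1.0)))
        assert out == base_case

    def test_set_complications_installed_verbatim(self, base_case):
        upper = ComplicationModel(0.06, 0.04, 0.03, 0.05, 2000.0, 40000.0)
        out = apply_scenario(base_case, ScenarioSpec("upper", SetComplications(upper)))
        assert out.complications == upper

    def test_replace_patient_curve(self, base_case):
        alt = AnnualCurve([1.0, 0.92, 0.86, 0.80, 0.75, 0.70, 0.65])
        out = apply_scenario(base_case, ScenarioSpec("alt survival",
                                                     ReplaceCurve("patient", alt)))
        assert out.patient_survival == alt

    def test_replace_battery_curve_by_label(self, base_case):
        alt = AnnualCurve([1.0, 1.0, 0.97, 0.95, 0.90, 0.85, 0.70])
        out = apply_scenario(base_case, ScenarioSpec("alt battery",
                                                     ReplaceCurve("2.1 Ah", alt)))
        assert out.device("2.1 Ah").battery_survival == alt
        assert out.device("1.0 Ah") == base_case.device("1.0 Ah")

    def test_missing_target_rejected(self, base_case):
        curve = AnnualCurve([1.0] * 7)
        with pytest.raises(ValidationError, match="not found"):
            apply_scenario(base_case, ScenarioSpec("bad", ReplaceCurve("3.0 Ah", curve)))

    def test_invalid_edit_rejected(self):
        with pytest.raises(ValidationError, match="factor"):
            ScaleCost("initial", 0.0)
        with pytest.raises(ValidationError, match="non-increasing"):
            AnnualCurve([1.0, 0.9, 0.95])


class TestExtendHorizon:
    def test_geometric_patient_tail(self, base_case):
        out = extend_horizon(base_case, 7)
        assert out.settings.horizon_years == 7
        assert out.patient_survival[7] == pytest.approx(0.72 * (0.72 / 0.77))

    def test_fifteen_year_curves_stay_valid(self, base_case):
        out = extend_horizon(base_case, 15)
        assert out.patient_survival.horizon == 15
        for d in out.devices:
            assert d.battery_survival.horizon == 15
            vals = d.battery_survival.values
            assert all(vals[t] >= vals[t + 1] >= 0.0 for t in range(15))

    def test_target_not_beyond_horizon_rejected(self, base_case):
        with pytest.raises(ValueError, match="exceed"):
            extend_horizon(base_case, 6)

    def test_absorbing_zero_tail(self, base_case):
        dead = dataclasses.replace(
            base_case,
            patient_survival=AnnualCurve([1.0, 0.5, 0.0, 0.0, 0.0, 0.0, 0.0]))
        out = extend_horizon(dead, 10)
        assert out.patient_survival.values[7:] == (0.0, 0.0, 0.0, 0.0)

    def test_explicit_tail_override(self, base_case):
        out = extend_horizon(base_case, 8, tails={"patient": [0.70, 0.68]})
        assert out.patient_survival.values[7:] == (0.70, 0.68)

    def test_extended_totals_dominate_base(self, base_case):
        out = extend_horizon(base_case, 15)
        for label in base_case.device_labels:
            assert (per_patient_costs(out, label).total
                    >= per_patient_costs(base_case, label).total)


class TestRunDsa:
    def test_procedure_cost_extremes_are_exact_year0_arithmetic(self, base_case):
        table = run_dsa(base_case, procedure_cost_scenarios(),
                        "2.1 Ah", ["1.0 Ah", "1.6 Ah"])
        base_total = table.base.totals["2.1 Ah"]
        lo, hi = table.reference_total_range
        assert lo == pytest.approx(base_total - 0.2 * 34436, rel=1e-12)
        assert hi == pytest.approx(base_total + 0.2 * 34436, rel=1e-12)
        # the extremes come from the initial-cost scenarios
        by_name = {row.scenario_name: row for row in table.rows}
        assert by_name["initial cost x1.2"].totals["2.1 Ah"] == pytest.approx(hi)
        assert by_name["initial cost x0.8"].totals["2.1 Ah"] == pytest.approx(lo)

    def test_initial_scaling_shifts_every_device_equally(self, base_case):
        table = run_dsa(base_case,
                        [ScenarioSpec("up", ScaleCost("initial", 1.2))],
                        "2.1 Ah", ["1.0 Ah"])
        for label in base_case.device_labels:
            assert (table.rows[0].totals[label] - table.base.totals[label]
                    == pytest.approx(0.2 * 34436, rel=1e-12))
        # savings therefore unchanged
        assert table.rows[0].savings["1.0 Ah"][0] == \
            pytest.approx(table.base.savings["1.0 Ah"][0], rel=1e-12)

    def test_replacement_scaling_scales_replacement_gap(self, base_case):
        table = run_dsa(base_case,
                        [ScenarioSpec("up", ScaleCost("replacement", 1.2))],
                        "2.1 Ah", ["1.0 Ah"])
        base_proc_gap = (per_patient_costs(base_case, "1.0 Ah").replacement_procedures
                         - per_patient_costs(base_case, "2.1 Ah").replacement_procedures)
        delta = table.rows[0].savings["1.0 Ah"][0] - table.base.savings["1.0 Ah"][0]
        assert delta == pytest.approx(0.2 * base_proc_gap, rel=1e-9)

    def test_empty_scenario_list(self, base_case):
        table = run_dsa(base_case, [], "2.1 Ah", ["1.0 Ah"])
        assert table.rows == ()
        assert table.reference_total_range[0] == table.reference_total_range[1]

    def test_failure_names_scenario(self, base_case):
        bad = ScenarioSpec("broken one", ReplaceCurve("nope", AnnualCurve([1.0] * 7)))
        with pytest.raises(RuntimeError, match="broken one"):
            run_dsa(base_case, [bad], "2.1 Ah", ["1.0 Ah"])

    def test_rows_ordered_by_swing_then_name(self, base_case):
        table = run_dsa(base_case, procedure_cost_scenarios(),
                        "2.1 Ah", ["1.0 Ah"])
        base_total = table.base.totals["2.1 Ah"]
        swings = [abs(r.totals["2.1 Ah"] - base_total) for r in table.rows]
        assert swings == sorted(swings, reverse=True)
        for a, b in zip(table.rows, table.rows[1:]):
            if abs(a.totals["2.1 Ah"] - base_total) == abs(b.totals["2.1 Ah"] - base_total):
                assert a.scenario_name <= b.scenario_name


class TestScenarioConfig:
    def test_load_from_yaml(self, base_case, tmp_path):
        path = tmp_path / "scenarios.yaml"
        path.write_text("""
scenarios:
  - name: initial +20%
    transform: {type: scale_cost, target: initial, factor: 1.2}
  - name: fifteen years
    transform: {type: set_horizon, years: 15}
  - name: alt patient survival
    transform:
      type: replace_curve
      target: patient
      curve: {percent: true, values: [100, 92, 86, 80, 75, 70, 65]}
""")
        specs = scenarios_from_config(path)
        assert [s.name for s in specs] == ["initial +20%", "fifteen years",
                                           "alt patient survival"]
        assert isinstance(specs[1].transform, SetHorizon)
        table = run_dsa(base_case, specs, "2.1 Ah", ["1.0 Ah"])
        assert len(table.rows) == 3

    def test_unknown_transform_type_rejected(self):
        with pytest.raises(ValidationError, match="unknown transform"):
            scenarios_from_config([{"name": "x", "transform": {"type": "wibble"}}])
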