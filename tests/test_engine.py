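"""Cohort engine: depletion densities, the renewal convolution (checked
against an independent path-enumeration oracle), discounting, and the
per-patient cost breakdown."""

import dataclasses

import numpy as np
import pytest

from crtdcost import (AnnualCurve, GeneratorConfig, battery_event_density,
                      compare_devices, discount_factor, expected_complication_cost,
                      expected_replacement_events, generate_parameters,
                      per_patient_costs, renewal_distribution, replacement_distribution)


def enumerate_renewal(f, horizon, max_replacements):
    """Independent oracle: explicit enumeration of replacement paths.

    Walks every sequence of depletion ages recursively and accumulates the
    probability of the k-th replacement landing at calendar year t --
    no convolution involved.
    """
    g = np.zeros((max_replacements, horizon + 1))

    def walk(k, implant_year, prob):
        if k >= max_replacements:
            return
        for age, p_age in enumerate(f):
            t = implant_year + age
            if p_age == 0.0 or t > horizon:
                continue
            g[k, t] += prob * p_age
            walk(k + 1, t, prob * p_age)

    walk(0, 0, 1.0)
    return g


class TestDiscountFactor:
    @pytest.mark.parametrize("rate, year, expected", [
        (0.03, 0, 1.0),
        (0.0, 5, 1.0),
        (0.03, 2, 1.0 / 1.03**2),
    ])
    def test_closed_form(self, rate, year, expected):
        assert discount_factor(rate, year) == pytest.approx(expected, abs=1e-12)

    def test_negative_year_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            discount_factor(0.03, -1)


class TestBatteryEventDensity:
    @pytest.mark.parametrize("label, expected_f", [
        ("2.1 Ah", [0, 0, 0.02, 0, 0.03, 0.05, 0.13]),
        ("1.0 Ah", [0, 0, 0.01, 0.07, 0.18, 0.38, 0.26]),
        ("1.6 Ah", [0, 0, 0, 0, 0.10, 0.21, 0.25]),
    ])
    def test_base_case_differences(self, base_case, label, expected_f):
        f = battery_event_density(base_case.device(label).battery_survival, 6)
        assert f == pytest.approx(expected_f, abs=1e-12)
        curve = base_case.device(label).battery_survival
        assert f.sum() == pytest.approx(1.0 - curve[6], abs=1e-12)

    def test_no_depletion_curve(self):
        f = battery_event_density(AnnualCurve([1.0] * 7), 6)
        assert np.all(f == 0.0)


class TestRenewalDistribution:
    def test_grace_structure_and_hand_values(self, base_case):
        f = battery_event_density(base_case.device("2.1 Ah").battery_survival, 6)
        g = renewal_distribution(f, 6, 3)
        assert g[0, 2] == pytest.approx(0.02)
        # earliest k-th replacement at year 2k
        for k in range(3):
            assert np.all(g[k, : 2 * (k + 1)] == 0.0)
        assert g[1, 4] == pytest.approx(0.02 * 0.02)

    def test_fourth_replacement_impossible_within_six_years(self, base_case):
        for d in base_case.devices:
            f = battery_event_density(d.battery_survival, 6)
            g = renewal_distribution(f, 6, 4)
            assert np.all(g[3] == 0.0)

    def test_zero_density_gives_zero_masses(self):
        g = renewal_distribution(np.zeros(7), 6, 3)
        assert np.all(g == 0.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_path_enumeration_oracle(self, seed):
        params = generate_parameters(GeneratorConfig(seed=seed))
        for d in params.devices:
            f = battery_event_density(d.battery_survival, 6)
            g = renewal_distribution(f, 6, 3)
            assert g == pytest.approx(enumerate_renewal(f, 6, 3), abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_conservation(self, seed):
        params = generate_parameters(GeneratorConfig(seed=seed))
        for d in params.devices:
            f = battery_event_density(d.battery_survival, 6)
            g = renewal_distribution(f, 6, 3)
            assert np.all(g.sum(axis=1) <= 1.0 + 1e-12)
            assert g.sum() <= 3.0 + 1e-12


class TestExpectedReplacementEvents:
    def test_alive_weighting_hand_value(self, base_case):
        dist = replacement_distribution(base_case, "2.1 Ah")
        R = dist.expected_events_by_year
        assert R[2] == pytest.approx(0.90 * 0.02)
        assert np.all(dist.alive_weighted_mass <= dist.mass + 1e-15)

    def test_immortal_cohort_identity(self, base_case):
        f = battery_event_density(base_case.device("1.0 Ah").battery_survival, 6)
        g = renewal_distribution(f, 6, 3)
        R = expected_replacement_events(g, AnnualCurve([1.0] * 7))
        assert R == pytest.approx(g.sum(axis=0), abs=1e-15)

    def test_zero_mass(self, base_case):
        R = expected_replacement_events(np.zeros((3, 7)), base_case.patient_survival)
        assert np.all(R == 0.0)


class TestExpectedComplicationCost:
    def test_base_case_values(self, base_case):
        cm = base_case.complications
        assert expected_complication_cost("primary", cm) == pytest.approx(635.48)
        assert expected_complication_cost("replacement", cm) == pytest.approx(908.74)

    def test_zero_incidence(self, base_case):
        cm = dataclasses.replace(base_case.complications,
                                 p_complication_primary=0.0, p_infection_primary=0.0)
        assert expected_complication_cost("primary", cm) == 0.0

    def test_unknown_context_rejected(self, base_case):
        with pytest.raises(ValueError, match="context"):
            expected_complication_cost("tertiary", base_case.complications)


class TestPerPatientCosts:
    def test_no_replacement_zero_discount_closed_form(self, base_case):
        devices = tuple(
            dataclasses.replace(d, battery_survival=AnnualCurve([1.0] * 7))
            for d in base_case.devices)
        settings = dataclasses.replace(base_case.settings, discount_rate=0.0)
        params = dataclasses.replace(base_case, devices=devices, settings=settings)
        bd = per_patient_costs(params, "2.1 Ah")
        expected = 34436 + 635.48 + 82 + 328 * (0.95 + 0.90 + 0.85 + 0.81 + 0.77 + 0.72)
        assert bd.replacement_total == 0.0
        assert bd.total == pytest.approx(expected, abs=1e-9)

    def test_unknown_device_rejected(self, base_case):
        with pytest.raises(KeyError, match="unknown device"):
            per_patient_costs(base_case, "9.9 Ah")

    def test_additivity(self, base_case):
        for label in base_case.device_labels:
            bd = per_patient_costs(base_case, label).as_dict()
            assert bd["initial_total"] == pytest.approx(
                bd["initial_procedure"] + bd["initial_complications"] + bd["initial_followups"])
            assert bd["total"] == pytest.approx(
                bd["initial_total"] + bd["replacement_total"] + bd["routine_followups"])
            assert all(v >= 0 for v in bd.values())

    @pytest.mark.parametrize("seed", range(6))
    def test_discount_monotonicity(self, seed):
        params = generate_parameters(GeneratorConfig(seed=seed))
        flat = dataclasses.replace(
            params, settings=dataclasses.replace(params.settings, discount_rate=0.0))
        for label in params.device_labels:
            undiscounted = per_patient_costs(flat, label).as_dict()
            discounted = per_patient_costs(params, label).as_dict()
            for cat, v0 in undiscounted.items():
                assert v0 >= discounted[cat] - 1e-9
            # year-0 categories are unaffected by the rate
            for cat in ("initial_procedure", "initial_followups"):
                assert undiscounted[cat] == discounted[cat]

    @pytest.mark.parametrize("seed", range(6))
    def test_battery_dominance(self, seed):
        """Pointwise-better battery curves never cost more in replacements."""
        params = generate_parameters(GeneratorConfig(seed=seed))
        labels = params.device_labels
        for weak, strong in zip(labels, labels[1:]):  # capacities are sorted
            weak_curve = params.device(weak).battery_survival
            strong_curve = params.device(strong).battery_survival
            assert all(s >= w for s, w in zip(strong_curve, weak_curve))
            assert (per_patient_costs(params, strong).replacement_total
                    <= per_patient_costs(params, weak).replacement_total + 1e-9)

    def test_horizon_monotonicity(self, base_case):
        for label in base_case.device_labels:
            previous = None
            for h in range(7):
                bd = per_patient_costs(base_case, label, horizon=h).as_dict()
                if previous is not None:
                    for cat, v in bd.items():
                        assert v >= previous[cat] - 1e-9
                previous = bd


class TestCompareDevices:
    def test_base_case_differences(self, base_case):
        cmp = compare_devices(base_case, "2.1 Ah", "1.6 Ah")
        assert cmp.absolute["replacement_total"] == pytest.approx(6988, rel=2e-4)
        assert cmp.percent["replacement_total"] == pytest.approx(140, abs=1)

    def test_identical_labels_zero(self, base_case):
        cmp = compare_devices(base_case, "2.1 Ah", "2.1 Ah")
        assert all(v == 0.0 for v in cmp.absolute.values())

    def test_zero_reference_category_not_applicable(self, base_case):
        devices = tuple(
            dataclasses.replace(d, battery_survival=AnnualCurve([1.0] * 7))
            if d.label == "2.1 Ah" else d
            for d in base_case.devices)
        params = dataclasses.replace(base_case, devices=devices)
        cmp = compare_devices(params, "2.1 Ah", "1.0 Ah")
        assert cmp.percent["replacement_total"] is None
        assert cmp.absolute["replacement_total"] > 0

    def test_unknown_label_rejected(self, base_case):
        with pytest.raises(KeyError):
            compare_devices(base_case, "2.1 Ah", "missing")
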