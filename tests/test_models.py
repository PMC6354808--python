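"""Compartmental structures and the exact concentration solver."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neuropk.models import (
    CSF,
    PLASMA,
    DoseEvent,
    InvalidParameterError,
    Observation,
    PKParams,
    StructureMismatchError,
    SubjectRecord,
    build_rate_matrix,
    get_structure,
    list_structures,
    predict_concentrations,
    solve_amounts,
    standard_regimen,
)
from neuropk.npag import default_bounds

from conftest import reference_ode_amounts


class TestDomainTypes:
    def test_dose_event_validation(self):
        with pytest.raises(ValueError):
            DoseEvent(-1.0, 10.0)
        with pytest.raises(ValueError):
            DoseEvent(0.0, -10.0)
        with pytest.raises(ValueError):
            DoseEvent(0.0, 10.0, -0.1)

    def test_observation_channel_and_sign(self):
        with pytest.raises(ValueError):
            Observation(1.0, 5.0, "serum")
        with pytest.raises(ValueError):
            Observation(1.0, -5.0, PLASMA)
        # excluded rows may carry any recorded value
        Observation(1.0, -5.0, PLASMA, excluded=True)

    def test_subject_requires_dose_and_weight(self):
        with pytest.raises(ValueError):
            SubjectRecord("r", 306.0, doses=[])
        with pytest.raises(ValueError):
            SubjectRecord("r", 0.0, doses=[DoseEvent(0, 1)])

    def test_standard_regimen_dose_amount(self):
        doses = standard_regimen(weight_g=306.0)
        assert len(doses) == 4
        assert all(d.amount == pytest.approx(45.9) for d in doses)
        assert doses[1].start_time == 24.0

    def test_params_vector_round_trip(self, four_comp, medians):
        v = medians.to_vector(four_comp)
        assert PKParams.from_vector(v, four_comp).to_vector(four_comp) == pytest.approx(v)

    def test_missing_active_param_raises(self, four_comp):
        with pytest.raises(InvalidParameterError):
            PKParams(kel=1.0, Vc=0.1).to_vector(four_comp)


class TestRateMatrix:
    def test_isolated_elimination_two_compartment(self):
        p = PKParams(kel=1.0, Vc=0.1, V_CSF=0.1, K13=0.0, K41=0.0)
        A = build_rate_matrix(p, "two_compartment")
        assert np.array_equal(A, np.array([[-1.0, 0.0], [0.0, 0.0]]))

    def test_reference_median_column_sums(self, medians, four_comp):
        # only the central compartment loses mass, at rate kel
        A = build_rate_matrix(medians, four_comp)
        np.testing.assert_allclose(A.sum(axis=0), [-3.15, 0.0, 0.0, 0.0], atol=1e-12)

    @pytest.mark.parametrize("name", ["two_compartment", "three_compartment",
                                      "three_compartment_lag_constant",
                                      "four_compartment_lag"])
    def test_total_outflow_equals_kel(self, name, medians):
        A = build_rate_matrix(medians, name)
        assert A.sum() == pytest.approx(-medians.kel, rel=1e-12)

    def test_offdiagonals_nonnegative(self, medians):
        for name in list_structures():
            A = build_rate_matrix(medians, name)
            off = A[~np.eye(len(A), dtype=bool)]
            assert np.all(off >= 0)

    def test_negative_rate_rejected(self):
        with pytest.raises(InvalidParameterError):
            build_rate_matrix(
                PKParams(kel=1.0, Vc=0.1, V_CSF=0.1, K13=-0.1, K41=0.2),
                "two_compartment",
            )


class TestSolver:
    def test_no_doses_all_zero(self, medians, four_comp):
        # an empty regimen is an error at the record level but the solver
        # itself must return zeros
        am = solve_amounts(medians, four_comp, [], [0.0, 1.0, 5.0])
        assert np.array_equal(am, np.zeros((3, 4)))

    def test_one_compartment_bolus_closed_form(self):
        p = PKParams(kel=1.0, Vc=0.1)
        am = solve_amounts(p, "one_compartment", [DoseEvent(0.0, 100.0, 0.0)], [np.log(2)])
        assert am[0, 0] == pytest.approx(50.0, rel=1e-12)

    def test_matches_numeric_oracle_at_reference_medians(
        self, medians, four_comp, single_dose
    ):
        times = [0.2, 1.0, 2.0, 8.0]
        exact = solve_amounts(medians, four_comp, single_dose, times)
        oracle = reference_ode_amounts(medians, four_comp, single_dose, times)
        np.testing.assert_allclose(exact, oracle, rtol=1e-6, atol=1e-12)

    def test_matches_numeric_oracle_random_draws(self, four_comp):
        lo, hi = default_bounds(four_comp).arrays(four_comp)
        rng = np.random.default_rng(20260925)
        doses = [DoseEvent(0.0, 45.9, 1 / 30), DoseEvent(24.0, 45.9, 1 / 30)]
        times = [0.1, 0.5, 2.0, 23.9, 24.1, 25.0]
        dose_scale = 1e-6 * sum(d.amount for d in doses)
        for _ in range(25):
            theta = np.exp(rng.uniform(np.log(lo), np.log(hi)))
            p = PKParams.from_vector(theta, four_comp)
            exact = solve_amounts(p, four_comp, doses, times)
            oracle = reference_ode_amounts(p, four_comp, doses, times)
            err = np.abs(exact - oracle) / np.maximum(np.abs(oracle), dose_scale)
            assert err.max() < 1e-6

    def test_mass_conservation_without_elimination(self, medians, four_comp):
        p = medians.replace(kel=0.0)
        doses = standard_regimen()
        after_last = 72.0 + 1 / 30
        am = solve_amounts(p, four_comp, doses, [after_last, 80.0, 120.0])
        totals = am.sum(axis=1)
        np.testing.assert_allclose(totals, 4 * 45.9, rtol=1e-9)

    def test_superposition_of_daily_doses(self, medians, four_comp):
        times = np.array([0.5, 10.0, 24.5, 30.0, 75.0, 90.0])
        doses = standard_regimen()
        full = solve_amounts(medians, four_comp, doses, times)
        summed = sum(
            solve_amounts(medians, four_comp, [d], times) for d in doses
        )
        np.testing.assert_allclose(full, summed, rtol=1e-9, atol=1e-12)

    def test_monotone_washout(self, medians, four_comp, single_dose):
        times = np.linspace(1.0, 48.0, 60)
        am = solve_amounts(medians, four_comp, single_dose, times)
        totals = am.sum(axis=1)
        assert np.all(np.diff(totals) <= 1e-12)

    def test_overlapping_infusions_sum(self, medians, four_comp):
        # two overlapping infusions equal one at double rate
        d2 = [DoseEvent(0.0, 20.0, 1.0), DoseEvent(0.0, 20.0, 1.0)]
        d1 = [DoseEvent(0.0, 40.0, 1.0)]
        t = [0.5, 1.0, 2.0]
        np.testing.assert_allclose(
            solve_amounts(medians, four_comp, d2, t),
            solve_amounts(medians, four_comp, d1, t),
            rtol=1e-12,
        )

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=20, deadline=None)
    def test_linearity_in_dose(self, scale):
        medians = PKParams(
            kel=3.15, Vc=0.11, V_CSF=0.14, K12=18.2, K21=41.98,
            K13=0.13, K34=2.96, K41=0.47,
        )
        four_comp = get_structure("four_compartment_lag")
        base = [DoseEvent(0.0, 45.9, 1 / 30)]
        scaled = [DoseEvent(0.0, 45.9 * scale, 1 / 30)]
        t = [0.2, 1.0, 6.0]
        np.testing.assert_allclose(
            solve_amounts(medians, four_comp, scaled, t),
            scale * solve_amounts(medians, four_comp, base, t),
            rtol=1e-9,
            atol=1e-12,
        )


class TestPredictConcentrations:
    def test_amount_to_concentration_division(self, single_dose):
        # 11 mg in a 0.11-liter central compartment is 100 ug/ml; with no
        # distribution or elimination the bolus stays put
        p = PKParams(kel=0.0, Vc=0.11)
        c = predict_concentrations(
            p, "one_compartment", [DoseEvent(0.0, 11.0, 0.0)], [5.0], PLASMA
        )
        assert c[0] == pytest.approx(100.0, rel=1e-12)

    def test_zero_doses_zero_everywhere(self, medians, four_comp):
        c = predict_concentrations(medians, four_comp, [], [0.5, 3.0], CSF)
        assert np.array_equal(c, [0.0, 0.0])

    def test_dose_doubling_doubles_concentration(self, medians, four_comp, single_dose):
        t = [0.2, 1.0, 5.0]
        c1 = predict_concentrations(medians, four_comp, single_dose, t, PLASMA)
        double = [DoseEvent(0.0, 2 * 45.9, 1 / 30)]
        c2 = predict_concentrations(medians, four_comp, double, t, PLASMA)
        np.testing.assert_allclose(c2, 2 * c1, rtol=1e-9)

    def test_plasma_vs_oracle(self, medians, four_comp, single_dose):
        oracle = reference_ode_amounts(medians, four_comp, single_dose, [0.2])
        expected = oracle[0, 0] / medians.Vc
        got = predict_concentrations(medians, four_comp, single_dose, [0.2], PLASMA)[0]
        assert got == pytest.approx(expected, rel=1e-6)

    def test_csf_output_requires_csf_state(self, single_dose):
        p = PKParams(kel=1.0, Vc=0.1)
        with pytest.raises(StructureMismatchError):
            predict_concentrations(p, "one_compartment", single_dose, [1.0], CSF)
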