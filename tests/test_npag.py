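"""Nonparametric population fitting, posteriors and posterior profiles."""

import numpy as np
import pytest

from neuropk.likelihood import ErrorModel, ErrorPolynomial, default_error_model
from neuropk.models import (
    CSF,
    PLASMA,
    DoseEvent,
    Observation,
    SubjectRecord,
    get_structure,
    predict_concentrations,
)
from neuropk.npag import (
    NPAG,
    ParamBounds,
    PopulationModel,
    SupportPoint,
    _optimize_weights,
    bayesian_posterior,
    default_bounds,
    fit_population,
    initialize_grid,
    population_diagnostics,
    posterior_profile,
    weighted_median,
)
from neuropk.simulate import rich_design, simulate_study


class TestBoundsAndGrid:
    def test_default_bounds_bracket_reference_medians(self, medians, four_comp):
        lo, hi = default_bounds(four_comp).arrays(four_comp)
        v = medians.to_vector(four_comp)
        assert np.all(lo < v) and np.all(v < hi)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            ParamBounds({"kel": 1.0}, {"kel": 0.5})
        with pytest.raises(ValueError):
            ParamBounds({"kel": 0.0}, {"kel": 1.0})

    def test_single_point_grid(self, four_comp):
        pts = initialize_grid(default_bounds(four_comp), 1, seed=0, structure=four_comp)
        assert len(pts) == 1
        assert pts[0].probability == 1.0

    def test_grid_determinism(self, four_comp):
        b = default_bounds(four_comp)
        a = initialize_grid(b, 100, seed=5, structure=four_comp)
        c = initialize_grid(b, 100, seed=5, structure=four_comp)
        assert all(x.params == y.params for x, y in zip(a, c))

    def test_grid_inside_box_with_equal_weights(self, four_comp):
        b = default_bounds(four_comp)
        lo, hi = b.arrays(four_comp)
        pts = initialize_grid(b, 1000, seed=1, structure=four_comp)
        theta = np.vstack([p.params.to_vector(four_comp) for p in pts])
        assert np.all(theta >= lo) and np.all(theta <= hi)
        assert all(p.probability == pytest.approx(1 / 1000) for p in pts)


class TestWeightedMedian:
    def test_three_point_hand_case(self):
        # cumulative weights 0.2, 0.5, 1.0 -> the 0.5 quantile is the
        # second sorted value
        assert weighted_median([5.0, 1.0, 3.0], [0.5, 0.2, 0.3]) == 3.0

    def test_equal_weights_is_lower_median(self):
        assert weighted_median([1.0, 2.0, 3.0, 4.0], [0.25] * 4) == 2.0

    def test_dominant_weight_wins(self):
        assert weighted_median([1.0, 2.0, 9.0], [0.05, 0.05, 0.9]) == 9.0


def _noise_free_subject(params, structure, sid="T1"):
    doses = [DoseEvent(0.0, 45.9, 1 / 30)]
    t_p = [0.1, 0.3, 0.5, 1.0, 2.0, 4.0]
    t_c = [0.5, 1.0, 2.0, 4.0]
    obs = [
        Observation(t, float(predict_concentrations(params, structure, doses, [t], PLASMA)[0]), PLASMA)
        for t in t_p
    ] + [
        Observation(t, float(predict_concentrations(params, structure, doses, [t], CSF)[0]), CSF)
        for t in t_c
    ]
    return SubjectRecord(sid, 306.0, doses, obs)


class TestFitPopulation:
    def test_noiseless_subject_concentrates_on_true_grid_point(self, medians, four_comp):
        # the true parameter vector is planted in the initial grid; with a
        # noise-free subject nearly all mass must land on it
        sub = _noise_free_subject(medians, four_comp)
        bounds = default_bounds(four_comp)
        est = NPAG(
            seed=3, n_init=64, max_cycles=0, polish=False, bounds=bounds
        )
        truth_vec = medians.to_vector(four_comp)
        # plant the truth by fitting a model whose grid includes it
        from neuropk.npag import _sobol_grid

        lo, hi = bounds.arrays(four_comp)
        grid = np.vstack([_sobol_grid(lo, hi, 63, 3), truth_vec])
        from neuropk.likelihood import subject_neg2ll_stacked

        ll = -0.5 * subject_neg2ll_stacked(grid, sub, four_comp)
        w, _ = _optimize_weights(ll[None, :])
        assert w[-1] > 0.99

    def test_seed_is_required(self):
        subjects, _ = simulate_study(design=rich_design(2), seed=0)
        with pytest.raises(ValueError, match="seed"):
            NPAG().fit(subjects)

    def test_neg2ll_monotone_and_reproducible(self):
        subjects, _ = simulate_study(design=rich_design(4), seed=11)
        kw = dict(seed=2, n_init=128, max_cycles=8, polish_max_points=5)
        m1 = fit_population(subjects, **kw)
        m2 = fit_population(subjects, **kw)
        traj = [c["neg2ll"] for c in m1.cycle_log]
        assert all(b <= a + 1e-9 for a, b in zip(traj, traj[1:]))
        assert m1.neg2ll == m2.neg2ll
        assert np.allclose(m1.weights(), m2.weights())
        assert m1.weights().sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_expansion_reduces_to_fixed_grid_weights(self):
        subjects, _ = simulate_study(design=rich_design(3), seed=13)
        est = NPAG(
            seed=4, n_init=96, max_cycles=6, expansion_fraction=0.0,
            min_expansion=0.0, polish=False,
        )
        est.fit(subjects)
        # reference: optimize weights once on the same fixed grid
        from neuropk.likelihood import subject_neg2ll_stacked
        from neuropk.npag import _sobol_grid

        st = get_structure("four_compartment_lag")
        lo, hi = default_bounds(st).arrays(st)
        grid = _sobol_grid(lo, hi, 96, 4)
        ll = np.vstack(
            [-0.5 * subject_neg2ll_stacked(grid, s, st) for s in subjects]
        )
        _, n2 = _optimize_weights(ll)
        assert est.neg2ll_ == pytest.approx(n2, abs=1e-6)

    def test_impossible_data_raises_helpful_error(self, four_comp):
        from neuropk.npag import FitError

        doses = [DoseEvent(0.0, 45.9, 1 / 30)]
        # with a purely additive error the density underflows when the
        # observations sit far above anything the box can predict
        em = ErrorModel(
            {PLASMA: ErrorPolynomial(1.0, 0.0), CSF: ErrorPolynomial(1.0, 0.0)}
        )
        obs = [Observation(t, 1e6, PLASMA) for t in (0.2, 0.5, 1.0)]
        sub = SubjectRecord("bad", 306.0, doses, obs)
        with pytest.raises(FitError, match="bounds"):
            NPAG(
                seed=1, n_init=16, max_cycles=1, polish=False, error_model=em
            ).fit([sub])

    def test_sklearn_estimator_interface(self):
        est = NPAG(seed=5, n_init=32)
        params = est.get_params()
        assert params["n_init"] == 32
        est.set_params(n_init=64)
        assert est.n_init == 64


class TestBayesianPosterior:
    def _model_from_points(self, points, structure="four_compartment_lag"):
        return PopulationModel(
            structure=structure,
            support_points=points,
            error_model=default_error_model(),
            neg2ll=0.0,
            aic=0.0,
        )

    def test_single_point_posterior_is_one(self, medians, four_comp):
        sub = _noise_free_subject(medians, four_comp)
        model = self._model_from_points([SupportPoint(medians, 1.0)])
        post = bayesian_posterior(sub, model)
        assert post == pytest.approx([1.0])

    def test_two_points_likelihood_ratio_four_to_one(self):
        # discrete Bayes with equal priors: posterior follows the ratio
        ll = np.log(np.array([4.0, 1.0]))
        prior = np.array([0.5, 0.5])
        post = prior * np.exp(ll)
        post /= post.sum()
        assert post == pytest.approx([0.8, 0.2])

    def test_five_point_hand_normalization(self, medians, four_comp):
        from neuropk.likelihood import subject_neg2ll

        sub = _noise_free_subject(medians, four_comp)
        pts = [
            SupportPoint(medians.replace(kel=medians.kel * f), p)
            for f, p in zip([0.6, 0.8, 1.0, 1.25, 2.0], [0.1, 0.2, 0.4, 0.2, 0.1])
        ]
        model = self._model_from_points(pts)
        post = bayesian_posterior(sub, model)
        ll = np.array(
            [-0.5 * subject_neg2ll(p.params, sub, four_comp) for p in pts]
        )
        expected = np.array([p.probability for p in pts]) * np.exp(ll - ll.max())
        expected /= expected.sum()
        np.testing.assert_allclose(post, expected, atol=1e-12)
        assert post.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_prior_stays_zero(self, medians, four_comp):
        sub = _noise_free_subject(medians, four_comp)
        pts = [
            SupportPoint(medians, 1.0),
            SupportPoint(medians.replace(kel=1.0), 0.0),
        ]
        post = bayesian_posterior(sub, self._model_from_points(pts))
        assert post[1] == 0.0

    def test_no_observations_returns_prior_with_warning(self, medians, four_comp):
        sub = SubjectRecord(
            "empty", 306.0, [DoseEvent(0.0, 45.9, 1 / 30)], []
        )
        pts = [SupportPoint(medians, 0.7), SupportPoint(medians.replace(kel=1.0), 0.3)]
        model = self._model_from_points(pts)
        with pytest.warns(UserWarning, match="posterior equals prior"):
            post = bayesian_posterior(sub, model)
        assert post == pytest.approx([0.7, 0.3])


class TestPosteriorProfile:
    def test_twelve_minute_grid_has_121_points(self, medians, four_comp):
        sub = _noise_free_subject(medians, four_comp)
        model = PopulationModel(
            structure="four_compartment_lag",
            support_points=[SupportPoint(medians, 1.0)],
            error_model=default_error_model(),
            neg2ll=0.0,
            aic=0.0,
        )
        prof = posterior_profile(sub, model, grid_step=0.2, horizon=24.0)
        assert len(prof.times) == 121
        assert prof.times[1] == pytest.approx(0.2)

    def test_single_point_profile_equals_prediction(self, medians, four_comp):
        sub = _noise_free_subject(medians, four_comp)
        model = PopulationModel(
            structure="four_compartment_lag",
            support_points=[SupportPoint(medians, 1.0)],
            error_model=default_error_model(),
            neg2ll=0.0,
            aic=0.0,
        )
        prof = posterior_profile(sub, model)
        direct = predict_concentrations(
            medians, four_comp, sub.doses, prof.times, PLASMA
        )
        np.testing.assert_allclose(prof.channel(PLASMA), direct, rtol=1e-12)

    def test_weighted_median_aggregation_three_points(self, medians, four_comp):
        sub = _noise_free_subject(medians, four_comp)
        pts = [
            SupportPoint(medians.replace(Vc=v), p)
            for v, p in [(0.10, 0.3), (0.11, 0.4), (0.12, 0.3)]
        ]
        model = PopulationModel(
            structure="four_compartment_lag",
            support_points=pts,
            error_model=default_error_model(),
            neg2ll=0.0,
            aic=0.0,
        )
        post = bayesian_posterior(sub, model)
        prof = posterior_profile(sub, model, grid_step=0.2, horizon=2.0)
        t_idx = 5
        preds = np.array(
            [
                predict_concentrations(
                    p.params, four_comp, sub.doses, [prof.times[t_idx]], PLASMA
                )[0]
                for p in pts
            ]
        )
        assert prof.channel(PLASMA)[t_idx] == pytest.approx(
            weighted_median(preds, post)
        )

    def test_bad_grid_rejected(self, medians, four_comp):
        sub = _noise_free_subject(medians, four_comp)
        model = PopulationModel(
            structure="four_compartment_lag",
            support_points=[SupportPoint(medians, 1.0)],
            error_model=default_error_model(),
            neg2ll=0.0,
            aic=0.0,
        )
        with pytest.raises(ValueError, match="multiple"):
            posterior_profile(sub, model, grid_step=0.7, horizon=24.0)


class TestPopulationDiagnostics:
    def _perfect_model(self, medians):
        return PopulationModel(
            structure="four_compartment_lag",
            support_points=[SupportPoint(medians, 1.0)],
            error_model=default_error_model(),
            neg2ll=0.0,
            aic=0.0,
        )

    def test_perfect_predictions(self, medians, four_comp):
        subs = [_noise_free_subject(medians, four_comp, f"T{i}") for i in range(3)]
        diag = population_diagnostics(self._perfect_model(medians), subs)
        for ch in (PLASMA, CSF):
            assert diag.channels[ch].bias == pytest.approx(0.0, abs=1e-9)
            assert diag.channels[ch].r2 == pytest.approx(1.0)

    def test_channel_separation(self, medians, four_comp):
        # permuting CSF values must not change plasma diagnostics
        subs = [_noise_free_subject(medians, four_comp, f"T{i}") for i in range(2)]
        base = population_diagnostics(self._perfect_model(medians), subs)
        permuted = []
        for s in subs:
            csf_obs = [o for o in s.observations if o.output == CSF]
            vals = [o.value for o in csf_obs][::-1]
            new_obs = [o for o in s.observations if o.output == PLASMA] + [
                Observation(o.time, v, CSF) for o, v in zip(csf_obs, vals)
            ]
            permuted.append(SubjectRecord(s.id, s.weight, list(s.doses), new_obs))
        perm = population_diagnostics(self._perfect_model(medians), permuted)
        assert perm.channels[PLASMA].bias == pytest.approx(
            base.channels[PLASMA].bias
        )
        assert perm.channels[PLASMA].r2 == pytest.approx(base.channels[PLASMA].r2)

    def test_model_json_round_trip(self, tmp_path, medians):
        model = self._perfect_model(medians)
        path = tmp_path / "fit.json"
        model.to_json(path)
        back = PopulationModel.from_json(path)
        assert back.structure == model.structure
        assert back.support_points[0].params == medians
        assert back.gamma == model.gamma
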