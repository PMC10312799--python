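import numpy as np
import pytest
from sklearn.base import clone

from bdscreen.dose_response import HillParams, SubpopulationParams
from bdscreen.estimators import SubpopulationDeconvolution
from bdscreen.inference import (
    TABLE4_BOUNDS,
    TABLE5_BOUNDS,
    bootstrap_cis,
    error_metric,
    fit,
    n_free_parameters,
    resolve_bounds,
    select_model,
)
from bdscreen.likelihoods import loglik_endpoints, loglik_livecell, loglik_phenopop
from bdscreen.moments import ModelParams, PhenoPopParams
from bdscreen.simulate import ExperimentDesign, simulate_dataset


@pytest.fixture(scope="module")
def growing_clone_data():
    """Small single-clone live-cell screen for cheap fit smoke tests."""
    params = ModelParams(
        (1.0,), (SubpopulationParams(0.6, 0.55, HillParams(0.85, 0.3, 2.5)),), 3.0
    )
    design = ExperimentDesign(
        times=(3.0, 6.0, 9.0, 12.0), doses=(0.0, 0.1, 0.3, 1.0), n_replicates=6,
        n_initial=400, assay="live_cell",
    )
    return params, simulate_dataset(params, design, 99)


class TestErrorMetric:
    def test_anchors(self):
        assert error_metric(2.0, 2.0) == 0.0
        assert error_metric(2.0, 1.0) == pytest.approx(np.log(2.0))
        assert error_metric(1.0, 2.0) == pytest.approx(np.log(2.0))

    def test_scale_invariance(self):
        assert error_metric(0.03, 0.07) == pytest.approx(error_metric(30.0, 70.0))

    @pytest.mark.parametrize("bad", [(0.0, 1.0), (1.0, 0.0), (-2.0, 1.0)])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            error_metric(*bad)


class TestBookkeeping:
    def test_free_parameter_counts(self):
        # birth-death: S-1 fractions + 5 per clone + noise; deterministic:
        # S-1 fractions + 4 per clone + two noise SDs
        assert n_free_parameters("live_cell", 2) == 12
        assert n_free_parameters("end_points", 3) == 18
        assert n_free_parameters("phenopop", 2) == 11

    def test_aic_arithmetic(self, growing_clone_data):
        _, data = growing_clone_data
        res = fit(data, method="end_points", S=1, n_restarts=2, rng=0)
        assert res.aic == pytest.approx(-2 * res.loglik + 2 * 6)
        assert res.bic == pytest.approx(
            -2 * res.loglik + 6 * np.log(np.prod(data.design.shape))
        )

    def test_bounds_presets(self):
        assert resolve_bounds("table4") is TABLE4_BOUNDS
        assert resolve_bounds("table5") is TABLE5_BOUNDS
        assert resolve_bounds(TABLE4_BOUNDS.with_overrides(c=(0, 1000))).c == (0, 1000)
        with pytest.raises(ValueError, match="preset"):
            resolve_bounds("table9")

    def test_method_data_mismatch(self, growing_clone_data, small_design, rng):
        params, _ = growing_clone_data
        ep_data = simulate_dataset(params, small_design("end_point"), rng)
        with pytest.raises(ValueError, match="live_cell"):
            fit(ep_data, method="live_cell", S=1, n_restarts=1, rng=0)
        with pytest.raises(ValueError, match="method"):
            fit(ep_data, method="bayesian", S=1, n_restarts=1, rng=0)


class TestLabelSymmetry:
    def test_likelihoods_invariant_under_clone_permutation(self, small_design, rng):
        params = ModelParams(
            (0.3, 0.7),
            (
                SubpopulationParams(0.5, 0.45, HillParams(0.85, 0.1, 3.0)),
                SubpopulationParams(0.3, 0.25, HillParams(0.8, 1.2, 2.0)),
            ),
            2.0,
        )
        flipped = ModelParams(
            params.fractions[::-1], params.subpops[::-1], params.noise_c
        )
        data = simulate_dataset(params, small_design("live_cell"), rng)
        assert loglik_livecell(params, data) == pytest.approx(
            loglik_livecell(flipped, data), rel=1e-12
        )
        assert loglik_endpoints(params, data) == pytest.approx(
            loglik_endpoints(flipped, data), rel=1e-12
        )
        pp = PhenoPopParams(
            fractions=(0.3, 0.7), alphas=(0.05, 0.02),
            hills=(HillParams(0.85, 0.1, 3.0), HillParams(0.8, 1.2, 2.0)),
            sigma_H=30.0, sigma_L=10.0, T_L=4.0, D_L=0.1,
        )
        pp_flipped = PhenoPopParams(
            fractions=(0.7, 0.3), alphas=(0.02, 0.05),
            hills=(HillParams(0.8, 1.2, 2.0), HillParams(0.85, 0.1, 3.0)),
            sigma_H=30.0, sigma_L=10.0, T_L=4.0, D_L=0.1,
        )
        assert loglik_phenopop(pp, data) == pytest.approx(
            loglik_phenopop(pp_flipped, data), rel=1e-12
        )

    def test_fit_reports_ascending_half_effect_dose(self, balanced_mixture):
        from bdscreen.simulate import default_design

        data = simulate_dataset(balanced_mixture, default_design("end_point"), 3)
        res = fit(data, method="phenopop", S=2, n_restarts=4, rng=1)
        es = [h.E for h in res.theta_hat.hills]
        assert es == sorted(es)


class TestFitBehaviour:
    def test_deterministic_given_seed(self, growing_clone_data):
        _, data = growing_clone_data
        a = fit(data, method="end_points", S=1, n_restarts=3, rng=7)
        b = fit(data, method="end_points", S=1, n_restarts=3, rng=7)
        assert a.loglik == b.loglik
        assert a.fractions == b.fractions

    def test_single_clone_recovery(self, growing_clone_data):
        """A one-clone fit lands near the generating growth and response."""
        params, data = growing_clone_data
        res = fit(data, method="live_cell", S=1, n_restarts=6, rng=0)
        sp_true, sp_hat = params.subpops[0], res.theta_hat.subpops[0]
        assert res.fractions == (1.0,)
        assert sp_hat.alpha == pytest.approx(sp_true.alpha, abs=0.02)
        assert error_metric(res.gr50[0], sp_true.gr50) < 0.35
        assert res.loglik >= loglik_livecell(params, data) - 1e-6

    def test_loglik_at_estimate_dominates_truth(self, growing_clone_data):
        params, data = growing_clone_data
        res = fit(data, method="end_points", S=1, n_restarts=6, rng=0)
        assert res.loglik >= loglik_endpoints(params, data) - 1e-6


class TestBootstrap:
    def test_single_replicate_collapses(self, growing_clone_data):
        _, data = growing_clone_data
        b = bootstrap_cis(
            data, method="end_points", S=1, n_boot=1, n_restarts=3,
            refit_restarts=1, rng=5,
        )
        assert b.n_boot == 1
        np.testing.assert_allclose(b.table["lower"], b.table["upper"])

    def test_interval_order_and_width(self, growing_clone_data):
        _, data = growing_clone_data
        b = bootstrap_cis(
            data, method="end_points", S=1, n_boot=8, n_restarts=3,
            refit_restarts=0, rng=5,
        )
        assert (b.table["lower"] <= b.table["upper"] + 1e-12).all()
        assert b.ci_width("p_1") == 0.0  # single clone: fraction pinned at 1
        assert b.ci_width("gr50_1") >= 0.0
        with pytest.raises(ValueError):
            bootstrap_cis(data, n_boot=0)


class TestModelSelection:
    def test_ranking_and_elbow_columns(self, growing_clone_data):
        _, data = growing_clone_data
        table = select_model(
            data, method="end_points", S_candidates=(1, 2), n_restarts=3, rng=2
        )
        assert set(table["S"]) == {1, 2}
        assert (table["aic"].diff().dropna() >= 0).all()  # sorted best-first
        np.testing.assert_allclose(table["neg_loglik"], -table["loglik"])

    def test_parsimony_on_homogeneous_data(self, growing_clone_data):
        """One true clone: S=1 beats S=2 by AIC (majority over seeds)."""
        _, data = growing_clone_data
        wins = 0
        for seed in range(3):
            table = select_model(
                data, method="end_points", S_candidates=(1, 2), n_restarts=4, rng=seed
            )
            wins += int(table["S"].iloc[0] == 1)
        assert wins >= 2

    def test_empty_candidates_rejected(self, growing_clone_data):
        _, data = growing_clone_data
        with pytest.raises(ValueError):
            select_model(data, S_candidates=())


class TestEstimatorFrontEnd:
    def test_sklearn_plumbing(self):
        est = SubpopulationDeconvolution(method="end_points", n_populations=1)
        params = est.get_params()
        assert params["method"] == "end_points"
        est2 = clone(est).set_params(n_restarts=5)
        assert est2.get_params()["n_restarts"] == 5

    def test_fit_sets_attributes_and_scores(self, growing_clone_data):
        params, data = growing_clone_data
        est = SubpopulationDeconvolution(
            method="live_cell", n_populations=1, n_restarts=4, random_state=0
        )
        est.fit(data)
        assert est.fractions_.shape == (1,)
        assert est.aic_ == pytest.approx(-2 * est.loglik_ + 2 * 6)
        assert est.score(data) == pytest.approx(est.loglik_)
        # predict returns the fitted mean surface; t=0 gives the seeding count
        frame = data.to_frame()
        pred = est.predict(frame[frame["time"] == 0.0])
        np.testing.assert_allclose(pred, data.design.n_initial)

    def test_fit_accepts_long_format_frame(self, growing_clone_data):
        _, data = growing_clone_data
        est = SubpopulationDeconvolution(
            method="end_points", n_populations=1, n_restarts=2, random_state=0
        )
        est.fit(data.to_frame())
        assert np.isfinite(est.loglik_)

    def test_rejects_other_inputs(self):
        with pytest.raises(TypeError):
            SubpopulationDeconvolution().fit(np.zeros((3, 3)))
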