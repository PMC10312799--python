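import numpy as np
import pytest

from bdscreen.dose_response import HillParams, SubpopulationParams
from bdscreen.moments import ModelParams, total_variance
from bdscreen.simulate import (
    ExperimentDesign,
    default_design,
    draw_parameters,
    largest_remainder_allocation,
    simulate_bd_counts,
    simulate_bd_path,
    simulate_bd_path_gillespie,
    simulate_dataset,
)


class TestBDPaths:
    def test_frozen_process_is_constant(self, rng):
        sp = SubpopulationParams(0.0, 0.0)
        path = simulate_bd_path(sp, 0.0, 123, [1.0, 2.0, 3.0], rng)
        np.testing.assert_array_equal(path, 123)

    def test_zero_start_is_absorbing(self, rng):
        sp = SubpopulationParams(0.9, 0.1)
        path = simulate_bd_path(sp, 0.0, 0, [1.0, 5.0], rng)
        np.testing.assert_array_equal(path, 0)

    def test_pure_death_decays(self, rng):
        sp = SubpopulationParams(0.0, 1.0)
        paths = simulate_bd_counts(sp, 0.0, 500, [1.0], rng, n_paths=4000)[:, 0]
        # survival probability e^{-t} per cell
        assert paths.mean() == pytest.approx(500 * np.exp(-1.0), rel=0.05)

    @pytest.mark.parametrize(
        "beta,nu", [(0.9058, 0.8101), (0.3, 0.3), (0.1, 0.4)]
    )
    def test_mean_and_variance_match_theory(self, beta, nu, rng):
        """Sample moments of 1e5 exact paths sit within 3 SE of the formulas."""
        sp = SubpopulationParams(beta, nu)
        n0, t = 1000, 1.0
        x = simulate_bd_counts(sp, 0.0, n0, [t], rng, n_paths=100_000)[:, 0]
        lam = beta - nu
        mean_th = n0 * np.exp(lam * t)
        var_th = n0 * total_variance(
            ModelParams((1.0,), (sp,), 0.0), [t], 0.0
        )[0]
        assert abs(x.mean() - mean_th) < 3 * np.sqrt(var_th / x.size)
        se_var = var_th * np.sqrt(2 / (x.size - 1)) * 2
        assert abs(x.var(ddof=1) - var_th) < 3 * se_var + 0.03 * var_th

    def test_exact_sampler_consistent_with_gillespie(self):
        """Interval sampling and event-by-event SSA give the same law.

        Checked with a two-sample energy-distance permutation test on the
        joint distribution over three observation times.
        """
        from bdscreen.diagnostics import empirical_energy_distance

        rng = np.random.default_rng(1)
        sp = SubpopulationParams(0.8, 0.6, HillParams(0.8, 0.5, 2.0))
        times = [0.5, 1.0, 2.0]
        n = 400
        a = simulate_bd_counts(sp, 0.3, 25, times, rng, n_paths=n).astype(float)
        b = np.array(
            [simulate_bd_path_gillespie(sp, 0.3, 25, times, rng) for _ in range(n)],
            dtype=float,
        )
        observed = empirical_energy_distance(a, b)
        pooled = np.vstack([a, b])
        null = []
        for _ in range(99):
            idx = rng.permutation(2 * n)
            null.append(
                empirical_energy_distance(pooled[idx[:n]], pooled[idx[n:]])
            )
        p_value = (1 + sum(x >= observed for x in null)) / 100
        assert p_value > 0.01


class TestDatasets:
    def test_deterministic_noise_free_dataset(self, rng):
        """beta = nu = 0 and no drug or noise: every count stays at n."""
        params = ModelParams(
            (0.5, 0.5), (SubpopulationParams(0, 0), SubpopulationParams(0, 0)), 0.0
        )
        design = ExperimentDesign(
            times=(2.0, 4.0, 6.0), doses=(0.0,), n_replicates=4, n_initial=200,
            assay="live_cell",
        )
        data = simulate_dataset(params, design, rng)
        np.testing.assert_allclose(data.counts, 200.0)

    def test_seed_reproducibility(self, balanced_mixture, small_design):
        a = simulate_dataset(balanced_mixture, small_design(), 42)
        b = simulate_dataset(balanced_mixture, small_design(), 42)
        np.testing.assert_array_equal(a.counts, b.counts)
        assert a.seed == 42

    def test_livecell_counts_are_time_correlated(self, rng):
        """Within-well lag-1 correlation is positive for growing live-cell data."""
        design = ExperimentDesign(
            times=(1.0, 2.0), doses=(0.0,), n_replicates=400, n_initial=300,
            assay="live_cell",
        )
        params = ModelParams((1.0,), (SubpopulationParams(0.9, 0.5),), 1.0)
        data = simulate_dataset(params, design, rng)
        corr = np.corrcoef(data.counts[0, 0, :], data.counts[1, 0, :])[0, 1]
        assert corr > 0.3

    def test_endpoint_counts_are_independent_across_time(self, rng):
        design = ExperimentDesign(
            times=(1.0, 2.0), doses=(0.0,), n_replicates=400, n_initial=300,
            assay="end_point",
        )
        params = ModelParams((1.0,), (SubpopulationParams(0.9, 0.5),), 1.0)
        data = simulate_dataset(params, design, rng)
        corr = np.corrcoef(data.counts[0, 0, :], data.counts[1, 0, :])[0, 1]
        assert abs(corr) < 0.15

    def test_dataset_moments_match_theory(self, rng):
        """Empirical mean/variance across many replicates track mu and
        n sigma^2 + c^2 at each (time, dose)."""
        from bdscreen.moments import mean_matrix, variance_matrix

        params = ModelParams(
            (0.6, 0.4),
            (
                SubpopulationParams(0.5, 0.45, HillParams(0.85, 0.2, 2.0)),
                SubpopulationParams(0.3, 0.28, HillParams(0.85, 2.0, 2.0)),
            ),
            5.0,
        )
        design = ExperimentDesign(
            times=(2.0, 6.0), doses=(0.0, 0.5), n_replicates=10_000, n_initial=500,
            assay="end_point",
        )
        data = simulate_dataset(params, design, rng)
        mu = mean_matrix(params, design.times, design.doses, 500)
        var = 500 * variance_matrix(params, design.times, design.doses) + 25.0
        emp_mean = data.counts.mean(axis=2)
        emp_var = data.counts.var(axis=2, ddof=1)
        assert np.all(np.abs(emp_mean - mu) < 3 * np.sqrt(var / 10_000))
        assert np.all(np.abs(emp_var - var) < 3 * var * np.sqrt(2 / 9999) * 2 + 0.03 * var)


class TestParameterDraws:
    def test_two_clone_ranges(self, rng):
        """1e4 draws stay inside the documented generation intervals."""
        draws = [draw_parameters(2, rng) for _ in range(10_000)]
        p_s = np.array([d.fractions[0] for d in draws])
        assert p_s.min() >= 0.3 and p_s.max() <= 0.5
        for d in draws[:200]:
            assert d.fractions[0] + d.fractions[1] == pytest.approx(1.0)
        for which, (lo, hi) in [(0, (0.05, 0.1)), (1, (0.75, 2.5))]:
            es = np.array([d.subpops[which].hill.E for d in draws])
            assert es.min() >= lo and es.max() <= hi
        for d in draws:
            for sp in d.subpops:
                assert 0.0 <= sp.beta <= 1.0
                assert 0.0 <= sp.nu <= sp.beta
                assert sp.beta - sp.nu <= 0.1 + 1e-12
                assert 0.8 <= sp.hill.b <= 0.9
                assert 1.5 <= sp.hill.m <= 5.0
            assert 0.0 <= d.noise_c <= 10.0

    def test_death_rate_truncation_at_zero(self, rng):
        """When beta < 0.1 the death-rate draw can clip to exactly 0."""
        draws = [draw_parameters(2, rng) for _ in range(3000)]
        nus = [sp.nu for d in draws for sp in d.subpops]
        assert min(nus) == 0.0

    def test_three_clone_overlay(self, rng):
        draws = [draw_parameters(3, rng) for _ in range(2000)]
        for d in draws:
            p_s, p_m, p_r = d.fractions
            assert 0.167 <= p_s <= 0.333 and 0.167 <= p_m <= 0.333
            assert p_r == pytest.approx(1 - p_s - p_m)
            assert p_r >= 0
            e = [sp.hill.E for sp in d.subpops]
            assert 0.0313 <= e[0] <= 0.0625
            assert 0.25 <= e[1] <= 0.375
            assert 1.25 <= e[2] <= 2.5

    def test_invalid_s_rejected(self, rng):
        with pytest.raises(ValueError):
            draw_parameters(4, rng)


class TestHelpers:
    @pytest.mark.parametrize(
        "n,fr", [(1000, (0.4856, 0.5144)), (7, (1 / 3, 1 / 3, 1 / 3)), (10, (0.99, 0.01))]
    )
    def test_largest_remainder_sums_to_n(self, n, fr):
        alloc = largest_remainder_allocation(n, fr)
        assert alloc.sum() == n
        assert np.all(alloc >= 0)
        assert np.all(np.abs(alloc - n * np.asarray(fr)) <= 1.0)

    def test_default_design_shape(self):
        d = default_design()
        assert len(d.times) == 13 and len(d.doses) == 11 and d.n_replicates == 14
        assert d.doses[0] == 0.0 and d.n_initial == 1000

    def test_design_validation(self):
        with pytest.raises(ValueError):
            ExperimentDesign((1.0,), (0.0,), 0, 100)
        with pytest.raises(ValueError):
            ExperimentDesign((1.0,), (-0.5,), 3, 100)
        with pytest.raises(ValueError):
            ExperimentDesign((1.0,), (0.0,), 3, 100, assay="imaging")
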