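"""MA statistics, random-sampling null moments and replicate calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dgescreen import rsm


class TestComputeMA:
    @pytest.mark.parametrize(
        "c1, c2, pc, exp_m, exp_a",
        [
            (100, 100, 1e-12, 0.0, np.log2(100)),
            (200, 100, 1e-12, 1.0, (np.log2(200) + np.log2(100)) / 2),
            (0, 16, 0.5, np.log2(0.5) - np.log2(16.5), (np.log2(0.5) + np.log2(16.5)) / 2),
        ],
    )
    def test_examples(self, c1, c2, pc, exp_m, exp_a):
        M, A = rsm.compute_ma(c1, c2, pseudocount=pc)
        assert M == pytest.approx(exp_m, abs=1e-9)
        assert A == pytest.approx(exp_a, abs=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            rsm.compute_ma(-1, 5)

    def test_vectorised(self):
        M, A = rsm.compute_ma([10, 20], [10, 5], pseudocount=1e-12)
        assert M == pytest.approx([0.0, 2.0], abs=1e-9)


class TestNullMoments:
    def test_symmetric_p_gives_zero_mean(self):
        assert rsm.rsm_null_moments(123, 0.5).muM == 0.0

    def test_four_to_one_split_gives_mean_two(self):
        assert rsm.rsm_null_moments(1000, 0.8).muM == pytest.approx(2.0)

    def test_variance_against_enumeration(self):
        nm = rsm.rsm_null_moments(400, 0.5)
        assert nm.varM == pytest.approx(0.0208, abs=2e-4)
        exact = rsm.rsm_null_moments_exact(400, 0.5)
        assert nm.varM == pytest.approx(exact.varM, rel=0.05)

    @pytest.mark.parametrize("K", [100, 400, 1000, 5000])
    @pytest.mark.parametrize("p0", [0.1, 0.3, 0.5, 0.8])
    def test_delta_method_grid(self, K, p0):
        """Delta-method moments track the exact binomial enumeration."""
        delta = rsm.rsm_null_moments(K, p0)
        exact = rsm.rsm_null_moments_exact(K, p0)
        assert delta.varM == pytest.approx(exact.varM, rel=0.05)
        assert delta.muM == pytest.approx(exact.muM, abs=0.05)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rsm.rsm_null_moments(0, 0.5)
        with pytest.raises(ValueError):
            rsm.rsm_null_moments(100, 1.0)


class TestRsmZscore:
    def test_equal_counts_equal_totals_is_zero(self):
        assert rsm.rsm_zscore(50, 50, 1000, 1000) == pytest.approx(0.0)

    def test_three_to_one_example(self):
        z = rsm.rsm_zscore(300, 100, 10_000, 10_000, pseudocount=1e-12)
        assert z == pytest.approx(np.log2(3) / np.sqrt(1 / (np.log(2) ** 2 * 100)), rel=1e-6)
        assert z == pytest.approx(11.0, abs=0.1)
        # default pseudocount barely moves it
        assert rsm.rsm_zscore(300, 100, 10_000, 10_000) == pytest.approx(11.0, abs=0.1)

    def test_zero_combined_count_is_nan(self):
        assert np.isnan(rsm.rsm_zscore(0, 0, 1000, 1000))

    @settings(derandomize=True, max_examples=200)
    @given(
        c1=st.integers(0, 10_000),
        c2=st.integers(0, 10_000),
        n1=st.integers(1, 10**7),
        n2=st.integers(1, 10**7),
    )
    def test_antisymmetry(self, c1, c2, n1, n2):
        """Swapping the samples negates both M and z."""
        M1, _ = rsm.compute_ma(c1, c2)
        M2, _ = rsm.compute_ma(c2, c1)
        assert M1 == pytest.approx(-M2, abs=1e-9)
        z1 = rsm.rsm_zscore(c1, c2, n1, n2)
        z2 = rsm.rsm_zscore(c2, c1, n2, n1)
        if c1 + c2 == 0:
            assert np.isnan(z1) and np.isnan(z2)
        else:
            assert z1 == pytest.approx(-z2, rel=1e-9, abs=1e-9)


class TestNoiseModel:
    def test_identical_replicates_hit_the_floor(self, rng):
        counts = rng.poisson(100, size=2000)
        model = rsm.fit_noise_model(counts, counts, window_size=100)
        assert np.all(model.mean_m == pytest.approx(0.0, abs=1e-12))
        assert np.all(model.sd_m == model.sd_floor)

    def test_poisson_sd_matches_delta_approximation(self, rng):
        lam = 100.0
        a = rng.poisson(lam, size=5000)
        b = rng.poisson(lam, size=5000)
        model = rsm.fit_noise_model(a, b)
        expected = np.sqrt(2 / (lam * np.log(2) ** 2))
        assert model.sd_at(np.log2(lam)) == pytest.approx(expected, rel=0.15)

    def test_overdispersion_raises_sd_above_poisson(self, rng):
        lam, disp, n = 100.0, 0.05, 5000
        pois_a, pois_b = rng.poisson(lam, n), rng.poisson(lam, n)
        nb_a = rng.poisson(rng.gamma(1 / disp, lam * disp, n))
        nb_b = rng.poisson(rng.gamma(1 / disp, lam * disp, n))
        m_pois = rsm.fit_noise_model(pois_a, pois_b)
        m_nb = rsm.fit_noise_model(nb_a, nb_b)
        grid = np.linspace(m_pois.a_grid[1], m_pois.a_grid[-2], 20)
        assert np.all(m_nb.sd_at(grid) > m_pois.sd_at(grid))

    def test_interpolation_reproduces_grid_points(self, rng):
        a = rng.poisson(80, size=3000)
        b = rng.poisson(80, size=3000)
        model = rsm.fit_noise_model(a, b, window_size=200)
        assert model.sd_at(model.a_grid) == pytest.approx(model.sd_m)
        assert model.mean_at(model.a_grid) == pytest.approx(model.mean_m)

    def test_clamped_outside_range(self, rng):
        a = rng.poisson(50, size=2000)
        model = rsm.fit_noise_model(a, rng.poisson(50, size=2000), window_size=200)
        assert model.sd_at(-100.0) == model.sd_m[0]
        assert model.sd_at(100.0) == model.sd_m[-1]

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            rsm.fit_noise_model(np.full(10, 100), np.full(10, 100), window_size=500)


class TestMatrZscore:
    def setup_method(self):
        self.model = rsm.NoiseModel(
            a_grid=np.array([2.0, 6.0, 10.0]),
            mean_m=np.array([0.0, 0.0, 0.0]),
            sd_m=np.array([0.4, 0.2, 0.2]),
        )

    def test_at_model_mean(self):
        assert rsm.matr_zscore(0.0, 6.0, self.model) == 0.0

    def test_direct_division(self):
        assert rsm.matr_zscore(1.0, 6.0, self.model) == pytest.approx(5.0)

    def test_strictly_increasing_in_m(self):
        ms = np.linspace(-3, 3, 50)
        zs = rsm.matr_zscore(ms, np.full(50, 6.0), self.model)
        assert np.all(np.diff(zs) > 0)


class TestTwoSidedP:
    @pytest.mark.parametrize(
        "z, p", [(0.0, 1.0), (1.96, 0.0500), (3.3, 9.67e-4), (-3.3, 9.67e-4)]
    )
    def test_normal_tail(self, z, p):
        assert rsm.two_sided_p(z) == pytest.approx(p, rel=1e-2)


class TestQQNormality:
    def test_exact_normal_quantiles_give_unit_correlation(self):
        q = stats.norm.ppf((np.arange(1, 101) - 0.5) / 100)
        pairs, r = rsm.qq_normality(q)
        assert r == pytest.approx(1.0, abs=1e-9)
        assert pairs.shape == (100, 2)

    def test_constant_vector_signalled(self):
        with pytest.raises(ValueError):
            rsm.qq_normality(np.ones(10))

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            rsm.qq_normality([1.0, 2.0])

    def test_simulated_log2_counts_near_normal(self, null_poisson_experiment):
        """log2 counts of a null library track the log2-normal baseline."""
        tables, _ = null_poisson_experiment
        counts = tables["uninjected_1"].column("uninjected_1")
        counts = counts[counts > 0][:10_000]
        _, r = rsm.qq_normality(np.log2(counts))
        assert r > 0.99


class TestNullCalibration:
    def test_matr_z_is_standard_normal_under_the_null(self, null_poisson_experiment):
        """Replicate-calibrated z on a matched null comparison is ~N(0,1)."""
        tables, _ = null_poisson_experiment
        model = rsm.fit_noise_model(
            tables["uninjected_1"].column("uninjected_1"),
            tables["uninjected_2"].column("uninjected_2"),
        )
        c1 = tables["wnt3_1"].column("wnt3_1").astype(float)
        c2 = tables["uninjected_1"].column("uninjected_1").astype(float)
        M, A = rsm.compute_ma(c1, c2)
        z = rsm.matr_zscore(M, A, model)
        z = z[(c1 + c2) >= rsm.LOW_COUNT_MIN_K]
        assert abs(z.mean()) < 0.05
        assert 0.85 < z.std() < 1.15
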