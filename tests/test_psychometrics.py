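"""Ordinal descriptives, polychoric correlation, one-factor fit, omega,
kappa, parallel analysis."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal
from statsmodels.stats.inter_rater import cohens_kappa as sm_cohens_kappa

from itemforge.psychometrics import (
    FactorModel,
    FrequencyTable,
    LikertMatrix,
    bivariate_normal_cdf,
    bootstrap_omega,
    cohens_kappa,
    fit_one_factor,
    likert_descriptives,
    omega_total,
    parallel_analysis,
    polychoric,
    polychoric_matrix,
)
from itemforge.synthetic import ResponseModelSpec, gen_likert


class TestDescriptives:
    def test_printed_frequency_row_openness(self):
        d = likert_descriptives((7, 13, 30, 71, 99))
        assert round(d["mean"], 2) == 4.10
        assert round(d["sd"], 2) == 1.05
        assert round(d["skewness"], 2) == -1.16
        assert round(d["kurtosis"], 2) == 0.76

    def test_printed_frequency_row_benevolence(self):
        d = likert_descriptives((2, 1, 21, 77, 119))
        assert round(d["mean"], 2) == 4.41
        assert round(d["sd"], 2) == 0.76

    def test_matches_direct_computation_on_expanded_vector(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 40, 5)
        x = np.repeat(np.arange(1, 6), counts).astype(float)
        d = likert_descriptives(tuple(int(c) for c in counts))
        n = x.size
        s = x.std(ddof=1)
        assert d["mean"] == pytest.approx(x.mean())
        assert d["sd"] == pytest.approx(s)
        assert d["skewness"] == pytest.approx(((x - x.mean()) ** 3).mean() / s**3)
        assert d["kurtosis"] == pytest.approx(
            ((x - x.mean()) ** 4).mean() / s**4 - 3
        )

    def test_degenerate_single_category(self):
        d = likert_descriptives((0, 0, 220, 0, 0))
        assert d["mean"] == 3.0 and d["sd"] == 0.0
        assert np.isnan(d["skewness"]) and np.isnan(d["kurtosis"])

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            FrequencyTable((0, 0, 0))


class TestBivariateNormalCdf:
    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 1.5, (15, 2))
        for rho in (-0.9, -0.3, 0.0, 0.5, 0.95):
            ref = multivariate_normal(cov=[[1, rho], [rho, 1]]).cdf(pts)
            mine = bivariate_normal_cdf(pts[:, 0], pts[:, 1], rho)
            assert np.allclose(mine, ref, atol=1e-8)

    def test_infinite_bounds(self):
        assert bivariate_normal_cdf(np.inf, np.inf, 0.5) == pytest.approx(1.0)
        assert bivariate_normal_cdf(-np.inf, 0.0, 0.5) == pytest.approx(0.0)


class TestPolychoric:
    def test_recovers_known_latent_correlation(self):
        # two items loading sqrt(.5) on one factor => latent corr .5
        spec = ResponseModelSpec(
            loadings=(np.sqrt(0.5), np.sqrt(0.5)), thresholds=((-0.5, 0.5),),
            n_respondents=5000, seed=42,
        )
        d = gen_likert(spec)
        rho, a, b, flag = polychoric(d.values[:, 0], d.values[:, 1], 3)
        assert rho == pytest.approx(0.5, abs=0.05)
        assert not flag
        # thresholds near the generating cut points
        assert np.allclose(a, [-0.5, 0.5], atol=0.06)

    def test_independent_ordinals_near_zero(self):
        spec = ResponseModelSpec(
            loadings=(0.0, 0.0), n_respondents=5000, seed=13
        )
        d = gen_likert(spec)
        rho, *_ = polychoric(d.values[:, 0], d.values[:, 1])
        assert abs(rho) < 0.05

    def test_perfect_concordance_hits_boundary(self):
        rng = np.random.default_rng(3)
        x = rng.integers(1, 6, 400)
        rho, _, _, flag = polychoric(x, x)
        assert rho >= 0.99 and flag

    def test_single_category_rejected(self):
        with pytest.raises(ValueError):
            polychoric(np.ones(100, dtype=int), np.arange(100) % 5 + 1)


class TestOneFactor:
    def test_exact_recovery_on_rank_one_plus_diagonal(self):
        lam = np.array([0.8, 0.7, 0.6, 0.5, 0.4])
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        m = fit_one_factor(R)
        assert np.allclose(m.loadings, lam, atol=1e-4)
        assert m.converged and not m.heywood

    def test_identity_matrix_gives_null_loadings(self):
        m = fit_one_factor(np.eye(5))
        assert np.all(np.abs(m.loadings) < 1e-3)

    def test_permutation_equivariance(self):
        lam = np.array([0.8, 0.3, 0.6, 0.45, 0.7])
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        perm = [4, 2, 0, 3, 1]
        m1 = fit_one_factor(R)
        m2 = fit_one_factor(R[np.ix_(perm, perm)])
        assert np.allclose(m2.loadings, m1.loadings[perm], atol=1e-6)

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            fit_one_factor(np.eye(2))

    def test_non_positive_definite_smoothed_and_flagged(self):
        R = np.array(
            [[1.0, 0.95, -0.9], [0.95, 1.0, 0.8], [-0.9, 0.8, 1.0]]
        )
        assert np.linalg.eigvalsh(R).min() < 0
        m = fit_one_factor(R)
        assert m.smoothed


class TestOmega:
    def test_hand_evaluated_formula(self):
        lam = np.full(5, 0.7)
        m = FactorModel(lam, 1 - lam**2, True, False)
        assert omega_total(m) == pytest.approx(12.25 / 14.80, abs=1e-4)

    def test_null_and_perfect_loadings(self):
        z = np.zeros(4)
        assert omega_total(FactorModel(z, 1 - z**2, True, False)) == 0.0
        o = np.ones(4)
        assert omega_total(FactorModel(o, 1 - o**2, True, False)) == 1.0

    def test_invariant_to_item_order_and_reflection(self):
        lam = np.array([0.7, 0.5, 0.6, 0.4])
        m = FactorModel(lam, 1 - lam**2, True, False)
        w = omega_total(m)
        perm = lam[[2, 0, 3, 1]]
        assert omega_total(FactorModel(perm, 1 - perm**2, True, False)) == pytest.approx(w)


class TestBootstrapOmega:
    @pytest.fixture(scope="class")
    def sample(self):
        return gen_likert(
            ResponseModelSpec(loadings=(0.7,) * 4, n_respondents=150, seed=2)
        )

    def test_same_seed_identical_estimates(self, sample):
        a = bootstrap_omega(sample, k_boot=100, seed=9)
        b = bootstrap_omega(sample, k_boot=100, seed=9)
        assert (a.omega, a.ci_low, a.ci_high) == (b.omega, b.ci_low, b.ci_high)

    def test_ci_brackets_point_estimate(self, sample):
        est = bootstrap_omega(sample, k_boot=100, seed=9)
        assert 0 <= est.ci_low <= est.omega <= est.ci_high <= 1
        assert est.n_nonconverged + len(range(est.k_boot)) >= est.k_boot

    def test_too_few_respondents_rejected(self):
        tiny = gen_likert(
            ResponseModelSpec(loadings=(0.7,) * 4, n_respondents=20, seed=2)
        )
        with pytest.raises(ValueError):
            bootstrap_omega(tiny, k_boot=100, seed=1)


class TestCohensKappa:
    def test_hand_computed_table(self):
        # p_o = 192/220, p_e = (85*83 + 135*137) / 220^2
        est = cohens_kappa(np.array([[70, 15], [13, 122]]))
        p_o = 192 / 220
        p_e = (85 * 83 + 135 * 137) / 220**2
        assert est.kappa == pytest.approx((p_o - p_e) / (1 - p_e))
        assert round(est.kappa, 2) == 0.73
        assert est.observed_agreement == pytest.approx(p_o)

    def test_matches_statsmodels_oracle(self):
        rng = np.random.default_rng(4)
        T = rng.integers(5, 60, (3, 3))
        mine = cohens_kappa(T)
        ref = sm_cohens_kappa(T)
        assert mine.kappa == pytest.approx(float(ref.kappa))
        assert mine.ci_low == pytest.approx(float(ref.kappa_low), abs=5e-3)
        assert mine.ci_high == pytest.approx(float(ref.kappa_upp), abs=5e-3)

    def test_perfect_agreement(self):
        est = cohens_kappa(np.diag([30, 40, 50]))
        assert est.kappa == pytest.approx(1.0)

    def test_independent_raters(self):
        p = np.array([0.3, 0.7])
        T = np.outer(p, p) * 1000
        assert cohens_kappa(T).kappa == pytest.approx(0.0, abs=1e-12)

    def test_ci_contains_kappa(self):
        est = cohens_kappa(np.array([[70, 15], [13, 122]]))
        assert est.ci_low <= est.kappa <= est.ci_high


class TestParallelAnalysis:
    def test_pure_noise_retains_nothing(self):
        # the 95th-percentile rule admits ~5% spurious retention per draw,
        # so check the property across draws rather than on a single one
        rng = np.random.default_rng(6)
        retained = [
            parallel_analysis(
                LikertMatrix(values=rng.integers(1, 6, (300, 10))),
                n_sims=60, seed=s,
            )
            for s in range(10)
        ]
        assert sum(k == 0 for k in retained) >= 8
        assert max(retained) <= 1

    def test_same_seed_same_result(self):
        d = gen_likert(
            ResponseModelSpec(loadings=(0.7,) * 6, n_respondents=200, seed=3)
        )
        assert parallel_analysis(d, n_sims=40, seed=5) == parallel_analysis(
            d, n_sims=40, seed=5
        )

    def test_one_factor_data_retains_one(self):
        d = gen_likert(
            ResponseModelSpec(loadings=(0.7,) * 8, n_respondents=400, seed=8)
        )
        assert parallel_analysis(d, n_sims=60, seed=2) == 1


class TestLikertMatrix:
    def test_listwise_deletion_counted(self):
        vals = np.array([[1, 2], [3, np.nan], [4, 5]])
        m = LikertMatrix(values=vals)
        assert m.n_respondents == 2 and m.n_listwise_dropped == 1

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            LikertMatrix(values=np.array([[0, 3]]))

    def test_reverse_scoring(self):
        m = LikertMatrix(
            values=np.array([[1, 5], [2, 4]]), keying=["+", "-"]
        )
        r = m.reverse_scored()
        assert np.array_equal(r.values[:, 1], [1, 2])
        assert np.array_equal(r.values[:, 0], m.values[:, 0])
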