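"""Sum-of-single-effects fine-mapping: closed forms, credible sets, grid
search, joint filter, and the sex-interaction test."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from cispqtl.assoc import marginal_scan
from cispqtl.finemap import (
    SusieFit,
    extract_credible_sets,
    joint_lead_test,
    select_L_grid,
    sex_interaction_test,
    single_effect_regression,
    susie_fit,
    variance_explained,
)
from cispqtl.simulate import SimTruth, simulate_genotypes, simulate_protein_trait


class TestSingleEffectRegression:
    def test_zero_prior_variance_gives_uniform_weights(self, rng):
        X = rng.standard_normal((50, 8))
        y = rng.standard_normal(50)
        alpha, mu, mu2, lbf = single_effect_regression(X, y, sigma2=1.0, prior_var=0.0)
        np.testing.assert_allclose(alpha, 1 / 8)
        np.testing.assert_allclose(lbf, 0.0)
        np.testing.assert_allclose(mu, 0.0)

    def test_identical_columns_share_weight(self, rng):
        x = rng.standard_normal(200)
        y = 0.5 * x + 0.1 * rng.standard_normal(200)
        X = np.column_stack([x, x, rng.standard_normal(200)])
        alpha, *_ = single_effect_regression(X, y, sigma2=1.0, prior_var=0.2)
        assert abs(alpha[0] - alpha[1]) < 1e-12
        assert alpha[0] > 0.45  # the duplicated causal dominates

    def test_single_variant_posterior_matches_hand_computation(self):
        # engineered sufficient statistics: bhat=0.3, s2=0.01, prior 0.04
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100)
        d = float(x @ x)
        y = 0.3 * x  # exact OLS estimate 0.3
        sigma2 = 0.01 * d  # so s2 = sigma2/d = 0.01
        alpha, mu, mu2, lbf = single_effect_regression(
            x[:, None], y, sigma2=sigma2, prior_var=0.04
        )
        np.testing.assert_allclose(alpha, [1.0])
        # hand: post_var = (1/0.04 + 1/0.01)^-1 = 0.008; mu = 0.008*0.3/0.01
        np.testing.assert_allclose(mu[0], 0.24, atol=1e-12)
        np.testing.assert_allclose(mu2[0], 0.008 + 0.24**2, atol=1e-12)

    def test_negative_prior_variance_rejected(self, rng):
        X = rng.standard_normal((20, 3))
        with pytest.raises(ValueError, match="non-negative"):
            single_effect_regression(X, rng.standard_normal(20), 1.0, -0.1)

    def test_brute_force_bayes_factor_oracle_small_m(self, rng):
        """For m<=3 and L=1 the weights equal direct two-Gaussian evaluation."""
        X = rng.standard_normal((60, 3))
        X = (X - X.mean(0)) / X.std(0)
        y = 0.4 * X[:, 1] + rng.standard_normal(60)
        y = y - y.mean()
        sigma2, V = 0.8, 0.3
        alpha, *_ = single_effect_regression(X, y, sigma2=sigma2, prior_var=V)
        # oracle: evaluate the two normal densities per variant directly
        bfs = []
        for j in range(3):
            d = X[:, j] @ X[:, j]
            bhat = (X[:, j] @ y) / d
            s2 = sigma2 / d
            bf = stats.norm.pdf(bhat, 0, np.sqrt(V + s2)) / stats.norm.pdf(
                bhat, 0, np.sqrt(s2)
            )
            bfs.append(bf)
        expected = np.array(bfs) / np.sum(bfs)
        np.testing.assert_allclose(alpha, expected, atol=1e-10)


class TestSusieFit:
    def test_elbo_non_decreasing(self, single_causal_region):
        G, y, _, _ = single_causal_region
        fit = susie_fit(G.dosages, y, L=5)
        diffs = np.diff(fit.elbo_trace)
        assert (diffs > -1e-6).all()

    def test_alpha_rows_sum_to_one(self, single_causal_region):
        G, y, _, _ = single_causal_region
        fit = susie_fit(G.dosages, y, L=5)
        np.testing.assert_allclose(fit.alpha.sum(axis=1), 1.0, atol=1e-8)
        assert fit.sigma2 > 0

    def test_strong_causal_concentrates_inclusion_weight(self):
        G = simulate_genotypes(1000, 100, rho=0.0, seed=41)
        truth = SimTruth({"p": [50]}, {"p": [1.0]}, {"p": 0.2})
        y, _ = simulate_protein_trait(G, truth, seed=42, trait="p")
        fit = susie_fit(G.dosages, y, L=3)
        assert fit.alpha[:, 50].max() > 0.95

    def test_null_trait_yields_no_credible_sets(self):
        none_count = 0
        reps = 20
        rng = np.random.default_rng(55)
        for rep in range(reps):
            G = simulate_genotypes(1000, 200, seed=600 + rep)
            y = rng.standard_normal(1000)
            fit = susie_fit(G.dosages, y, L=5)
            sets = extract_credible_sets(fit, G.dosages, allow_unconverged=True)
            none_count += len(sets) == 0
        assert none_count >= 0.9 * reps

    def test_pip_monotone_in_sample_size(self):
        """Median causal-variant PIP does not decrease as n grows."""
        medians = []
        for n in (500, 2000):
            pips = []
            for rep in range(15):
                G = simulate_genotypes(n, 100, seed=700 + rep)
                truth = SimTruth({"p": [40]}, {"p": [1.0]}, {"p": 0.08})
                y, _ = simulate_protein_trait(G, truth, seed=rep, trait="p")
                fit = susie_fit(G.dosages, y, L=3)
                pips.append(fit.pip[40])
            medians.append(np.median(pips))
        assert medians[1] >= medians[0] - 0.05


class TestExtractCredibleSets:
    def _fake_fit(self, alpha_row, m):
        L = 1
        alpha = np.array([alpha_row])
        return SusieFit(
            L=L, alpha=alpha, mu=np.ones((L, m)), mu2=np.ones((L, m)),
            lbf_variable=np.where(alpha > 1 / m, 1.0, -1.0),
            sigma2=1.0, prior_var=np.array([0.2]),
            elbo_trace=[0.0, 0.1], converged=True,
        )

    def test_dominant_variant_forms_singleton_set(self, rng):
        X = rng.standard_normal((100, 3))
        fit = self._fake_fit([0.97, 0.02, 0.01], 3)
        sets = extract_credible_sets(fit, X)
        assert len(sets) == 1
        assert sets[0].variant_indices == [0]
        assert abs(sets[0].attained_coverage - 0.97) < 1e-12
        assert sets[0].purity == 1.0

    def test_high_ld_pair_kept_with_purity(self, rng):
        x = rng.standard_normal(2000)
        v2 = 0.95 * x + np.sqrt(1 - 0.95**2) * rng.standard_normal(2000)
        X = np.column_stack([x, v2, rng.standard_normal(2000)])
        fit = self._fake_fit([0.50, 0.46, 0.04], 3)
        sets = extract_credible_sets(fit, X)
        assert len(sets) == 1
        assert sorted(sets[0].variant_indices) == [0, 1]
        assert sets[0].purity > 0.9

    def test_low_ld_pair_discarded_by_purity(self, rng):
        X = rng.standard_normal((2000, 3))  # mutually uncorrelated
        fit = self._fake_fit([0.50, 0.46, 0.04], 3)
        sets = extract_credible_sets(fit, X)
        assert sets == []

    def test_null_effect_skipped(self, rng):
        X = rng.standard_normal((50, 4))
        fit = self._fake_fit([0.25, 0.25, 0.25, 0.25], 4)
        fit.prior_var = np.array([0.0])
        assert extract_credible_sets(fit, X) == []


class TestSelectLGrid:
    def test_single_causal_returns_one_set(self):
        G = simulate_genotypes(1000, 200, seed=81)
        truth = SimTruth({"p": [100]}, {"p": [1.0]}, {"p": 0.15})
        y, _ = simulate_protein_trait(G, truth, seed=82, trait="p")
        fit, sets = select_L_grid(G.dosages, y)
        assert len(sets) == 1
        assert 100 in sets[0].variant_indices

    def test_two_isolated_causals_give_disjoint_low_ld_sets(self):
        G = simulate_genotypes(1500, 200, seed=83)
        truth = SimTruth({"p": [40, 160]}, {"p": [1.0, 1.0]}, {"p": 0.1})
        y, _ = simulate_protein_trait(G, truth, seed=84, trait="p")
        fit, sets = select_L_grid(G.dosages, y)
        assert len(sets) == 2
        members = [set(cs.variant_indices) for cs in sets]
        assert members[0].isdisjoint(members[1])
        Xs = (G.dosages - G.dosages.mean(0)) / G.dosages.std(0)
        cross = [
            abs(float(Xs[:, i] @ Xs[:, j]) / G.n)
            for i in members[0] for j in members[1]
        ]
        assert max(cross) ** 2 <= 0.1 + 1e-12

    def test_inadmissible_region_falls_back_to_l1(self):
        """Two strong causals in moderate LD (r^2 > 0.1) cannot be split
        into admissible sets, so the grid falls back to a single effect."""
        rng = np.random.default_rng(9)
        n = 3000
        a = rng.standard_normal(n)
        b = 0.55 * a + np.sqrt(1 - 0.55**2) * rng.standard_normal(n)
        X = np.column_stack([a, b, rng.standard_normal((n, 4))])
        y = 0.3 * a + 0.3 * b + rng.standard_normal(n)
        fit, sets = select_L_grid(X, y, grid=range(2, 5))
        if fit.L == 1:
            assert len(sets) >= 1
        else:
            # if some L was admissible its sets must obey the LD rule
            from cispqtl.finemap import sets_admissible

            assert sets_admissible(X, sets, 0.1)

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            select_L_grid(rng.standard_normal((50, 5)), rng.standard_normal(50), grid=[])


class TestJointLeadTest:
    def test_single_lead_matches_marginal_ols(self, single_causal_region):
        G, y, causal, _ = single_causal_region
        g = G.dosages[:, causal]
        joint = joint_lead_test(g[:, None], y)
        marg = sm.OLS(y, sm.add_constant(g)).fit()
        assert abs(joint.table["beta"].iloc[0] - marg.params[1]) < 1e-12
        assert abs(joint.table["p"].iloc[0] - marg.pvalues[1]) < 1e-12

    def test_null_lead_dropped_by_significance_filter(self):
        G = simulate_genotypes(1000, 50, rho=0.0, seed=91)
        truth = SimTruth({"p": [10]}, {"p": [1.0]}, {"p": 0.2})
        y, _ = simulate_protein_trait(G, truth, seed=92, trait="p")
        joint = joint_lead_test(G.dosages[:, [10, 40]], y, lead_indices=[10, 40])
        t = joint.table.set_index("lead_index")
        assert bool(t.loc[10, "retained"])
        assert not bool(t.loc[40, "retained"])

    def test_two_orthogonal_strong_leads_both_retained(self):
        G = simulate_genotypes(1500, 60, rho=0.0, seed=93)
        truth = SimTruth({"p": [10, 50]}, {"p": [1.0, 1.0]}, {"p": 0.25})
        y, _ = simulate_protein_trait(G, truth, seed=94, trait="p")
        joint = joint_lead_test(G.dosages[:, [10, 50]], y, lead_indices=[10, 50])
        assert joint.table["retained"].all()
        # betas within 3 se of the simulated per-allele effects
        for j, row in zip([10, 50], joint.table.itertuples(index=False)):
            sd_g = G.dosages[:, j].std()
            beta_true = np.sqrt(0.125) * y.std() / sd_g
            assert abs(row.beta - beta_true) < 3 * row.se

    def test_collinear_lead_dropped_with_warning(self, rng):
        g = rng.binomial(2, 0.3, 500).astype(float)
        X = np.column_stack([g, g])
        y = 0.5 * g + rng.standard_normal(500)
        with pytest.warns(UserWarning, match="dropped"):
            joint = joint_lead_test(X, y, lead_indices=[0, 1])
        assert joint.dropped == [1]

    def test_too_few_samples_rejected(self, rng):
        X = rng.standard_normal((4, 3))
        with pytest.raises(ValueError, match="too few"):
            joint_lead_test(X, rng.standard_normal(4))


class TestVarianceExplained:
    def test_exact_linear_function_gives_r2_one(self, rng):
        X = rng.standard_normal((100, 2))
        y = X @ np.array([1.0, -2.0]) + 3
        assert abs(variance_explained(X, y) - 1.0) < 1e-12

    def test_independent_leads_give_small_r2(self, rng):
        X = rng.standard_normal((1000, 5))
        y = rng.standard_normal(1000)
        assert variance_explained(X, y) < 0.03

    def test_single_causal_r2_matches_simulated_h2(self):
        G = simulate_genotypes(2000, 40, rho=0.0, seed=95)
        truth = SimTruth({"p": [20]}, {"p": [1.0]}, {"p": 0.3})
        y, _ = simulate_protein_trait(G, truth, seed=96, trait="p")
        assert abs(variance_explained(G.dosages[:, [20]], y) - 0.3) < 0.05


class TestSexInteraction:
    def test_single_sex_rejected(self, rng):
        g = rng.binomial(2, 0.3, 100).astype(float)
        with pytest.raises(ValueError, match="both sexes"):
            sex_interaction_test(g, rng.standard_normal(100), np.zeros(100))

    def test_differential_effect_detected(self, rng):
        n = 2000
        g = rng.binomial(2, 0.3, n).astype(float)
        sex = rng.integers(0, 2, n).astype(float)
        beta = np.where(sex == 1, 0.2, 0.7)  # women 0.2, men 0.7
        y = beta * g + rng.standard_normal(n)
        res = sex_interaction_test(g, y, sex)
        assert res["p_interaction"] < 0.05 / 1553
        assert abs(res["beta_by_sex"][1.0] - 0.2) < 0.15
        assert abs(res["beta_by_sex"][0.0] - 0.7) < 0.15

    def test_equal_effects_not_flagged(self, rng):
        n = 2000
        g = rng.binomial(2, 0.3, n).astype(float)
        sex = rng.integers(0, 2, n).astype(float)
        y = 0.4 * g + rng.standard_normal(n)
        res = sex_interaction_test(g, y, sex)
        assert res["p_interaction"] > 1e-4


def test_coverage_of_credible_sets_on_simulated_regions():
    """95% credible sets contain the true causal in nearly all regions
    (small-scale version of the calibration study)."""
    from cispqtl.evaluation import finemap_single_causal_study

    res = finemap_single_causal_study(n_regions=25, seed=2024)
    assert res["coverage_rate"] >= 0.85
    assert res["single_set_rate"] >= 0.8
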