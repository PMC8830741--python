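import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import clonemix as cm
from clonemix.em import (cell_log_likelihood, entry_log_prob, update_alpha,
                         update_beta, update_genotypes, update_pi)
from conftest import assert_monotone_trace, naive_total_loglik, random_gtm


class TestEntryLogProb:
    @pytest.mark.parametrize("d, c, expected", [
        (1, 0, math.log(0.01)),   # false positive: p(1|0) = alpha
        (0, 1, math.log(0.2)),    # false negative: p(0|1) = beta
        (1, 1, math.log(0.8)),
        (0, 0, math.log(0.99)),
    ])
    def test_error_model(self, d, c, expected):
        assert entry_log_prob(d, c, 0.01, 0.2) == pytest.approx(expected)

    def test_missing_contributes_factor_one(self):
        assert entry_log_prob(cm.MISSING, 1, 0.3, 0.4) == 0.0
        assert entry_log_prob(cm.MISSING, 0, 0.3, 0.4) == 0.0


class TestCellLogLikelihood:
    def test_hand_computed_product(self):
        got = cell_log_likelihood([1, 0], [1, 1], 0.01, 0.2)
        assert got == pytest.approx(math.log(0.8) + math.log(0.2))

    def test_all_missing_row_is_zero(self):
        assert cell_log_likelihood([cm.MISSING] * 3, [1, 0, 1], 0.1, 0.1) == 0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            cell_log_likelihood([1, 0], [1], 0.1, 0.1)


class TestTotalLogLikelihood:
    def test_single_component_is_row_sum(self, tiny_gtm):
        params = cm.MixtureParams(C=np.array([[1, 0, 1, 0]]), pi=[1.0],
                                  alpha=0.05, beta=0.2)
        expected = sum(
            cell_log_likelihood(tiny_gtm.values[i], params.C[0], 0.05, 0.2)
            for i in range(3))
        assert cm.total_log_likelihood(tiny_gtm, params) == pytest.approx(expected)

    def test_duplicating_a_cluster_preserves_value(self, tiny_gtm):
        one = cm.MixtureParams(C=np.array([[1, 0, 1, 0], [0, 1, 1, 0]]),
                               pi=[0.6, 0.4], alpha=0.05, beta=0.2)
        dup = cm.MixtureParams(
            C=np.array([[1, 0, 1, 0], [1, 0, 1, 0], [0, 1, 1, 0]]),
            pi=[0.3, 0.3, 0.4], alpha=0.05, beta=0.2)
        assert (cm.total_log_likelihood(tiny_gtm, one)
                == pytest.approx(cm.total_log_likelihood(tiny_gtm, dup)))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        g = random_gtm(rng, 3, 2)
        params = cm.MixtureParams(
            C=rng.integers(0, 2, size=(2, 2)), pi=[0.3, 0.7],
            alpha=0.02, beta=0.25)
        assert cm.total_log_likelihood(g, params) == pytest.approx(
            naive_total_loglik(g, params), abs=1e-10)


class TestEStep:
    def test_identical_components_give_pi(self, tiny_gtm):
        params = cm.MixtureParams(C=np.array([[1, 0, 1, 0]] * 2),
                                  pi=[0.7, 0.3], alpha=0.05, beta=0.2)
        gamma = cm.e_step(tiny_gtm, params)
        np.testing.assert_allclose(gamma, np.tile([0.7, 0.3], (3, 1)))

    def test_single_component_gives_ones(self, tiny_gtm):
        params = cm.MixtureParams(C=np.array([[0, 0, 0, 0]]), pi=[1.0],
                                  alpha=0.05, beta=0.2)
        np.testing.assert_allclose(cm.e_step(tiny_gtm, params), 1.0)

    def test_matches_direct_bayes_arithmetic(self):
        g = cm.GenotypeMatrix(np.array([[1, 0], [0, 1]]))
        params = cm.MixtureParams(C=np.array([[1, 1], [0, 0]]),
                                  pi=[0.5, 0.5], alpha=0.1, beta=0.2)
        gamma = cm.e_step(g, params)
        # cell 0 = (1,0): p(.|C1)=0.8*0.2, p(.|C2)=0.1*0.9
        w1, w2 = 0.5 * 0.8 * 0.2, 0.5 * 0.1 * 0.9
        assert gamma[0, 0] == pytest.approx(w1 / (w1 + w2))
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0)


class TestMStepUpdates:
    def test_unanimous_evidence_sets_mutation(self):
        g = cm.GenotypeMatrix(np.ones((4, 2), dtype=int))
        gamma = np.ones((4, 1))
        C = update_genotypes(g, gamma, alpha=0.05, beta=0.2)
        assert C.tolist() == [[1, 1]]

    def test_exact_tie_breaks_to_zero(self):
        # a fully-missing column gives both states objective 0
        g = cm.GenotypeMatrix(np.array([[1, cm.MISSING], [1, cm.MISSING]]))
        C = update_genotypes(g, np.ones((2, 1)), alpha=0.05, beta=0.2)
        assert C[0, 1] == 0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_per_state_exhaustive_objective(self, seed):
        rng = np.random.default_rng(seed)
        g = random_gtm(rng, 4, 3)
        gamma = rng.dirichlet([1, 1], size=4)
        alpha, beta = 0.03, 0.3
        C = update_genotypes(g, gamma, alpha, beta)
        for k in range(2):
            for j in range(3):
                scores = []
                for s in (0, 1):
                    tot = sum(
                        gamma[i, k] * entry_log_prob(
                            int(g.values[i, j]), s, alpha, beta)
                        for i in range(4))
                    scores.append(tot)
                best = 1 if scores[1] > scores[0] else 0
                assert C[k, j] == best

    def test_pi_from_hard_cluster_sizes(self):
        gamma = np.zeros((4, 2))
        gamma[:3, 0] = 1
        gamma[3, 1] = 1
        np.testing.assert_allclose(update_pi(gamma), [0.75, 0.25])

    def test_pi_normalised_for_soft_gamma(self, rng):
        gamma = rng.dirichlet([1, 2, 3], size=10)
        assert update_pi(gamma).sum() == pytest.approx(1.0)

    def test_beta_counts_false_negatives(self):
        # single all-ones cluster; 10 observed entries, 3 of them zero
        vals = np.ones((2, 6), dtype=int)
        vals[0, :3] = 0
        vals[0, 5] = cm.MISSING
        vals[1, 5] = cm.MISSING
        g = cm.GenotypeMatrix(vals)
        beta = update_beta(g, np.ones((2, 1)), np.ones((1, 6)))
        assert beta == pytest.approx(0.3)

    def test_beta_clamps_at_floor_on_clean_data(self):
        g = cm.GenotypeMatrix(np.ones((3, 4), dtype=int))
        beta = update_beta(g, np.ones((3, 1)), np.ones((1, 4)))
        assert beta == pytest.approx(1e-6)

    def test_beta_degenerate_keeps_previous_and_warns(self):
        g = cm.GenotypeMatrix(np.ones((2, 2), dtype=int))
        with pytest.warns(RuntimeWarning):
            beta = update_beta(g, np.ones((2, 1)), np.zeros((1, 2)),
                               prev_beta=0.37)
        assert beta == 0.37

    def test_alpha_counts_false_positives(self):
        # all-zero genotypes, 20 observed entries, exactly one 1
        vals = np.zeros((4, 5), dtype=int)
        vals[0, 0] = 1
        g = cm.GenotypeMatrix(vals)
        alpha = update_alpha(g, np.ones((4, 1)), np.zeros((1, 5)))
        assert alpha == pytest.approx(0.05)

    def test_alpha_degenerate_keeps_previous(self):
        g = cm.GenotypeMatrix(np.ones((2, 2), dtype=int))
        with pytest.warns(RuntimeWarning):
            alpha = update_alpha(g, np.ones((2, 1)), np.ones((1, 2)),
                                 prev_alpha=0.017)
        assert alpha == 0.017


class TestInitParams:
    def test_uniform_weights_and_default_alpha(self, rng):
        g = random_gtm(rng, 10, 4)
        params = cm.init_params(g, 4, beta0=0.3, rng=rng)
        np.testing.assert_allclose(params.pi, 0.25)
        assert params.alpha == pytest.approx(0.01)
        assert params.beta == pytest.approx(0.3)

    def test_genotypes_sampled_from_cells_without_missing(self, rng):
        g = random_gtm(rng, 8, 5, p_missing=0.4)
        params = cm.init_params(g, 3, beta0=0.2, rng=rng)
        assert np.isin(params.C, (0, 1)).all()

    def test_deterministic_under_seed(self, rng):
        g = random_gtm(rng, 10, 4)
        a = cm.init_params(g, 3, 0.2, rng=np.random.default_rng(5))
        b = cm.init_params(g, 3, 0.2, rng=np.random.default_rng(5))
        np.testing.assert_array_equal(a.C, b.C)

    def test_k_larger_than_n_rejected(self, rng):
        g = random_gtm(rng, 3, 4)
        with pytest.raises(ValueError):
            cm.init_params(g, 4, 0.2, rng=rng)


class TestFitEM:
    def test_noise_free_three_clusters_recovered_exactly(self):
        truth = cm.simulate_dataset(cm.SimConfig(
            N=60, M=30, K=3, alpha=0, beta=0, eta=0, rho=0, seed=2))
        g = truth.gtm()
        fit = cm.fit_em(g, 3, cm.EMConfig(n_restarts=5),
                        np.random.default_rng(0))
        assert cm.v_measure(truth.cell_clone, fit.assignments) == pytest.approx(1.0)
        np.testing.assert_array_equal(fit.Z, truth.Z_star)

    def test_result_contract(self, rng):
        g = random_gtm(rng, 20, 8)
        fit = cm.fit_em(g, 3, cm.EMConfig(n_restarts=3), rng)
        np.testing.assert_allclose(fit.gamma.sum(axis=1), 1.0, atol=1e-8)
        np.testing.assert_array_equal(fit.assignments,
                                      np.argmax(fit.gamma, axis=1))
        np.testing.assert_array_equal(fit.Z, fit.params.C[fit.assignments])
        assert_monotone_trace(fit)

    def test_fixed_rates_are_honoured(self, rng):
        g = random_gtm(rng, 15, 6)
        fit = cm.fit_em(g, 2, cm.EMConfig(fixed_alpha=0.03, fixed_beta=0.25,
                                          n_restarts=2), rng)
        assert fit.params.alpha == pytest.approx(0.03)
        assert fit.params.beta == pytest.approx(0.25)

    def test_alpha_pinned_at_alpha0_unless_estimated(self, rng):
        g = random_gtm(rng, 15, 6)
        pinned = cm.fit_em(g, 2, cm.EMConfig(n_restarts=2),
                           np.random.default_rng(1))
        assert pinned.params.alpha == pytest.approx(0.01)
        free = cm.fit_em(g, 2, cm.EMConfig(n_restarts=2, estimate_alpha=True),
                         np.random.default_rng(1))
        assert free.params.alpha != pytest.approx(0.01)

    def test_label_permutation_leaves_likelihood_unchanged(self, rng):
        g = random_gtm(rng, 12, 5)
        fit = cm.fit_em(g, 3, cm.EMConfig(n_restarts=2), rng)
        p = fit.params
        perm = [2, 0, 1]
        permuted = cm.MixtureParams(C=p.C[perm], pi=p.pi[perm],
                                    alpha=p.alpha, beta=p.beta)
        assert cm.total_log_likelihood(g, permuted) == pytest.approx(
            cm.total_log_likelihood(g, p))

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10 ** 6), k=st.integers(1, 3))
    def test_monotone_likelihood_property(self, seed, k):
        rng = np.random.default_rng(seed)
        g = random_gtm(rng, int(rng.integers(4, 12)), int(rng.integers(2, 6)))
        fit = cm.fit_em(g, min(k, g.n_cells),
                        cm.EMConfig(n_restarts=2), rng)
        assert_monotone_trace(fit)
        np.testing.assert_allclose(fit.gamma.sum(axis=1), 1.0, atol=1e-8)

    def test_beta_recovery_on_simulated_data(self):
        hits = 0
        for seed in range(10):
            truth = cm.simulate_dataset(cm.SimConfig(
                N=200, M=100, K=5, rho=0.0, seed=seed))
            fit = cm.fit_em(truth.gtm(), 5, cm.EMConfig(),
                            np.random.default_rng(seed))
            rep = cm.evaluate(truth.cell_clone, fit.assignments, fit.Z,
                              truth.Z_star, [])
            if abs(fit.params.beta - 0.2) <= 0.05 and rep.v_measure >= 0.95:
                hits += 1
        assert hits >= 9
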