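import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kstest

from mcgfinder import (
    GeneNetwork,
    aggregate,
    analyze,
    bh_fdr,
    generate,
    monte_carlo_pvalues,
    network_influenced_matrix,
    null_moments,
    semi_exact_pvalues,
    update_gene_scores,
)
from mcgfinder.synthetic import background_scenario, default_scenario

from _oracles import enumerate_null_scores


class TestNetworkInfluencedMatrix:
    def test_unregularized_is_scaled_copy(self):
        X = np.array([[1.0, 0.0], [1.0, 1.0], [0.0, 0.0]])
        s = np.array([1, 1, 0])
        Xnet = network_influenced_matrix(X, s, None, 0.0)
        assert np.allclose(Xnet, X / 2.0)

    def test_zero_row_stays_zero(self, path_network):
        X = np.array([[1.0, 0.0], [0.0, 0.0]])
        Xnet = network_influenced_matrix(X, np.ones(2), path_network.L, 0.4)
        assert np.allclose(Xnet[1], 0)

    def test_row_sums_reproduce_gene_scores(self, path_network):
        # the defining identity g = Xnet^T s against the direct solve
        X = np.array([[1.0, 0.0], [1.0, 0.0]])
        s = np.ones(2)
        g = update_gene_scores(X, s, path_network.L, 0.1)
        Xnet = network_influenced_matrix(X, s, path_network.L, 0.1)
        assert np.allclose(Xnet.T @ s, g, atol=1e-10)

    def test_empty_indicator_rejected(self, path_network):
        with pytest.raises(ValueError, match="active sample"):
            network_influenced_matrix(np.zeros((2, 2)), np.zeros(2), path_network.L, 0.1)


class TestNullMoments:
    def test_single_two_entry_row_enumerated(self):
        a, b = 0.7, 0.1
        mu, sigma2 = null_moments(np.array([[a, b]]), np.array([1]))
        assert np.allclose(mu, (a + b) / 2)
        assert np.allclose(sigma2, (a - b) ** 2 / 4)

    def test_constant_rows_are_degenerate(self):
        Xnet = np.array([[0.3, 0.3, 0.3], [0.5, 0.5, 0.5]])
        mu, sigma2 = null_moments(Xnet, np.array([1, 1]))
        assert np.allclose(mu, 0.8) and np.allclose(sigma2, 0)

    def test_matches_exhaustive_permutation_enumeration(self):
        rng = np.random.default_rng(0)
        rows = rng.random((2, 3))
        nulls = enumerate_null_scores(rows)  # all (3!)^2 combinations
        mu, sigma2 = null_moments(rows, np.array([1, 1]))
        assert np.allclose(mu, nulls.mean(axis=0), atol=1e-12)
        assert np.allclose(sigma2, nulls.var(axis=0), atol=1e-12)

    def test_inactive_rows_do_not_contribute(self):
        rows = np.array([[1.0, 0.0], [100.0, 100.0]])
        mu, _ = null_moments(rows, np.array([1, 0]))
        assert np.allclose(mu, 0.5)


class TestSemiExactPvalues:
    def test_center_and_three_sigma_tail(self):
        mu = np.array([1.0, 1.0])
        sigma2 = np.array([0.25, 0.25])
        p = semi_exact_pvalues(np.array([1.0, 1.0 + 3 * 0.5]), mu, sigma2)
        assert p[0] == pytest.approx(0.5, abs=1e-12)
        assert p[1] == pytest.approx(0.0013499, abs=1e-6)

    def test_degenerate_null(self):
        mu = np.zeros(2)
        sigma2 = np.zeros(2)
        p = semi_exact_pvalues(np.array([0.0, 0.5]), mu, sigma2)
        assert p.tolist() == [1.0, 0.0]

    def test_close_to_monte_carlo_on_random_fixture(self):
        rng = np.random.default_rng(1)
        Xnet = rng.random((20, 15))
        s = np.ones(20)
        scores = Xnet.T @ s
        mu, sigma2 = null_moments(Xnet, s)
        p_se = semi_exact_pvalues(scores, mu, sigma2)
        p_mc = monte_carlo_pvalues(Xnet, s, scores, n_perm=20_000, seed=2)
        assert np.abs(p_se - p_mc).max() <= 0.02


class TestMonteCarloPvalues:
    def test_add_one_floor_when_score_dominates(self):
        Xnet = np.array([[0.5, 0.1], [0.4, 0.2]])
        p = monte_carlo_pvalues(Xnet, np.ones(2), np.array([10.0, 10.0]), n_perm=99, seed=0)
        assert np.allclose(p, 1 / 100)

    def test_constant_rows_give_floor_above_and_one_at(self):
        Xnet = np.array([[0.2, 0.2], [0.2, 0.2]])
        p = monte_carlo_pvalues(Xnet, np.ones(2), np.array([0.4, 0.5]), n_perm=49, seed=0)
        assert p[0] == 1.0  # null equals the score, >= counts everything
        assert p[1] == pytest.approx(1 / 50)

    def test_clt_regime_matches_gaussian(self):
        rng = np.random.default_rng(3)
        Xnet = rng.random((50, 10))
        s = np.ones(50)
        scores = Xnet.T @ s + 2.0
        mu, sigma2 = null_moments(Xnet, s)
        p_se = semi_exact_pvalues(scores, mu, sigma2)
        p_mc = monte_carlo_pvalues(Xnet, s, scores, n_perm=100_000, seed=4)
        assert np.abs(p_se - p_mc).max() <= 0.01

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(5)
        Xnet = rng.random((5, 6))
        args = (Xnet, np.ones(5), Xnet.sum(axis=0))
        p1 = monte_carlo_pvalues(*args, n_perm=500, seed=7)
        p2 = monte_carlo_pvalues(*args, n_perm=500, seed=7)
        assert np.array_equal(p1, p2)


class TestBHFdr:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_fdr(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03])

    def test_all_ones_stay_one(self):
        assert np.allclose(bh_fdr(np.ones(4)), 1.0)

    def test_single_pvalue_unchanged(self):
        assert np.allclose(bh_fdr(np.array([0.04])), [0.04])

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20), st.integers(0, 2**30))
    def test_permutation_equivariance_and_monotonicity(self, pvals, seed):
        p = np.array(pvals)
        q = bh_fdr(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0 + 1e-12).all()
        perm = np.random.default_rng(seed).permutation(len(p))
        assert np.allclose(bh_fdr(p[perm]), q[perm])
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestAggregate:
    @staticmethod
    def table(records):
        return pd.DataFrame(
            records,
            columns=["gene", "component", "score", "null_mean", "null_sd", "p_value", "q_value"],
        )

    def test_min_q_picks_most_significant_component(self):
        df = self.table(
            [("GA", 1, 1.0, 0, 1, 0.15, 0.2), ("GA", 2, 2.0, 0, 1, 0.005, 0.01)]
        )
        sig = aggregate(df)
        row = sig.per_gene.iloc[0]
        assert row["min_q"] == 0.01 and row["component"] == 2 and row["candidate"]

    def test_tied_q_goes_to_smallest_component_index(self):
        df = self.table(
            [("GA", 2, 1.0, 0, 1, 0.01, 0.01), ("GA", 1, 1.0, 0, 1, 0.01, 0.01)]
        )
        assert aggregate(df).per_gene.iloc[0]["component"] == 1

    def test_threshold_is_strict(self):
        df = self.table([("GA", 1, 1.0, 0, 1, 0.05, 0.05)])
        assert not aggregate(df, q_threshold=0.05).per_gene.iloc[0]["candidate"]


class TestPipelineSignificance:
    def test_identity_holds_for_every_fitted_component(self):
        mm, edges, _ = generate(default_scenario(seed=11))
        sig, result, _ = analyze(mm, edges, seed=11)
        net = GeneNetwork.from_edges(edges, mm.genes)
        row_of = {sid: i for i, sid in enumerate(mm.samples)}
        for comp in result.components:
            X_sub = mm.X[[row_of[sid] for sid in comp.sample_ids]].astype(float)
            Xnet = network_influenced_matrix(X_sub, comp.s, net.L, 0.1)
            assert np.allclose(Xnet.T @ comp.s, comp.g, atol=1e-8)

    def test_null_pvalues_near_uniform_in_large_sample_regime(self):
        mm, edges, _ = generate(background_scenario(n=1000, p=200, seed=3))
        sig, result, _ = analyze(mm, edges, seed=3)
        first = sig.per_component
        pvals = first[first["component"] == 1]["p_value"].to_numpy()
        assert kstest(pvals, "uniform").statistic < 0.1

    def test_planted_genes_reach_significance(self):
        mm, edges, truth = generate(default_scenario(seed=12))
        sig, _, _ = analyze(mm, edges, seed=12)
        planted = set(truth.gene_sets[0])
        called = set(sig.candidates)
        assert len(called & planted) >= 8

    def test_modes_agree_on_well_separated_genes(self):
        """Both estimators call the same genes when p-values are far from
        the q-threshold margin: planted genes (extreme tail) in, clearly
        null genes (p > 0.2 in every component) out."""
        mm, edges, truth = generate(default_scenario(seed=13))
        sig_se, _, _ = analyze(mm, edges, significance_mode="semi_exact", seed=13)
        sig_mc, _, _ = analyze(
            mm, edges, significance_mode="monte_carlo", n_perm=2000, seed=13
        )
        planted = set(truth.gene_sets[0])
        se_p = sig_se.per_gene.set_index("gene")["p_value"]
        strong = {g for g in planted if se_p[g] < 1e-6}
        assert strong  # the planted block must produce extreme scores
        assert strong <= set(sig_se.candidates)
        assert strong <= set(sig_mc.candidates)
        clear_null = set(
            sig_se.per_component.groupby("gene")["p_value"].min().pipe(
                lambda s: s[s > 0.2].index
            )
        )
        assert clear_null.isdisjoint(sig_se.candidates)
        assert clear_null.isdisjoint(sig_mc.candidates)
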