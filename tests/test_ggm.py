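"""GGM structure learning: score, sampler, exhaustive oracle, averaging."""

import numpy as np
import pytest

from ggmnet import (
    GGMConfig,
    MPLScorer,
    average_over_repetitions,
    birth_death_sample,
    edge_probabilities,
    exhaustive_posterior,
    fit_constrained_precision,
    fit_ggm,
    mpl_log_score,
    select_graph,
)
from ggmnet.exceptions import DataError, EmptyChainError, SchemaError
from ggmnet.ggm import BDChain, GGMResult

from conftest import single_group_spec


def _chain_adj(P):
    adj = np.zeros((P, P), dtype=int)
    for i in range(P - 1):
        adj[i, i + 1] = adj[i + 1, i] = 1
    return adj


@pytest.fixture(scope="module")
def independent_data():
    rng = np.random.default_rng(123)
    return rng.standard_normal((500, 3))


class TestScore:
    def test_empty_graph_beats_spurious_edge_on_independent_data(self, independent_data):
        empty = np.zeros((3, 3), dtype=int)
        one_edge = empty.copy()
        one_edge[0, 1] = one_edge[1, 0] = 1
        assert mpl_log_score(independent_data, empty) > mpl_log_score(independent_data, one_edge)

    def test_score_is_deterministic(self, independent_data):
        adj = _chain_adj(3)
        assert mpl_log_score(independent_data, adj) == mpl_log_score(independent_data, adj)

    def test_chain_graph_beats_chain_plus_extra_edge(self, chain3):
        """On 3-node chain data the true chain scores above the graph with the
        superfluous (1,3) edge: pseudo-likelihood selection consistency."""
        _, _, data = chain3
        chain = _chain_adj(3)
        extra = chain.copy()
        extra[0, 2] = extra[2, 0] = 1
        assert mpl_log_score(data.values, chain) > mpl_log_score(data.values, extra)

    def test_edge_prior_shifts_score_by_log_odds(self, chain3):
        _, _, data = chain3
        chain = _chain_adj(3)
        s_half = mpl_log_score(data.values, chain, edge_prior=0.5)
        s_sparse = mpl_log_score(data.values, chain, edge_prior=0.2)
        assert s_half - s_sparse == pytest.approx(-2 * np.log(0.2 / 0.8), rel=1e-12)


class TestExhaustivePosterior:
    def test_single_edge_improbable_for_independent_columns(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((2000, 2))
        incl = exhaustive_posterior(data)
        assert incl[0, 1] < 0.5

    def test_chain_edges_dominate_shortcut(self, chain3):
        _, _, data = chain3
        incl = exhaustive_posterior(data.values)
        assert incl[0, 1] > incl[0, 2]
        assert incl[1, 2] > incl[0, 2]

    def test_size_limit(self):
        rng = np.random.default_rng(0)
        with pytest.raises(DataError):
            exhaustive_posterior(rng.standard_normal((50, 6)))


class TestSampler:
    def test_occupancies_match_exhaustive_on_chain(self, chain3):
        """Time-weighted occupancies agree with the 8-graph exact posterior:
        strong chain edges near 1, the shortcut below 0.5."""
        _, _, data = chain3
        exact = exhaustive_posterior(data.values)
        chain = birth_death_sample(data.values, GGMConfig(n_burnin=3000, n_sample=8000, seed=4))
        p_avg = edge_probabilities(chain)
        assert np.abs(p_avg - exact).max() < 0.05
        assert p_avg[0, 1] > 0.9 and p_avg[1, 2] > 0.9
        assert p_avg[0, 2] < 0.5

    def test_seeded_chains_identical(self, chain3):
        _, _, data = chain3
        cfg = GGMConfig(n_burnin=500, n_sample=1000, seed=9)
        a = birth_death_sample(data.values, cfg)
        b = birth_death_sample(data.values, cfg)
        assert np.array_equal(a.occupancy, b.occupancy)
        assert a.total_time == b.total_time
        assert np.array_equal(a.final_adjacency, b.final_adjacency)

    def test_pure_noise_keeps_all_edges_below_threshold(self):
        rng = np.random.default_rng(77)
        data = rng.standard_normal((1000, 5))
        chain = birth_death_sample(data, GGMConfig(n_burnin=3000, n_sample=8000, seed=1))
        p_avg = edge_probabilities(chain)
        assert p_avg.max() < 0.5

    def test_occupancy_agrees_with_exact_posterior_p4(self):
        """Detailed-balance surrogate at P=4: sampler vs 64-graph enumeration."""
        spec = single_group_spec(n_regions=4, group_sizes=(300,), rho_intra=0.45, seed=21)
        from ggmnet import simulate_cohort

        data = simulate_cohort(spec).values
        exact = exhaustive_posterior(data)
        chain = birth_death_sample(data, GGMConfig(n_burnin=4000, n_sample=12000, seed=3))
        assert np.abs(edge_probabilities(chain) - exact).max() < 0.05

    def test_too_few_rows_rejected(self):
        with pytest.raises(DataError):
            birth_death_sample(np.zeros((3, 4)), GGMConfig(n_burnin=10, n_sample=10))


class TestEdgeProbabilities:
    def test_always_present_edge_has_probability_one(self):
        occ = np.zeros((2, 2))
        occ[0, 1] = occ[1, 0] = 5.0
        chain = BDChain(
            occupancy=occ, total_time=5.0, n_jumps=10, n_births=5, n_deaths=5,
            final_adjacency=np.array([[0, 1], [1, 0]]), node_names=["a", "b"],
        )
        p = edge_probabilities(chain)
        assert p[0, 1] == 1.0

    def test_never_present_edge_has_probability_zero(self):
        chain = BDChain(
            occupancy=np.zeros((2, 2)), total_time=5.0, n_jumps=10, n_births=5,
            n_deaths=5, final_adjacency=np.zeros((2, 2), int), node_names=["a", "b"],
        )
        assert edge_probabilities(chain)[0, 1] == 0.0

    def test_empty_chain_raises(self):
        chain = BDChain(
            occupancy=np.zeros((2, 2)), total_time=0.0, n_jumps=0, n_births=0,
            n_deaths=0, final_adjacency=np.zeros((2, 2), int), node_names=["a", "b"],
        )
        with pytest.raises(EmptyChainError):
            edge_probabilities(chain)


class TestSelectGraph:
    def test_threshold_is_strict(self):
        p = np.array([[0.0, 0.5], [0.5, 0.0]])
        assert select_graph(p, 0.5).sum() == 0

    def test_zero_probabilities_give_empty_graph(self):
        assert select_graph(np.zeros((4, 4))).sum() == 0

    def test_tiny_threshold_includes_all_positive(self):
        p = np.full((3, 3), 0.01)
        np.fill_diagonal(p, 0)
        adj = select_graph(p, 1e-9)
        assert adj.sum() == 6  # all 3 undirected edges, symmetric count


class TestAveraging:
    @staticmethod
    def _result(ep_value, P=3):
        ep = np.full((P, P), ep_value)
        np.fill_diagonal(ep, 0)
        adj = select_graph(ep)
        pc = adj * 0.3
        return GGMResult(
            node_names=[f"v{i}" for i in range(P)],
            edge_prob=ep, adjacency=adj, partial_corr=pc,
        )

    def test_single_repetition_is_identity(self):
        res = self._result(0.8)
        avg = average_over_repetitions([res])
        assert np.array_equal(avg.edge_prob, res.edge_prob)
        assert np.array_equal(avg.adjacency, res.adjacency)
        assert np.array_equal(avg.partial_corr, res.partial_corr)

    def test_mean_crosses_threshold(self):
        avg = average_over_repetitions([self._result(0.4), self._result(0.8)])
        assert np.allclose(avg.edge_prob[0, 1], 0.6)
        assert avg.adjacency[0, 1] == 1

    def test_partial_corr_masked_to_selected_graph(self):
        avg = average_over_repetitions([self._result(0.2), self._result(0.6)])
        assert avg.adjacency.sum() == 0
        assert np.all(avg.partial_corr == 0)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(SchemaError):
            average_over_repetitions([self._result(0.5, P=3), self._result(0.5, P=4)])

    def test_averaging_reduces_across_seed_variance(self):
        """The averaged edge-probability matrix varies less across seeds than
        single repetitions do (checked on data with mid-range posterior
        probabilities, where chain noise is largest)."""
        from ggmnet import simulate_cohort

        spec = single_group_spec(group_sizes=(120,), rho_intra=0.3, seed=5)
        data = simulate_cohort(spec).values
        cfg = dict(n_burnin=500, n_sample=1500)
        iu = np.triu_indices(3, 1)
        singles, averaged = [], []
        for outer in range(3):
            eps = []
            for inner in range(4):
                chain = birth_death_sample(
                    data, GGMConfig(seed=outer * 10 + inner, **cfg)
                )
                eps.append(edge_probabilities(chain)[iu])
            singles.extend(eps)
            averaged.append(np.mean(eps, axis=0))
        var_single = np.var(np.array(singles), axis=0).sum()
        var_avg = np.var(np.array(averaged), axis=0).sum()
        assert var_avg < var_single


class TestFitGGM:
    def test_fit_ggm_on_chain_selects_chain(self, chain3):
        _, truth, data = chain3
        res = fit_ggm(data.values, GGMConfig(n_burnin=1000, n_sample=3000, n_repetitions=3, seed=2))
        assert np.array_equal(res.adjacency, truth.adjacency)
        # partial correlations recovered with the right sign
        assert res.partial_corr[0, 1] > 0.4
        assert res.partial_corr[0, 2] == 0.0
        assert len(res.per_repetition) == 3

    def test_partial_corr_pattern_within_adjacency(self, multimodal_ggm):
        res = multimodal_ggm
        assert np.all((res.partial_corr != 0) <= res.adjacency.astype(bool))
        assert np.allclose(res.partial_corr, res.partial_corr.T)
        off = ~np.eye(res.n_nodes, dtype=bool)
        assert np.abs(res.partial_corr[off]).max() < 1.0
        assert res.edge_prob.min() >= 0 and res.edge_prob.max() <= 1
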