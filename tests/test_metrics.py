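"""Weighted graph metrics against brute-force and closed-form oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from ggmnet import (
    CohortSpec,
    GGMConfig,
    clustering,
    fit_ggm,
    metrics_table,
    modality_block_metrics,
    path_length,
    simulate_cohort,
    small_world,
    to_distance,
)
from ggmnet.exceptions import DomainError, SchemaError
from ggmnet.ggm import GGMResult

from conftest import random_weighted_graph


# --------------------------------------------------------------- oracles
def brute_force_shortest(omega: np.ndarray) -> np.ndarray:
    """Exhaustive simple-path enumeration (feasible for <= 8 nodes)."""
    P = omega.shape[0]
    dist = np.full((P, P), np.inf)
    np.fill_diagonal(dist, 0.0)
    nodes = range(P)
    for i, j in itertools.combinations(nodes, 2):
        best = np.inf
        inner = [k for k in nodes if k not in (i, j)]
        for r in range(len(inner) + 1):
            for mid in itertools.permutations(inner, r):
                path = (i, *mid, j)
                length = 0.0
                for a, b in zip(path[:-1], path[1:]):
                    length += omega[a, b]
                    if not np.isfinite(length):
                        break
                best = min(best, length)
        dist[i, j] = dist[j, i] = best
    return dist


def brute_force_clustering(theta: np.ndarray, adj: np.ndarray) -> np.ndarray:
    w = np.abs(theta) * adj
    wmax = w.max()
    P = theta.shape[0]
    C = np.zeros(P)
    if wmax == 0:
        return C
    wn = w / wmax
    for i in range(P):
        k = adj[i].sum()
        if k < 2:
            continue
        t = 0.0
        for j in range(P):
            for h in range(P):
                if len({i, j, h}) == 3 and adj[i, j] and adj[i, h] and adj[j, h]:
                    t += (wn[i, j] * wn[i, h] * wn[j, h]) ** (1.0 / 3.0)
        C[i] = t / (k * (k - 1))
    return C


# ----------------------------------------------------------------- tests
class TestDistance:
    def test_unit_theta_gives_zero_distance(self):
        theta = np.array([[0.0, 1.0], [1.0, 0.0]])
        omega = to_distance(theta)
        assert omega[0, 1] == 0.0

    def test_absolute_value_taken(self):
        theta = np.array([[0.0, -0.5], [-0.5, 0.0]])
        assert to_distance(theta)[0, 1] == 0.5

    def test_non_edges_unreachable_not_distance_one(self):
        theta = np.zeros((3, 3))
        theta[0, 1] = theta[1, 0] = 0.4
        omega = to_distance(theta)
        assert omega[0, 2] == np.inf
        L = path_length(omega)
        assert np.isnan(L[2])  # isolated node flagged, not given distance 1

    def test_out_of_range_theta_rejected(self):
        with pytest.raises(DomainError):
            to_distance(np.array([[0.0, 1.5], [1.5, 0.0]]))


class TestPathLength:
    def test_equal_triangle(self):
        theta = np.full((3, 3), 0.5)
        np.fill_diagonal(theta, 0)
        L = path_length(to_distance(theta))
        assert np.allclose(L, 0.5)

    def test_three_node_path_hand_enumeration(self):
        """Distances 0.2 and 0.3 on a path: middle node L = 0.25, the 0.2-end
        node L = (0.2 + 0.5) / 2 = 0.35."""
        theta = np.zeros((3, 3))
        theta[0, 1] = theta[1, 0] = 0.8  # distance 0.2
        theta[1, 2] = theta[2, 1] = 0.7  # distance 0.3
        L = path_length(to_distance(theta))
        assert L[1] == pytest.approx(0.25)
        assert L[0] == pytest.approx(0.35)
        assert L[2] == pytest.approx((0.3 + 0.5) / 2)

    def test_matches_exhaustive_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            theta, adj = random_weighted_graph(rng, rng.integers(4, 9))
            omega = to_distance(theta, adj)
            from scipy.sparse.csgraph import csgraph_from_dense, dijkstra

            d = dijkstra(csgraph_from_dense(omega, null_value=np.inf), directed=False)
            assert np.allclose(d, brute_force_shortest(omega))

    def test_adding_edge_never_increases_path_length(self):
        rng = np.random.default_rng(11)
        theta, adj = random_weighted_graph(rng, 7, p_edge=0.4)
        absent = [(i, j) for i in range(7) for j in range(i + 1, 7) if not adj[i, j]]
        if not absent:
            pytest.skip("dense draw")
        L_before = path_length(to_distance(theta, adj))
        i, j = absent[0]
        adj2, theta2 = adj.copy(), theta.copy()
        adj2[i, j] = adj2[j, i] = 1
        theta2[i, j] = theta2[j, i] = 0.5
        L_after = path_length(to_distance(theta2, adj2))
        both = np.isfinite(L_before) & np.isfinite(L_after)
        assert np.all(L_after[both] <= L_before[both] + 1e-12)

    def test_negative_weight_rejected(self):
        omega = np.array([[0.0, -0.1], [-0.1, 0.0]])
        with pytest.raises(DomainError):
            path_length(omega)


class TestClustering:
    def test_equal_triangle_is_fully_clustered(self):
        theta = np.full((3, 3), 0.4)
        np.fill_diagonal(theta, 0)
        assert np.allclose(clustering(theta), 1.0)

    def test_degree_one_node_zero(self):
        theta = np.zeros((3, 3))
        theta[0, 1] = theta[1, 0] = 0.5
        assert clustering(theta)[0] == 0.0

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            theta, adj = random_weighted_graph(rng, rng.integers(4, 9))
            assert np.allclose(clustering(theta, adj), brute_force_clustering(theta, adj))

    def test_matches_networkx_onnela(self):
        rng = np.random.default_rng(13)
        theta, adj = random_weighted_graph(rng, 8)
        G = nx.Graph()
        G.add_nodes_from(range(8))
        for i in range(8):
            for j in range(i + 1, 8):
                if adj[i, j]:
                    G.add_edge(i, j, weight=abs(theta[i, j]))
        ref = np.array([nx.clustering(G, weight="weight")[i] for i in range(8)])
        assert np.allclose(clustering(theta, adj), ref)

    def test_invariant_to_uniform_rescaling(self):
        rng = np.random.default_rng(14)
        theta, adj = random_weighted_graph(rng, 6)
        assert np.allclose(clustering(theta, adj), clustering(0.3 * theta, adj))


class TestSmallWorld:
    def test_ratio(self):
        assert small_world(np.array([0.5]), np.array([0.5]))[0] == 1.0

    def test_zero_clustering_gives_zero(self):
        assert small_world(np.array([0.0]), np.array([0.7]))[0] == 0.0

    def test_equal_triangle_closed_form(self):
        """Equal-weight triangle: C = 1, L = 1 - rho, so S = 1 / (1 - rho)."""
        rho = 0.6
        theta = np.full((3, 3), rho)
        np.fill_diagonal(theta, 0)
        C = clustering(theta)
        L = path_length(to_distance(theta))
        S = small_world(C, L)
        assert np.allclose(C, 1.0)
        assert np.allclose(L, 1 - rho)
        assert np.allclose(S, 1 / (1 - rho))

    def test_undefined_path_length_propagates(self):
        S = small_world(np.array([0.2]), np.array([np.nan]))
        assert np.isnan(S[0])


class TestModalityBlocks:
    @staticmethod
    def _result_from_theta(theta, names):
        adj = (theta != 0).astype(int)
        np.fill_diagonal(adj, 0)
        return GGMResult(node_names=names, edge_prob=adj * 0.9, adjacency=adj, partial_corr=theta)

    def test_partition_into_per_modality_tables(self, multimodal_cohort, multimodal_ggm):
        spec, _, _ = multimodal_cohort
        for modality in spec.modality_names:
            table = modality_block_metrics(multimodal_ggm, modality)
            assert len(table) == spec.n_regions
            assert set(table["modality"]) == {modality}

    def test_unknown_modality_raises(self, multimodal_ggm):
        with pytest.raises(SchemaError):
            modality_block_metrics(multimodal_ggm, "tau")

    def test_block_diagonal_theta_blocks_equal_full_graph(self):
        """Without inter-modal edges the block sub-graph metrics equal the
        full-graph metrics of those nodes."""
        rng = np.random.default_rng(15)
        block, _ = random_weighted_graph(rng, 4, p_edge=0.8)
        theta = np.zeros((8, 8))
        theta[:4, :4] = block
        names = [f"roi{i}_amy" for i in range(4)] + [f"roi{i}_vol" for i in range(4)]
        res = self._result_from_theta(theta, names)
        table = modality_block_metrics(res, "amy")
        adj = (block != 0).astype(int)
        full_L = path_length(to_distance(theta))[:4]
        assert np.allclose(table["clustering"], clustering(block, adj))
        both = np.isfinite(full_L)
        assert np.allclose(table["path_length"][both], full_L[both])

    def test_metrics_table_is_tidy_across_groups(self, multimodal_ggm):
        table = metrics_table({"CN": multimodal_ggm, "AD": multimodal_ggm}, ["amy", "vol"])
        assert set(table["group"]) == {"CN", "AD"}
        assert {"group", "modality", "region", "degree", "clustering",
                "path_length", "small_world", "reachable_count"} <= set(table.columns)


class TestBiphasicConstruction:
    def test_emci_like_group_shows_higher_clustering(self):
        """A group that gains triangle-closing dependencies (simultaneous
        accumulation across neighbouring regions) shows a higher median
        clustering coefficient than controls, and its stronger edges shorten
        weighted paths — the early-MCI limb of the biphasic trajectory."""
        spec = CohortSpec(
            group_names=("CN", "EMCI"), group_sizes=(400, 400), n_regions=12,
            modality_names=("amy", "metab"), cluster_sizes=(6, 6),
            rho_intra=0.25, rho_intra2=0.18, rho_intermodal=0.18,
            group_rho_scale={"CN": 1.0, "EMCI": 1.25},
            group_rho2_scale={"CN": 0.0, "EMCI": 1.0},
            noise_scale=1.0, seed=0,
        )
        data = simulate_cohort(spec)
        cfg = GGMConfig(n_burnin=2000, n_sample=4000, n_repetitions=2, seed=1)
        results = {
            g: fit_ggm(data.subset(g).values, cfg) for g in ("CN", "EMCI")
        }
        table = metrics_table(results, ["amy"])
        med = table.groupby("group")["clustering"].median()
        assert med["EMCI"] > med["CN"]
        med_L = table.groupby("group")["path_length"].median()
        assert med_L["EMCI"] < med_L["CN"]
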