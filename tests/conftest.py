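"""Shared fixtures: small synthetic cohorts reused across test modules."""

import numpy as np
import pytest

from ggmnet import CohortSpec, GGMConfig, build_precision, fit_ggm, simulate_cohort


def single_group_spec(**overrides) -> CohortSpec:
    """One-group cohort spec with unit noise and no covariate effects."""
    base = dict(
        group_names=("CN",),
        group_sizes=(500,),
        n_regions=3,
        modality_names=("amy",),
        cluster_sizes=None,
        rho_intra=0.6,
        rho_intermodal=0.0,
        group_rho_scale={"CN": 1.0},
        covariate_effects={"amy": {}},
        noise_scale=1.0,
        seed=0,
    )
    base.update(overrides)
    if base["cluster_sizes"] is None:
        base["cluster_sizes"] = (base["n_regions"],)
    return CohortSpec(**base)


@pytest.fixture(scope="session")
def chain3():
    """3-node chain (rho=0.6), n=500: truth and simulated values."""
    spec = single_group_spec()
    truth = build_precision(spec, "CN")
    data = simulate_cohort(spec, {"CN": truth})
    return spec, truth, data


@pytest.fixture(scope="session")
def multimodal_cohort():
    """P=30 (10 regions x amy/metab/vol), n=700, chain + inter-modal truth."""
    spec = CohortSpec(
        group_names=("CN",),
        group_sizes=(700,),
        n_regions=10,
        modality_names=("amy", "metab", "vol"),
        cluster_sizes=(5, 5),
        rho_intra=0.3,
        rho_intermodal=0.21,
        group_rho_scale={"CN": 1.0},
        noise_scale=1.0,
        seed=0,
    )
    truth = build_precision(spec, "CN")
    data = simulate_cohort(spec, {"CN": truth})
    return spec, truth, data


@pytest.fixture(scope="session")
def multimodal_ggm(multimodal_cohort):
    """Averaged GGM estimate on the P=30 cohort (shared across tests)."""
    _, _, data = multimodal_cohort
    config = GGMConfig(n_burnin=5000, n_sample=10000, n_repetitions=5, seed=0)
    return fit_ggm(data.values, config)


def random_weighted_graph(rng: np.random.Generator, n_nodes: int, p_edge: float = 0.5):
    """Random symmetric theta with |theta| in (0.1, 0.9) and its adjacency."""
    adj = np.zeros((n_nodes, n_nodes), dtype=int)
    theta = np.zeros((n_nodes, n_nodes))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                adj[i, j] = adj[j, i] = 1
                val = rng.uniform(0.1, 0.9) * rng.choice([-1.0, 1.0])
                theta[i, j] = theta[j, i] = val
    return theta, adj
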