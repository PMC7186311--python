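"""Bayesian GGM structure learning and its exact small-problem oracle.

On a 4-node chain, compares birth-death sampler edge probabilities with the
exact posterior from enumerating all 64 graphs, then recovers the structure
of a larger multimodal cohort and scores it against the generator's truth.
"""

import numpy as np

from ggmnet import (
    CohortSpec,
    GGMConfig,
    build_precision,
    exhaustive_posterior,
    fit_ggm,
    simulate_cohort,
)

# --- exact check at P=4 ----------------------------------------------------
small = CohortSpec(
    group_names=("CN",), group_sizes=(200,), n_regions=4,
    modality_names=("amy",), cluster_sizes=(4,), rho_intra=0.45,
    rho_intermodal=0.0, group_rho_scale={"CN": 1.0},
    covariate_effects={"amy": {}}, noise_scale=1.0, seed=0,
)
data4 = simulate_cohort(small).values
exact = exhaustive_posterior(data4)
result4 = fit_ggm(data4, GGMConfig(n_burnin=3000, n_sample=8000, n_repetitions=4, seed=1))
print("P=4 chain: max |sampler - exact posterior| =",
      f"{np.abs(result4.edge_prob - exact).max():.4f}")

# --- structure recovery at P=30 -------------------------------------------
spec = CohortSpec(
    group_names=("CN",), group_sizes=(700,), n_regions=10,
    modality_names=("amy", "metab", "vol"), cluster_sizes=(5, 5),
    rho_intra=0.3, rho_intermodal=0.21, group_rho_scale={"CN": 1.0},
    noise_scale=1.0, seed=0,
)
truth = build_precision(spec, "CN")
data = simulate_cohort(spec, {"CN": truth})
result = fit_ggm(data.values, GGMConfig(n_burnin=3000, n_sample=6000, n_repetitions=3, seed=2))

iu = np.triu_indices(result.n_nodes, 1)
true_e = truth.adjacency[iu].astype(bool)
sel = result.adjacency[iu].astype(bool)
tp = (sel & true_e).sum()
print(f"P=30, n=700: selected {sel.sum()} edges ({result.density:.1%} density), "
      f"{true_e.sum()} true")
print(f"edge precision {tp / sel.sum():.2f}, recall {tp / true_e.sum():.2f}")
inter = [result.partial_corr[spec.node_index(r, 0), spec.node_index(r, 1)]
         for r in range(spec.n_regions)]
print(f"mean fitted amy-metab partial correlation: {np.mean(inter):.3f} (true 0.21)")
# The sampler's time-weighted edge probabilities track the exact posterior;
# on realistic sizes the selected graph recovers the true conditional
# dependencies, including the inter-modal amyloid-metabolism coupling.
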