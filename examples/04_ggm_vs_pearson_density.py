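"""Sparsity of conditional-dependency graphs vs Pearson covariance networks.

Marginal correlations propagate along chains of conditional dependencies, so
Bonferroni-thresholded Pearson networks stay dense while the GGM keeps only
direct dependencies.
"""

from ggmnet import CohortSpec, GGMConfig, fit_ggm, pearson_network, simulate_cohort

spec = CohortSpec(
    group_names=("CN",), group_sizes=(700,), n_regions=10,
    modality_names=("amy", "metab", "vol"), cluster_sizes=(5, 5),
    rho_intra=0.3, rho_intermodal=0.21, group_rho_scale={"CN": 1.0},
    noise_scale=1.0, seed=0,
)
data = simulate_cohort(spec)

ggm = fit_ggm(data.values, GGMConfig(n_burnin=3000, n_sample=6000, n_repetitions=3, seed=0))
pearson = pearson_network(data.values, alpha=0.05, correction="bonferroni")

print(f"GGM selected graph:      {ggm.n_edges:4d} edges  ({ggm.density:.1%} density)")
print(f"Pearson (Bonferroni):    {pearson.n_edges:4d} edges  ({pearson.density:.1%} density)")
print("The conditional-dependency graph is the sparser description of the")
print("same data: shared variance along chains never becomes an edge.")
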