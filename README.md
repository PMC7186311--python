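# ggmnet

Conditional-dependency networks of multimodal regional brain measures.

Regional imaging markers of Alzheimer's disease — amyloid-β load (AV45-PET),
glucose metabolism (FDG-PET) and gray matter volume (MRI), summarized per
atlas region — are strongly multicollinear: Pearson correlation matrices
between dozens of such variables are dominated by shared variance and stay
dense even after Bonferroni thresholding.  `ggmnet` instead estimates the
**Gaussian graphical model (GGM)** of the data: the sparse graph whose edges
are the non-zero entries of the precision matrix, i.e. the *partial*
correlations $\theta_{ij} = -K_{ij}/\sqrt{K_{ii}K_{jj}}$ that remain after
conditioning on all other regions and modalities.

The package covers the full analysis chain for a cohort study:

1. **W-score normalization** — per-node control-group regressions on age,
   gender and education; $W = (x - e)/s_{\mathrm{res}}$, so control scores
   have mean 0, SD 1, and ±1.645 mark the 5th/95th percentiles;
2. **Bayesian GGM structure learning** — a continuous-time birth–death
   sampler over graph space scored by a closed-form marginal
   pseudo-likelihood; posterior edge probabilities $P_{avg}$ are
   waiting-time-weighted occupancies averaged over repeated chains, edges are
   kept where $P_{avg} > 0.5$, and partial correlations are fitted on the
   selected graph by covariance selection;
3. **Pearson baseline networks** — all-pairs correlations with
   Bonferroni-corrected significance, for the density contrast;
4. **Weighted graph metrics** — distances $\Omega = 1-|\Theta|$,
   characteristic path length $L_i$, Onnela clustering $C_i$, small-world
   ratio $S_i = C_i/L_i$, per diagnostic group and modality block;
5. **Group comparison** — one-way ANOVA (regions as observations) with
   Tukey HSD post-hoc pairs.

A synthetic-cohort generator with known ground-truth networks (group-specific
sparse precision matrices, covariate effects, CN/EMCI/LMCI/AD group sizes
254/309/220/189) makes every stage testable end to end without any data
download.  See `docs/methods.md` for model details and assumptions.

## Worked example

Recover a known multimodal network (10 regions × 3 modalities, n = 700,
intra-modal chains at ρ = 0.3, intra-regional amyloid–metabolism edges at
ρ = 0.21):

```python
import numpy as np
from ggmnet import CohortSpec, GGMConfig, build_precision, fit_ggm, simulate_cohort

spec = CohortSpec(
    group_names=("CN",), group_sizes=(700,), n_regions=10,
    modality_names=("amy", "metab", "vol"), cluster_sizes=(5, 5),
    rho_intra=0.3, rho_intermodal=0.21, group_rho_scale={"CN": 1.0},
    noise_scale=1.0, seed=0,
)
truth = build_precision(spec, "CN")
data = simulate_cohort(spec, {"CN": truth})
result = fit_ggm(data.values, GGMConfig(n_burnin=3000, n_sample=6000,
                                        n_repetitions=3, seed=2))
```

Running `python examples/03_ggm_structure_learning.py` (which adds an exact
4-node check) prints:

```
P=4 chain: max |sampler - exact posterior| = 0.0001
P=30, n=700: selected 38 edges (8.7% density), 34 true
edge precision 0.89, recall 1.00
mean fitted amy-metab partial correlation: 0.215 (true 0.21)
```

The sampler's edge probabilities match the exhaustively enumerated posterior
to 1e-4; the selected graph recovers every true conditional dependency at
~9% density, and the fitted inter-modal partial correlations reproduce the
generating value 0.21.  `examples/04_ggm_vs_pearson_density.py` shows the
contrast with the Pearson baseline on the same cohort (9.2% vs 14.3%
density); the other examples walk through normalization, metrics, group
comparison and the full pipeline.

## Command line

Each pipeline stage is also a subcommand:

```bash
ggmnet all --config config.yaml --outdir run1 --seed 7        # full pipeline
ggmnet simulate --config config.yaml                          # single stage
```

Artifacts are plain TSV matrices, GraphML graphs and a JSON manifest with
content hashes and per-stage seeds; re-running an unchanged configuration
reuses finished stages.

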