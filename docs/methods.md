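# Methods

`ggmnet` estimates conditional-dependency networks between regional brain
measures from several imaging modalities (amyloid-β deposition, glucose
metabolism, gray matter volume — "amy", "metab", "vol"), and compares their
graph structure across diagnostic groups (CN, EMCI, LMCI, AD).  This note
documents the models, the choices behind them, and what the synthetic cohorts
do and do not establish.

## W-score normalization

For node $j$ (a region × modality pair), an OLS model with age, gender and
education is fitted on control subjects only.  Each subject's value is then
normalized as

$$W_{ij} = \frac{x_{ij} - e_{ij}}{s_{\mathrm{res},j}},$$

where $e_{ij}$ is the control-model expectation for subject $i$'s covariates
and $s_{\mathrm{res},j}$ the standard deviation of control residuals.

*Residual-scale convention.*  $s_{\mathrm{res},j} = \sqrt{\mathrm{RSS}/(n-1)}$
(the sample SD of residuals), not the regression convention
$\sqrt{\mathrm{RSS}/(n-p)}$.  With an intercept in the model this makes
in-sample control W-scores have mean exactly 0 and SD exactly 1 — the
defining property of the normalization — and ±1.645 mark the 5th/95th
percentiles under Gaussian residuals.  Patients are scored with the control
model unchanged; nothing is refitted.

Degenerate nodes (zero residual variance in controls) raise an error naming
the node; fits require at least 10 controls and more controls than
predictors.

## Gaussian graphical model estimation

The data (W-score table, subjects × P nodes) are modelled as multivariate
Gaussian; conditional independencies are the zeros of the precision matrix
$K$, and the reported edge weights are partial correlations
$\theta_{ij} = -K_{ij}/\sqrt{K_{ii}K_{jj}}$.

### Graph score: marginal pseudo-likelihood

A graph $G$ is scored by the product over nodes of the marginal likelihood of
each column regressed on its neighbours, in closed form under a Zellner
g-prior with $g = n$ (unit information) and the improper scale prior
$p(\sigma^2) \propto 1/\sigma^2$:

$$\log m(y_j \mid X_N) = \mathrm{const} - \tfrac{d}{2}\log(1+g)
  - \tfrac{n}{2}\log\Big(y_j^\top y_j - \tfrac{g}{1+g}\, y_j^\top X_N
  (X_N^\top X_N)^{-1} X_N^\top y_j\Big),$$

with $d = |N|$; columns are centered first and graph-independent constants
are dropped (only score differences matter anywhere downstream).  Each edge
additionally contributes $\log\{p_e/(1-p_e)\}$ from an independent
Bernoulli($p_e$) edge prior, $p_e = 0.5$ by default (uniform over graphs).
Toggling one edge changes only the two incident node terms, so score
differences cost one small linear solve each.

### Birth–death sampling

Graph space is explored by a continuous-time birth–death process: in state
$G$, every absent edge has a birth rate and every present edge a death rate
$\min\{1, \exp(\Delta \mathrm{score})\}$; the waiting time in $G$ is the
reciprocal of the total rate; one edge is toggled with probability
proportional to its rate.  These rates satisfy the balance condition
$\beta_e(G)\,p(G) = \delta_e(G\cup e)\,p(G\cup e)$, so waiting-time-weighted
occupancy estimates posterior edge probabilities ($P_{avg}$).  Chains start
from the empty graph; burn-in jumps are discarded.  On problems small enough
to enumerate (P ≤ 5), occupancies reproduce the exact posterior from scoring
every graph (the package ships this enumeration as `exhaustive_posterior`).

Several independent repetitions (default 10) are run from spawned seeds and
their $P_{avg}$ matrices averaged; the graph is selected by the strict
threshold $P_{avg} > 0.5$.  Default desk-scale chain lengths are 10,000
burn-in and 20,000 retained jumps, which on the oracle suite is
indistinguishable from exact enumeration; `GGMConfig.full_scale()` sets the
full-scale 1,000,000/150,000 counts for large cohorts.

### Partial correlations on the selected graph

Estimation is decoupled from structure sampling: after graph selection the
maximum-likelihood precision with the selected zero pattern is fitted by
classical covariance selection — cyclic node-wise regression updates on a
working covariance initialized at the sample covariance, which enforce the
edge margins exactly and leave non-edge precision entries at zero.  At the
fixed point the implied covariance matches the sample covariance on every
edge and on the diagonal (tolerance 1e-10 by default); a complete graph
yields the inverse sample covariance exactly, an empty graph a diagonal
matrix.  Per-repetition partial-correlation matrices are also kept; when
averaging repetitions element-wise, the averaged matrix is masked to the
graph re-derived from the averaged probabilities, so the reported zero
pattern never exceeds the selected adjacency.

## Pearson baseline

All-pairs Pearson correlations with two-sided t-tests ($n-2$ df) and
Bonferroni correction over the $P(P-1)/2$ tested pairs at $\alpha = 0.05$.
The matrix handed to graph metrics is $|r|$ with non-significant entries
zeroed — the correction defines the graph, the absolute coefficient its
weights.  Network density is the significant-edge fraction of all pairs.

## Graph metrics

Distances between connected nodes are $\Omega = 1 - |\Theta|$; absent edges
are *unreachable*, not at distance 1.  Per node:

- **path length** $L_i$: mean Dijkstra distance to all reachable nodes;
  unreachable pairs are excluded from the mean and isolated nodes get an
  undefined (NaN) $L_i$ that downstream statistics drop with a logged count;
- **clustering** $C_i = 2t_i/(k_i(k_i-1))$ with
  $t_i = \tfrac12\sum_{j,h}(w_{ij}w_{ih}w_{jh})^{1/3}$ and weights
  max-normalised over present edges (Onnela convention, keeping $C_i \le 1$);
  $C_i = 0$ for degree < 2;
- **small-world ratio** $S_i = C_i/L_i$, with no random-network reference.

Per-modality tables are computed on the within-modality sub-matrix
(inter-modal edges excluded entirely); this sub-matrix convention is one of
two defensible readings and is stated here because the other (full-graph
paths restricted to modality nodes) gives different path lengths when
inter-modal shortcuts exist.

## Group comparison

For each metric × modality stratum, node values are compared across groups by
one-way ANOVA (explicit sum-of-squares decomposition; 4 groups × 54 regions
give total df 215) with $\eta^2 = SS_b/SS_t$, and by Tukey–Kramer HSD using
the studentized range with the ANOVA within-group df.  Regions are treated as
independent observations within a group; they are not (spatial dependence),
so these tests are descriptive summaries of node-wise distributions, not
inference about subjects.

## Synthetic cohorts

The generator emulates the post-imaging stage of a multimodal study: regional
values per subject drawn from a group-specific multivariate Gaussian plus
linear covariate effects.  The true precision matrix has unit diagonal and
$-\rho$ on specified edges:

- within each modality, regions form clusters (default ~6 regions) with chain
  edges between consecutive regions at `rho_intra` (default 0.35), optionally
  second-neighbour "closure" edges at `rho_intra2` (default 0), which are the
  only source of triangles in the true graph;
- each region's amyloid and metabolism nodes are linked at `rho_intermodal`
  (default 0.21).

Default group sizes are 254/309/220/189 (CN/EMCI/LMCI/AD).  Group differences
scale edge strength uniformly (`group_rho_scale`, defaults 1.0/1.25/1.05/0.8)
— a biphasic trajectory with early-MCI strengthening and dementia weakening.
A separate per-group multiplier for the closure edges (`group_rho2_scale`)
exists because a *uniform* rescaling cancels exactly in the max-normalised
clustering coefficient; clustering differences require changing the relative
strength of triangle-closing dependencies, which is also the natural encoding
of spatially simultaneous accumulation in early disease.

If the assembled matrix is not positive-definite, the diagonal is uniformly
inflated by the smallest amount restoring a minimum eigenvalue of `pd_floor`
(default 0.05) and the *realized* partial correlations are re-derived and
reported next to the requested ones; the edge set is never changed by repair.
The floor is set at 0.05 rather than machine-level because a barely-positive
minimum eigenvalue means a covariance with an enormous-variance direction:
simulated cohorts would be numerically degenerate in a way no regional
imaging dataset is.

Covariates: age ~ N(74.0, 7.3²) clipped to [55, 95] years, education ~
N(16.1, 2.7²) clipped to [6, 20] years, gender ~ Bernoulli(0.48) coded 1 =
female (the contrast direction is a documented constant, not a claim).
Covariate effects default to small per-modality slopes so that covariates
explain a minor share of variance.  `noise_scale` (default 0.15) sets the
residual SD on the raw-value scale; W-scoring removes both it and the
covariate structure.

*What the generator does not emulate:* spatial smoothness and measurement
point-spread, site/scanner effects, missing data, non-Gaussian tails, any
anatomical claim about which regions cluster, and disease-progression
mechanisms.  Passing recovery tests therefore show that the estimation chain
is correct under its own model assumptions at realistic sizes — not that
real multimodal cohorts satisfy those assumptions.

## Problem sizes and numerical choices

Oracle and recovery checks run at deliberately modest sizes chosen so each
check is decisive: exhaustive-posterior comparisons at P ≤ 5; structure
recovery at P = 30 (10 regions × 3 modalities), n = 700, edge strengths
≥ 0.2, with 5 repetitions of 5,000/10,000-jump chains; metric oracles on
≤ 8-node graphs against exhaustive path enumeration and triple-loop triangle
counting.  The W-score percentile check uses n = 10,000 controls and averages
per-node empirical 95th percentiles over 20 exchangeable nodes, keeping the
estimator's own sampling noise (~0.006) well below the ±0.02 tolerance, where
a single node's quantile (SE ≈ 0.021) would be noise-dominated.

Ties and degenerate inputs: edge selection uses a strict inequality, so
$P_{avg} = 0.5$ exactly is excluded; $|\theta| = 1$ edges collapse distances
to 0 and raise an error in the small-world ratio; constant columns are
rejected by name; samplers whose rates vanish numerically raise a stall error
with diagnostics rather than spinning.
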