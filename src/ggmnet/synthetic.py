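"""Synthetic multimodal cohorts with known conditional-dependency structure.

The generator emulates the post-imaging stage of a multimodal regional study:
per-subject regional values for several imaging modalities drawn from a
multivariate Gaussian whose precision matrix encodes a known sparse graph,
plus linear covariate effects (age, gender, education) and diagnosis-group
labels.  The true graph combines

* intra-modal "anatomical adjacency" chains: consecutive regions inside each
  cluster are conditionally dependent at partial correlation ``rho_intra``
  (optionally with second-neighbour closure edges at ``rho_intra2``, which
  create triangles in the true graph);
* intra-regional inter-modal edges between the amyloid and metabolism value
  of the same region at partial correlation ``rho_intermodal`` (default 0.21).

Group differences are induced by scaling all edge partial correlations with a
per-group factor (``group_rho_scale``); the edge SET is identical across
groups.  Every ground-truth object reports the *realized* partial
correlations, which can differ slightly from the requested ones when the
assembled matrix needed a positive-definiteness repair.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import RegionalDataset, node_name, write_matrix_tsv
from .exceptions import InvalidSpecError

DEFAULT_GROUPS = ("CN", "EMCI", "LMCI", "AD")
#: Cohort sizes of the emulated study population (CN, EMCI, LMCI, AD).
DEFAULT_GROUP_SIZES = (254, 309, 220, 189)
DEFAULT_MODALITIES = ("amy", "metab", "vol")

#: Overall edge-strength multiplier per diagnostic group.  Chosen to encode a
#: biphasic disease trajectory: strengthened conditional dependencies in early
#: MCI, near-control strength in late MCI, weakened dependencies in dementia.
DEFAULT_GROUP_RHO_SCALE = {"CN": 1.0, "EMCI": 1.25, "LMCI": 1.05, "AD": 0.8}

#: Modality intercepts on plausible scales for TIV-/reference-scaled measures.
DEFAULT_INTERCEPTS = {"amy": 1.15, "metab": 1.30, "vol": 0.65}

#: Linear covariate effects per modality (units of raw value per year of age,
#: per female-vs-male contrast, per year of education).  Modest by design:
#: covariates explain a small share of variance, as in regional imaging data.
DEFAULT_COVARIATE_EFFECTS = {
    "amy": {"age": 0.003, "gender": 0.005, "education": -0.001},
    "metab": {"age": -0.004, "gender": 0.010, "education": 0.001},
    "vol": {"age": -0.005, "gender": -0.010, "education": 0.001},
}

#: Covariate sampling distributions: age ~ N(74.0, 7.3) clipped to [55, 95],
#: gender ~ Bernoulli(0.48) with 1 = female, education ~ N(16.1, 2.7) clipped
#: to [6, 20].  Scales follow typical elderly memory-clinic cohorts.
DEFAULT_COVARIATE_DISTRIBUTIONS = {
    "age_mean": 74.0,
    "age_sd": 7.3,
    "age_range": (55.0, 95.0),
    "gender_p": 0.48,
    "education_mean": 16.1,
    "education_sd": 2.7,
    "education_range": (6.0, 20.0),
}



def _default_clusters(n_regions: int, target: int = 6) -> tuple[int, ...]:
    """Partition ``n_regions`` into near-equal clusters of about ``target``."""
    n_clusters = max(1, round(n_regions / target))
    base, extra = divmod(n_regions, n_clusters)
    return tuple(base + (1 if i < extra else 0) for i in range(n_clusters))


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort and its true network."""

    group_names: tuple[str, ...] = DEFAULT_GROUPS
    group_sizes: tuple[int, ...] = DEFAULT_GROUP_SIZES
    n_regions: int = 54
    modality_names: tuple[str, ...] = DEFAULT_MODALITIES
    cluster_sizes: tuple[int, ...] | None = None
    rho_intra: float = 0.35
    rho_intra2: float = 0.0
    rho_intermodal: float = 0.21
    group_rho_scale: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_RHO_SCALE)
    )
    group_rho2_scale: Mapping[str, float] | None = None
    covariate_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {m: dict(v) for m, v in DEFAULT_COVARIATE_EFFECTS.items()}
    )
    covariate_distributions: Mapping[str, object] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_DISTRIBUTIONS)
    )
    modality_intercepts: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INTERCEPTS)
    )
    noise_scale: float = 0.15
    pd_floor: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cluster_sizes is None:
            self.cluster_sizes = _default_clusters(self.n_regions)
        self.validate()

    # ------------------------------------------------------------- validation
    def validate(self) -> None:
        if len(self.group_sizes) != len(self.group_names):
            raise InvalidSpecError("group_sizes and group_names differ in length")
        if any(n <= 0 for n in self.group_sizes):
            raise InvalidSpecError("group sizes must all be positive")
        if self.n_regions <= 0:
            raise InvalidSpecError("n_regions must be positive")
        if sum(self.cluster_sizes) != self.n_regions:
            raise InvalidSpecError(
                f"cluster_sizes {self.cluster_sizes} do not partition R={self.n_regions}"
            )
        if any(c <= 0 for c in self.cluster_sizes):
            raise InvalidSpecError("cluster sizes must be positive")
        for group in self.group_names:
            for rho in (
                self.rho_intra * self.rho_scale(group),
                self.rho_intra2 * self.rho2_scale(group),
                self.rho_intermodal * self.rho_scale(group),
            ):
                if abs(rho) >= 1.0:
                    raise InvalidSpecError(
                        f"requested |rho| = {abs(rho):.3f} >= 1 for group {group}"
                    )
        if self.noise_scale <= 0:
            raise InvalidSpecError("noise_scale must be positive")
        if not 0.0 < self.pd_floor < 1.0:
            raise InvalidSpecError("pd_floor must lie in (0, 1)")

    # ---------------------------------------------------------------- helpers
    @property
    def n_modalities(self) -> int:
        return len(self.modality_names)

    @property
    def n_nodes(self) -> int:
        """Total node count P = R x number of modalities."""
        return self.n_regions * self.n_modalities

    @property
    def region_names(self) -> list[str]:
        width = len(str(self.n_regions))
        return [f"roi{r + 1:0{width}d}" for r in range(self.n_regions)]

    @property
    def node_labels(self) -> list[tuple[str, str]]:
        """(region, modality) per node, modality-major ordering."""
        return [(r, m) for m in self.modality_names for r in self.region_names]

    @property
    def node_names(self) -> list[str]:
        return [node_name(r, m) for r, m in self.node_labels]

    def rho_scale(self, group: str) -> float:
        if group not in self.group_names:
            raise InvalidSpecError(f"unknown group {group!r}; have {list(self.group_names)}")
        return float(self.group_rho_scale.get(group, 1.0))

    def rho2_scale(self, group: str) -> float:
        """Per-group multiplier for the closure edges.

        Defaults to the overall group scale; specifying it separately lets a
        group gain or lose triangle-closing dependencies specifically, which
        is what moves the clustering coefficient (a uniform rescaling of all
        edges cancels in the max-normalised triangle weights).
        """
        if self.group_rho2_scale is None:
            return self.rho_scale(group)
        if group not in self.group_names:
            raise InvalidSpecError(f"unknown group {group!r}; have {list(self.group_names)}")
        return float(self.group_rho2_scale.get(group, 1.0))

    def node_index(self, region_idx: int, modality_idx: int) -> int:
        return modality_idx * self.n_regions + region_idx

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["group_rho_scale"] = dict(self.group_rho_scale)
        if self.group_rho2_scale is not None:
            d["group_rho2_scale"] = dict(self.group_rho2_scale)
        return d


@dataclass
class GroundTruth:
    """True graph of one diagnostic group: adjacency, precision, partial corr."""

    group: str
    adjacency: np.ndarray
    precision: np.ndarray
    partial_corr_true: np.ndarray
    diagonal_inflation: float
    node_names: list[str]

    @property
    def covariance(self) -> np.ndarray:
        return np.linalg.inv(self.precision)

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, 1).sum())

    def edge_partial_corrs(self, pairs: Sequence[tuple[int, int]] | None = None) -> np.ndarray:
        """Realized partial correlations on edges (all edges by default)."""
        if pairs is None:
            ii, jj = np.nonzero(np.triu(self.adjacency, 1))
        else:
            ii, jj = zip(*pairs)
        return self.partial_corr_true[np.asarray(ii), np.asarray(jj)]


def partial_correlation_from_precision(precision: np.ndarray) -> np.ndarray:
    """-K_ij / sqrt(K_ii K_jj) with a zero diagonal (network convention)."""
    d = np.sqrt(np.diag(precision))
    pc = -precision / np.outer(d, d)
    np.fill_diagonal(pc, 0.0)
    return pc


def build_precision(spec: CohortSpec, group: str) -> GroundTruth:
    """Assemble the true precision matrix of one diagnostic group.

    The matrix starts from a unit diagonal; each specified edge (i, j) receives
    the off-diagonal entry -rho, so that (before any repair) the requested
    partial correlation on that edge is exactly rho.  If the assembled matrix
    is not positive-definite (or poorly conditioned), the diagonal is
    uniformly inflated by the smallest amount restoring a minimum eigenvalue
    of ``spec.pd_floor`` (default 0.05, which keeps the implied covariance
    well conditioned so simulated cohorts are not near-degenerate), and
    realized partial correlations are re-derived; the edge set is unchanged
    by repair.
    """
    spec.validate()
    scale = spec.rho_scale(group)
    P = spec.n_nodes
    R = spec.n_regions
    K = np.eye(P)

    def set_edge(i: int, j: int, rho: float) -> None:
        K[i, j] = K[j, i] = -rho

    # intra-modal chains (and optional second-neighbour closures) per cluster
    for m in range(spec.n_modalities):
        start = 0
        for size in spec.cluster_sizes:
            for r in range(start, start + size - 1):
                set_edge(spec.node_index(r, m), spec.node_index(r + 1, m),
                         spec.rho_intra * scale)
            if spec.rho_intra2 != 0.0:
                scale2 = spec.rho2_scale(group)
                for r in range(start, start + size - 2):
                    set_edge(spec.node_index(r, m), spec.node_index(r + 2, m),
                             spec.rho_intra2 * scale2)
            start += size

    # intra-regional amyloid--metabolism conditional dependency
    if spec.rho_intermodal != 0.0 and {"amy", "metab"} <= set(spec.modality_names):
        m_amy = spec.modality_names.index("amy")
        m_met = spec.modality_names.index("metab")
        for r in range(R):
            set_edge(spec.node_index(r, m_amy), spec.node_index(r, m_met),
                     spec.rho_intermodal * scale)

    adjacency = (K != 0).astype(int)
    np.fill_diagonal(adjacency, 0)

    eigmin = float(np.linalg.eigvalsh(K)[0])
    inflation = 0.0
    if eigmin < spec.pd_floor:
        inflation = spec.pd_floor - eigmin
        K = K + inflation * np.eye(P)

    return GroundTruth(
        group=group,
        adjacency=adjacency,
        precision=K,
        partial_corr_true=partial_correlation_from_precision(K),
        diagonal_inflation=inflation,
        node_names=spec.node_names,
    )


def build_all_precisions(spec: CohortSpec) -> dict[str, GroundTruth]:
    return {g: build_precision(spec, g) for g in spec.group_names}


def _draw_covariates(rng: np.random.Generator, n: int, dist: Mapping[str, object]) -> pd.DataFrame:
    age = np.clip(
        rng.normal(dist["age_mean"], dist["age_sd"], n), *dist["age_range"]
    )
    gender = rng.binomial(1, dist["gender_p"], n).astype(float)
    education = np.clip(
        rng.normal(dist["education_mean"], dist["education_sd"], n),
        *dist["education_range"],
    )
    return pd.DataFrame({"age": age, "gender": gender, "education": education})


def simulate_cohort(
    spec: CohortSpec, truths: Mapping[str, GroundTruth] | None = None
) -> RegionalDataset:
    """Draw a full cohort: covariates, group labels, regional values.

    Per subject, the value of node (region r, modality m) is::

        intercept_m + beta_m . (age, gender, education) + noise_scale * z

    with z a zero-mean Gaussian vector whose covariance is the inverse of the
    subject's group precision matrix.  Deterministic under ``spec.seed``.
    """
    spec.validate()
    if truths is None:
        truths = build_all_precisions(spec)
    rng = np.random.default_rng(spec.seed)
    dist = spec.covariate_distributions

    beta = np.zeros((3, spec.n_nodes))
    intercept = np.zeros(spec.n_nodes)
    for k, (region, modality) in enumerate(spec.node_labels):
        eff = spec.covariate_effects.get(modality, {})
        beta[:, k] = [eff.get("age", 0.0), eff.get("gender", 0.0), eff.get("education", 0.0)]
        intercept[k] = spec.modality_intercepts.get(modality, 0.0)

    frames = []
    ids: list[str] = []
    labels: list[str] = []
    covs = []
    for group, n in zip(spec.group_names, spec.group_sizes):
        truth = truths[group]
        cov_chol = np.linalg.cholesky(truth.covariance)
        covariates = _draw_covariates(rng, n, dist)
        z = rng.standard_normal((n, spec.n_nodes)) @ cov_chol.T
        X = covariates[["age", "gender", "education"]].to_numpy()
        values = intercept[None, :] + X @ beta + spec.noise_scale * z
        frames.append(values)
        covs.append(covariates)
        ids.extend(f"{group}{i + 1:04d}" for i in range(n))
        labels.extend([group] * n)

    values = pd.DataFrame(np.vstack(frames), columns=spec.node_names)
    return RegionalDataset(
        subject_ids=ids,
        diagnosis=np.asarray(labels, dtype=object),
        covariates=pd.concat(covs, ignore_index=True),
        values=values,
        node_labels=spec.node_labels,
    )


def write_ground_truth(
    spec: CohortSpec, truths: Mapping[str, GroundTruth], outdir: str | Path
) -> Path:
    """TSV matrices plus a JSON manifest (seed, spec echo, realized rhos)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": spec.seed, "spec": spec.to_dict(), "groups": {}}
    for group, truth in truths.items():
        write_matrix_tsv(truth.adjacency, truth.node_names, outdir / f"adjacency_{group}.tsv")
        write_matrix_tsv(truth.precision, truth.node_names, outdir / f"precision_{group}.tsv")
        write_matrix_tsv(
            truth.partial_corr_true, truth.node_names, outdir / f"partial_corr_true_{group}.tsv"
        )
        edge_pc = truth.edge_partial_corrs()
        manifest["groups"][group] = {
            "n_edges": truth.n_edges,
            "diagonal_inflation": truth.diagonal_inflation,
            "realized_partial_corr_mean_abs": float(np.mean(np.abs(edge_pc))) if edge_pc.size else 0.0,
            "realized_partial_corr_min_abs": float(np.min(np.abs(edge_pc))) if edge_pc.size else 0.0,
        }
    path = outdir / "ground_truth.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
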