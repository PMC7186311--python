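"""Pearson covariance-network baseline with Bonferroni thresholding."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .dataset import write_matrix_tsv
from .exceptions import DataError, DegenerateDataError
from .ggm import _as_array


@dataclass
class PearsonNetwork:
    """Pairwise correlations, corrected significance mask and density."""

    node_names: list[str]
    corr: np.ndarray
    p_values: np.ndarray
    mask: np.ndarray
    alpha: float
    correction: str

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.mask, 1).sum())

    @property
    def density(self) -> float:
        P = self.n_nodes
        return self.n_edges / (P * (P - 1) / 2)

    def weighted(self) -> np.ndarray:
        """|r| with non-significant entries zeroed — the matrix graph metrics use."""
        w = np.abs(self.corr) * self.mask
        np.fill_diagonal(w, 0.0)
        return w


def pearson_network(
    data, alpha: float = 0.05, correction: str = "bonferroni"
) -> PearsonNetwork:
    """All-pairs Pearson r with two-sided t-tests and Bonferroni correction.

    The Bonferroni factor is the number of tested pairs, P(P-1)/2; an edge is
    significant iff its adjusted p-value is below ``alpha``.
    """
    X, names = _as_array(data)
    n, P = X.shape
    if n < 4:
        raise DataError(f"need at least 4 subjects, got {n}")
    if not np.all(np.isfinite(X)):
        raise DataError("data contain non-finite values")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise DegenerateDataError(f"constant column {names[int(np.argmin(sd))]!r}")
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")

    r = np.corrcoef(X, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.abs(r) >= 1.0] = 0.0
    np.fill_diagonal(p, 1.0)

    m = P * (P - 1) // 2
    p_adj = np.minimum(p * m, 1.0) if correction == "bonferroni" else p
    mask = (p_adj < alpha).astype(int)
    np.fill_diagonal(mask, 0)
    return PearsonNetwork(
        node_names=names, corr=r, p_values=p, mask=mask,
        alpha=alpha, correction=correction,
    )


def write_pearson_network(net: PearsonNetwork, outdir: str | Path, prefix: str = "") -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"{prefix}_" if prefix else ""
    paths = [outdir / f"{tag}pearson_corr.tsv", outdir / f"{tag}pearson_mask.tsv"]
    write_matrix_tsv(net.corr, net.node_names, paths[0])
    write_matrix_tsv(net.mask, net.node_names, paths[1])
    return paths
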