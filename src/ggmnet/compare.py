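"""Group comparison of node-wise graph metrics: one-way ANOVA and Tukey HSD.

Regions are treated as independent observations within each diagnostic group
(so 4 groups x 54 regions give a total df of 215), mirroring common practice
in regional network studies; this ignores spatial dependence between regions
and should be read as descriptive.  Undefined metric values (isolated nodes)
are dropped listwise per metric with a logged count.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError
from .metrics import METRIC_NAMES

logger = logging.getLogger(__name__)


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    df_total: int
    p_value: float
    eta_squared: float
    group_means: dict[str, float] = field(default_factory=dict)
    group_sizes: dict[str, int] = field(default_factory=dict)


def _clean_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    cleaned = {}
    dropped = 0
    for name, values in groups.items():
        arr = np.asarray(values, dtype=float)
        keep = np.isfinite(arr)
        dropped += int((~keep).sum())
        cleaned[name] = arr[keep]
    if dropped:
        logger.info("dropped %d undefined observations", dropped)
    if len(cleaned) < 2:
        raise DataError("need at least 2 groups")
    for name, arr in cleaned.items():
        if len(arr) < 2:
            raise DataError(f"group {name!r} has fewer than 2 observations")
    return cleaned


def anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way ANOVA by explicit sum-of-squares decomposition."""
    cleaned = _clean_groups(groups)
    all_values = np.concatenate(list(cleaned.values()))
    grand = all_values.mean()
    ss_total = float(((all_values - grand) ** 2).sum())
    ss_between = float(
        sum(len(a) * (a.mean() - grand) ** 2 for a in cleaned.values())
    )
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in cleaned.values()))
    k = len(cleaned)
    n = len(all_values)
    df_b, df_w = k - 1, n - k
    ms_b, ms_w = ss_between / df_b, ss_within / df_w
    if ms_w == 0.0:
        F = 0.0 if ms_b == 0.0 else np.inf
    else:
        F = ms_b / ms_w
    p = float(stats.f.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0
    eta2 = ss_between / ss_total if ss_total > 0 else 0.0
    return AnovaResult(
        F=float(F),
        df_between=df_b,
        df_within=df_w,
        df_total=n - 1,
        p_value=p,
        eta_squared=float(eta2),
        group_means={g: float(a.mean()) for g, a in cleaned.items()},
        group_sizes={g: int(len(a)) for g, a in cleaned.items()},
    )


def tukey_hsd(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """All-pairs Tukey--Kramer comparisons via the studentized range.

    For groups a, b with sizes n_a, n_b the statistic is
    q = |mean_a - mean_b| / sqrt(MSW/2 * (1/n_a + 1/n_b)) and the p-value is
    the studentized-range upper tail with k groups and the ANOVA within df.
    Handles unequal group sizes (Tukey--Kramer).
    """
    cleaned = _clean_groups(groups)
    k = len(cleaned)
    df_w = sum(len(a) for a in cleaned.values()) - k
    ms_w = sum(((a - a.mean()) ** 2).sum() for a in cleaned.values()) / df_w
    rows = []
    for a, b in itertools.combinations(cleaned, 2):
        xa, xb = cleaned[a], cleaned[b]
        diff = xa.mean() - xb.mean()
        se = np.sqrt(ms_w / 2.0 * (1.0 / len(xa) + 1.0 / len(xb)))
        if se == 0.0:
            q, p = (0.0, 1.0) if diff == 0.0 else (np.inf, 0.0)
        else:
            q = abs(diff) / se
            p = float(np.clip(stats.studentized_range.sf(q, k, df_w), 0.0, 1.0))
        rows.append((a, b, float(diff), float(q), p))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "mean_diff", "q", "p_value"])


@dataclass
class ComparisonResult:
    """ANOVA and Tukey tables per (metric x modality) stratum."""

    anova_table: pd.DataFrame
    tukey_table: pd.DataFrame

    def to_files(self, outdir: str | Path, prefix: str = "comparison") -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tsv = outdir / f"{prefix}_tukey.tsv"
        self.tukey_table.to_csv(tsv, sep="\t", index=False)
        js = outdir / f"{prefix}_anova.json"
        js.write_text(json.dumps(self.anova_table.to_dict(orient="records"), indent=2))
        return [tsv, js]


def compare_metrics(table: pd.DataFrame) -> ComparisonResult:
    """Run ANOVA + Tukey HSD for every metric within every modality block.

    ``table`` is the tidy output of :func:`ggmnet.metrics.metrics_table`
    (columns: group, modality, node metrics).
    """
    anova_rows = []
    tukey_frames = []
    for modality in table["modality"].unique():
        sub = table[table["modality"] == modality]
        for metric in METRIC_NAMES:
            groups = {
                g: sub.loc[sub["group"] == g, metric].to_numpy()
                for g in sub["group"].unique()
            }
            res = anova(groups)
            anova_rows.append(
                {
                    "modality": modality,
                    "metric": metric,
                    "F": res.F,
                    "df_between": res.df_between,
                    "df_within": res.df_within,
                    "df_total": res.df_total,
                    "p_value": res.p_value,
                    "eta_squared": res.eta_squared,
                }
            )
            pairs = tukey_hsd(groups)
            pairs.insert(0, "modality", modality)
            pairs.insert(1, "metric", metric)
            tukey_frames.append(pairs)
    return ComparisonResult(
        anova_table=pd.DataFrame(anova_rows),
        tukey_table=pd.concat(tukey_frames, ignore_index=True),
    )
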