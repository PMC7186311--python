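"""End-to-end orchestration: simulate -> W-score -> GGM/Pearson -> metrics -> compare.

All randomness flows from one master seed, expanded into fixed per-stage
seeds, so re-running a configuration reproduces identical artifacts.  Each
stage writes its outputs plus an entry (content hash, seed) in the run
manifest; a stage whose outputs already exist under an unchanged
configuration is skipped and its artifacts are reloaded from disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .compare import compare_metrics
from .dataset import RegionalDataset, read_matrix_tsv
from .exceptions import PipelineError, SchemaError
from .ggm import GGMConfig, GGMResult, fit_ggm, write_ggm_result
from .metrics import metrics_table
from .pearson import pearson_network, write_pearson_network
from .synthetic import CohortSpec, build_all_precisions, simulate_cohort, write_ground_truth
from .wscore import apply_wscore, fit_wscore_model

logger = logging.getLogger(__name__)

STAGES = ("simulate", "wscore", "ggm", "pearson", "metrics", "compare")


@dataclass
class RunConfig:
    """One pipeline run: cohort, sampler settings and analysis selection."""

    outdir: str = "ggmnet_run"
    cohort: CohortSpec = field(default_factory=CohortSpec)
    ggm: GGMConfig = field(default_factory=GGMConfig)
    pearson_alpha: float = 0.05
    pearson_correction: str = "bonferroni"
    analyses: tuple[str, ...] = ("combined", "per_group")
    control_label: str = "CN"
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.analyses) - {"combined", "per_group"}
        if unknown:
            raise SchemaError(f"unknown analyses {sorted(unknown)}")

    def stage_seed(self, stage: str, extra: str = "") -> int:
        """Stable per-stage seed below 2^31 derived from the master seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}:{extra}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        d["analyses"] = list(self.analyses)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "cohort" in raw and isinstance(raw["cohort"], dict):
            cohort = dict(raw["cohort"])
            for key in ("group_names", "group_sizes", "modality_names", "cluster_sizes"):
                if key in cohort and cohort[key] is not None:
                    cohort[key] = tuple(cohort[key])
            raw["cohort"] = CohortSpec(**cohort)
        if "ggm" in raw and isinstance(raw["ggm"], dict):
            raw["ggm"] = GGMConfig(**raw["ggm"])
        if "analyses" in raw:
            raw["analyses"] = tuple(raw["analyses"])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineRun:
    """Stateful runner with a JSON manifest and per-stage resumability."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "run_manifest.json"
        self.manifest = self._load_manifest()
        self.dataset: RegionalDataset | None = None
        self.wscores: RegionalDataset | None = None
        self.ggm_results: dict[str, GGMResult] = {}
        self.pearson_results: dict = {}

    # ------------------------------------------------------------- manifest
    def _load_manifest(self) -> dict:
        if self.manifest_path.exists():
            manifest = json.loads(self.manifest_path.read_text())
            if manifest.get("config_hash") == self.config.config_hash():
                return manifest
            logger.info("configuration changed; previous artifacts will be rebuilt")
        return {
            "config_hash": self.config.config_hash(),
            "config": self.config.to_dict(),
            "stages": {},
        }

    def _save_manifest(self) -> None:
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2, default=str))

    def _record(self, stage: str, paths: list[Path], seed: int | None) -> None:
        self.manifest["stages"][stage] = {
            "status": "done",
            "seed": seed,
            "artifacts": {str(p.relative_to(self.outdir)): _sha256(p) for p in paths},
        }
        self._save_manifest()

    def _stage_done(self, stage: str) -> bool:
        entry = self.manifest["stages"].get(stage)
        if not entry or entry.get("status") != "done":
            return False
        return all((self.outdir / rel).exists() for rel in entry["artifacts"])

    # --------------------------------------------------------------- stages
    def _strata(self) -> dict[str, list[str]]:
        """Analysis strata: subject labels entering each model."""
        spec = self.config.cohort
        patients = [g for g in spec.group_names if g != self.config.control_label]
        strata: dict[str, list[str]] = {}
        if "combined" in self.config.analyses:
            strata["combined"] = patients
        if "per_group" in self.config.analyses:
            for g in spec.group_names:
                strata[g] = [g]
        return strata

    def run_simulate(self) -> RegionalDataset:
        stage = "simulate"
        path = self.outdir / "dataset.tsv"
        if self._stage_done(stage):
            self.dataset = RegionalDataset.from_tsv(path)
            return self.dataset
        spec = dataclasses.replace(self.config.cohort, seed=self.config.stage_seed(stage))
        truths = build_all_precisions(spec)
        self.dataset = simulate_cohort(spec, truths)
        self.dataset.to_tsv(path)
        truth_manifest = write_ground_truth(spec, truths, self.outdir / "truth")
        paths = [path, truth_manifest] + sorted((self.outdir / "truth").glob("*.tsv"))
        self._record(stage, paths, spec.seed)
        return self.dataset

    def run_wscore(self) -> RegionalDataset:
        stage = "wscore"
        wpath = self.outdir / "wscores.tsv"
        mpath = self.outdir / "wscore_model.json"
        if self._stage_done(stage):
            self.wscores = RegionalDataset.from_tsv(wpath)
            return self.wscores
        if self.dataset is None:
            self.run_simulate()
        model = fit_wscore_model(self.dataset, self.config.control_label)
        self.wscores = apply_wscore(model, self.dataset)
        model.to_json(mpath)
        self.wscores.to_tsv(wpath)
        self._record(stage, [wpath, mpath], None)
        return self.wscores

    def run_ggm(self) -> dict[str, GGMResult]:
        stage = "ggm"
        if self.wscores is None:
            self.run_wscore()
        if self._stage_done(stage):
            for name in self._strata():
                self.ggm_results[name] = load_ggm_result(
                    self.outdir / "ggm", name, threshold=self.config.ggm.threshold
                )
            return self.ggm_results
        paths: list[Path] = []
        for name, labels in self._strata().items():
            sub = self.wscores.subset(labels)
            cfg = dataclasses.replace(self.config.ggm, seed=self.config.stage_seed(stage, name))
            logger.info("GGM stratum %s: n=%d, P=%d", name, sub.n_subjects, sub.n_nodes)
            result = fit_ggm(sub.values, cfg)
            self.ggm_results[name] = result
            paths += write_ggm_result(result, self.outdir / "ggm", prefix=name)
        self._record(stage, paths, self.config.stage_seed(stage))
        return self.ggm_results

    def run_pearson(self) -> dict:
        stage = "pearson"
        if self.wscores is None:
            self.run_wscore()
        paths: list[Path] = []
        for name, labels in self._strata().items():
            sub = self.wscores.subset(labels)
            net = pearson_network(
                sub.values, alpha=self.config.pearson_alpha,
                correction=self.config.pearson_correction,
            )
            self.pearson_results[name] = net
            paths += write_pearson_network(net, self.outdir / "pearson", prefix=name)
        densities = {name: net.density for name, net in self.pearson_results.items()}
        (self.outdir / "pearson" / "densities.json").write_text(json.dumps(densities, indent=2))
        paths.append(self.outdir / "pearson" / "densities.json")
        self._record(stage, paths, None)
        return self.pearson_results

    def run_metrics(self):
        stage = "metrics"
        if not self.ggm_results:
            self.run_ggm()
        if not self.pearson_results:
            self.run_pearson()
        modalities = list(self.config.cohort.modality_names)
        per_group = {g: r for g, r in self.ggm_results.items() if g != "combined"}
        tables = {}
        paths = []
        for tag, results in (
            ("partial", per_group),
            ("pearson", {g: r for g, r in self.pearson_results.items() if g != "combined"}),
        ):
            if not results:
                continue
            table = metrics_table(results, modalities)
            tables[tag] = table
            p = self.outdir / f"metrics_{tag}.tsv"
            table.to_csv(p, sep="\t", index=False)
            paths.append(p)
        self._record(stage, paths, None)
        return tables

    def run_compare(self):
        stage = "compare"
        tables = self.run_metrics()
        paths = []
        results = {}
        for tag, table in tables.items():
            if table["group"].nunique() < 2:
                continue
            comparison = compare_metrics(table)
            results[tag] = comparison
            paths += comparison.to_files(self.outdir, prefix=f"comparison_{tag}")
        self._record(stage, paths, None)
        return results

    def run_all(self) -> dict:
        for stage in STAGES:
            runner = getattr(self, f"run_{stage}")
            try:
                runner()
            except Exception as exc:  # noqa: BLE001 - re-raise with the stage named
                self.manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
                self._save_manifest()
                raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        return self.manifest


def load_ggm_result(outdir: str | Path, prefix: str, threshold: float = 0.5) -> GGMResult:
    """Rebuild a GGMResult from its on-disk matrices."""
    from .ggm import select_graph

    outdir = Path(outdir)
    tag = f"{prefix}_" if prefix else ""
    edge_prob, names = read_matrix_tsv(outdir / f"{tag}edge_prob.tsv")
    partial, names2 = read_matrix_tsv(outdir / f"{tag}partial_corr.tsv")
    if names != names2:
        raise SchemaError("edge_prob and partial_corr node labels differ")
    return GGMResult(
        node_names=names,
        edge_prob=edge_prob,
        adjacency=select_graph(edge_prob, threshold),
        partial_corr=partial,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute every configured stage; returns the run manifest."""
    return PipelineRun(config).run_all()
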