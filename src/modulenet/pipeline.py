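"""End-to-end pipeline orchestration.

Runs collapse -> risk labels -> DEG filter -> penalty scan -> network ->
partition, with optional clustering/log-rank and re-sampling
classification stages, writing every artifact plus a machine-readable
run manifest. A run is fully reproducible from (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .degs import selected_genes, ttest_degs, write_deg_table, write_gene_list
from .errors import DataError, ModulenetError
from .evaluate import cluster_two_groups, resample_evaluate
from .expression_io import (
    ExpressionMatrix,
    assign_risk,
    read_annotation,
    read_expression,
    read_mapping,
    risk_labels,
    write_annotation,
)
from .network import degree_distribution_fit, penalty_scan
from .partition import partition_network, write_merge_log, write_modules_gmt

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Serializable description of one pipeline run."""

    expression_path: str
    annotation_path: str
    output_dir: str
    mapping_path: str | None = None
    collapse_method: str = "mean"
    risk_mode: str = "survival_cutoff"
    cutoff_days: int = 365
    low_risk_subtype: str = "PN"
    alpha: float = 0.05
    penalty_grid: list[float] = field(default_factory=lambda: [round(0.1 * i, 1) for i in range(11)])
    k_hubs: int = 20
    support_tol: float = 1e-8
    standardize: bool = True
    orphan_policy: str = "merge"
    overlap: str = "cardinality"
    run_clustering: bool = False
    cluster_method: str = "average"
    cluster_metric: str = "correlation"
    run_resampling: bool = False
    resampling_reps: int = 100
    n_features: int = 30
    train_frac: float = 0.8
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


class PipelineError(ModulenetError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def _stage(name):
        logger.info("pipeline stage: %s", name)

    try:
        _stage("load")
        mat = read_expression(config.expression_path)
        ann = read_annotation(config.annotation_path)
    except ModulenetError as exc:
        raise PipelineError("load", f"{exc}; check input paths and formats") from exc

    if config.mapping_path:
        try:
            _stage("collapse")
            from .expression_io import collapse_probesets

            mapping = read_mapping(config.mapping_path)
            mat = collapse_probesets(mat, mapping, method=config.collapse_method)
        except ModulenetError as exc:
            raise PipelineError("collapse", str(exc)) from exc

    try:
        _stage("risk")
        ann = assign_risk(
            ann,
            mode=config.risk_mode,
            cutoff_days=config.cutoff_days,
            low_risk_subtype=config.low_risk_subtype,
        )
        labels = risk_labels(ann)
        write_annotation(ann, out / "risk_labels.tsv")
        artifacts["risk_labels"] = "risk_labels.tsv"
    except ModulenetError as exc:
        raise PipelineError("risk", str(exc)) from exc

    try:
        _stage("degs")
        deg = ttest_degs(mat, labels, alpha=config.alpha)
        degs_list = selected_genes(deg)
        if len(degs_list) < 3:
            raise DataError(f"only {len(degs_list)} DEGs at alpha={config.alpha}")
        write_deg_table(deg, out / "degs.tsv")
        write_gene_list(degs_list, out / "deg_genes.txt")
        artifacts["degs"] = "degs.tsv"
        artifacts["deg_genes"] = "deg_genes.txt"
        mat_deg = mat.subset_genes(degs_list)
    except ModulenetError as exc:
        raise PipelineError("degs", str(exc)) from exc

    try:
        _stage("network")
        scan = penalty_scan(
            mat_deg,
            grid=config.penalty_grid,
            k=config.k_hubs,
            support_tol=config.support_tol,
            do_standardize=config.standardize,
        )
        scan.write_table(out / "penalty_scan.tsv")
        scan.network.write_edgelist(out / "edges.tsv")
        scan.network.write_graphml(out / "network.graphml")
        scan.network.write_degree_table(out / "degrees.tsv")
        fit = degree_distribution_fit(scan.network)
        (out / "degree_fit.json").write_text(
            json.dumps(asdict(fit), indent=2, sort_keys=True) + "\n"
        )
        artifacts.update(
            penalty_scan="penalty_scan.tsv", edges="edges.tsv",
            graphml="network.graphml", degrees="degrees.tsv",
            degree_fit="degree_fit.json",
        )
    except ModulenetError as exc:
        raise PipelineError("network", f"{exc}; consider a different penalty grid") from exc

    try:
        _stage("partition")
        n_pos = sum(1 for d in scan.network.degree().values() if d >= 1)
        k_eff = min(config.k_hubs, n_pos)
        result = partition_network(
            scan.network, k=k_eff,
            orphan_policy=config.orphan_policy, overlap=config.overlap,
        )
        best = result.best[0]
        write_modules_gmt(best, out / "modules.gmt")
        write_merge_log(best, out / "merge_log.tsv")
        result.write_e_table(out / "e_table.tsv")
        artifacts.update(modules="modules.gmt", merge_log="merge_log.tsv", e_table="e_table.tsv")
    except ModulenetError as exc:
        raise PipelineError("partition", str(exc)) from exc

    if config.run_clustering:
        try:
            _stage("clustering")
            results = {}
            for i, module in enumerate(best.modules, 1):
                sub = mat.subset_genes(sorted(module))
                res = cluster_two_groups(
                    sub, ann, method=config.cluster_method, metric=config.cluster_metric
                )
                results[f"module_{i}"] = {
                    "logrank_statistic": res.statistic,
                    "logrank_p": res.p_value,
                    "risk_by_cluster": res.risk_by_cluster,
                    "n_genes": len(module),
                }
            (out / "clustering.json").write_text(
                json.dumps(results, indent=2, sort_keys=True) + "\n"
            )
            artifacts["clustering"] = "clustering.json"
        except ModulenetError as exc:
            raise PipelineError("clustering", str(exc)) from exc

    if config.run_resampling:
        try:
            _stage("resampling")
            for i, module in enumerate(best.modules, 1):
                sub = mat.subset_genes(sorted(module))
                report = resample_evaluate(
                    sub, labels,
                    reps=config.resampling_reps, train_frac=config.train_frac,
                    seed=config.seed, n_features=min(config.n_features, sub.n_genes),
                )
                report.to_json(out / f"resampling_module_{i}.json")
                report.summary_frame().to_csv(
                    out / f"resampling_module_{i}.tsv", sep="\t", index=False,
                    lineterminator="\n",
                )
                artifacts[f"resampling_module_{i}"] = f"resampling_module_{i}.json"
        except ModulenetError as exc:
            raise PipelineError(
                "resampling",
                f"{exc}; resampling needs risk labels with >=5 samples per class",
            ) from exc

    manifest = {
        "modulenet_version": __version__,
        "python_version": platform.python_version(),
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "selected_rho": scan.selected_rho,
        "n_degs": len(degs_list),
        "n_edges": scan.network.n_edges,
        "best_partition_E": best.avg_overlap,
        "n_modules": len(best.modules),
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
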