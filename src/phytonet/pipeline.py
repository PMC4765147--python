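"""End-to-end orchestration: expression -> network -> modules ->
metabolite-associated modules -> per-module compression -> candidate screen.

`run_pipeline` drives the whole chain from a `RunConfig` (single YAML file
or constructed in code), writes every intermediate table to the output
directory, and returns a machine-readable `RunReport`. Module-specific
networks are exported and compressed per selected module: the topological
overlap is recomputed on each selected module's own adjacency submatrix
before thresholding, matching the per-module sub-networks the screening
stage works on.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import coexpression as cx
from . import powergraph as pgx
from .candidates import AnnotationTable, screen_candidates, reports_frame
from .expression import ExpressionMatrix, filter_genes

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All inputs and thresholds of one pipeline run."""

    expression_tsv: str | None = None
    sample_meta_tsv: str | None = None
    metabolites_tsv: str | None = None
    guides_tsv: str | None = None
    annotations_tsv: str | None = None
    de_tsv: str | None = None
    out_dir: str = "results/pipeline"
    seed: int = 0
    # network parameters
    correlation: str = "spearman"
    beta: int | None = None
    max_block_size: int = 3500
    export_threshold: float = 0.5
    min_module_size: int = 30
    cut_height: float = 0.99
    # screening thresholds
    q_threshold: float = 0.58
    alpha: float = 0.05
    r_min: float = 0.8
    p_max: float = 0.01
    fc_min: float = 2.0
    fdr_max: float = 0.01
    distance_max: float = 4.0
    mirna_score_max: float = 4.0
    top_hubs: int = 10
    hub_method: str = "degree"
    max_bad_values: int = 3

    def network_params(self) -> cx.NetworkParams:
        return cx.NetworkParams(
            correlation=self.correlation, beta=self.beta,
            max_block_size=self.max_block_size,
            export_threshold=self.export_threshold,
            min_module_size=self.min_module_size, cut_height=self.cut_height,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class RunReport:
    params: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    version: str = "0.1.0"

    def add_stage(self, name: str, **summary) -> None:
        self.stages.append({"stage": name, **summary})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _require(config: RunConfig, attr: str) -> str:
    path = getattr(config, attr)
    if path is None:
        raise PipelineError("load-inputs", f"missing required input {attr!r}")
    if not Path(path).exists():
        raise PipelineError("load-inputs", f"input {attr!r} not found at {path}")
    return path


def network_and_modules(
    expr: ExpressionMatrix,
    metabolites: pd.DataFrame,
    params: cx.NetworkParams,
    r_min: float = 0.8,
    p_max: float = 0.01,
    max_bad_values: int = 3,
) -> cx.CoexpressionResult:
    """Filter genes, build the network, detect modules, correlate modules
    with metabolites. In-memory core shared by `run_pipeline`, the analysis
    scripts and the tests."""
    expr = filter_genes(expr, max_bad=max_bad_values)
    corr = cx.correlation_matrix(expr.values, method=params.correlation,
                                 max_block_size=params.max_block_size)
    beta = params.beta or cx.select_soft_threshold(corr, signed=params.signed)
    adjacency = cx.soft_threshold_adjacency(corr, beta, signed=params.signed)
    tom = cx.compute_tom(adjacency)
    module_of = cx.detect_modules(tom, min_module_size=params.min_module_size,
                                  cut_height=params.cut_height)
    eigengenes = cx.module_eigengenes(expr.values, module_of)
    records = []
    if len(eigengenes):
        records = cx.module_trait_correlations(eigengenes, metabolites,
                                               r_min=r_min, p_max=p_max)
    result = cx.CoexpressionResult(
        adjacency=adjacency, tom=tom, module_of=module_of,
        eigengenes=eigengenes, params=params, beta_used=beta,
        correlation=corr, trait_records=records,
    )
    return result


def module_edge_lists(result: cx.CoexpressionResult, modules: list[str]) -> dict:
    """Per selected module: topological overlap of the module's own
    unpowered correlation strengths (|rho|), thresholded for export.

    The soft-threshold power serves global module *detection*; within an
    established module the exported edge weight is the TOM of |rho| itself,
    so the output threshold is on the correlation scale rather than being
    penalized twice.
    """
    out = {}
    for module in modules:
        genes = result.module_of[result.module_of == module].index
        sub = result.correlation.loc[genes, genes].abs()
        tom = cx.compute_tom(sub)
        out[module] = cx.export_edges(tom, threshold=result.params.export_threshold)
    return out


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full chain from a configuration; every intermediate is
    written under ``config.out_dir``. A stage failure aborts with the stage
    name; partial outputs are kept next to a FAILED marker file."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(params=asdict(config))
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    try:
        expr_path = _require(config, "expression_tsv")
        met_path = _require(config, "metabolites_tsv")
        expr = ExpressionMatrix.from_tsv(expr_path, config.sample_meta_tsv)
        metabolites = pd.read_csv(met_path, sep="\t", index_col=0)
        for attr in ("expression_tsv", "metabolites_tsv", "guides_tsv",
                     "annotations_tsv", "de_tsv", "sample_meta_tsv"):
            p = getattr(config, attr)
            if p and Path(p).exists():
                report.input_digests[attr] = _digest(p)
        report.add_stage("load-inputs", genes_in=len(expr.values),
                         samples=len(expr.values.columns),
                         metabolites=len(metabolites))

        result = network_and_modules(
            expr, metabolites, config.network_params(),
            r_min=config.r_min, p_max=config.p_max,
            max_bad_values=config.max_bad_values,
        )
        n_modules = len(result.eigengenes)
        report.add_stage("network", genes_out=len(result.module_of),
                         beta=result.beta_used, modules=n_modules)
        result.module_of.to_frame("module").to_csv(out / "modules.tsv", sep="\t")
        result.eigengenes.to_csv(out / "eigengenes.tsv", sep="\t")
        trait_df = cx.trait_records_frame(result.trait_records)
        trait_df.to_csv(out / "module_trait.tsv", sep="\t", index=False)

        selected = cx.select_significant_modules(result.trait_records,
                                                 r_min=config.r_min, p_max=config.p_max)
        report.add_stage("module-selection", selected=selected)
        edges_by_module = module_edge_lists(result, selected)
        union_edges = []
        ratios = {}
        pg_all = pgx.PowerGraph()
        for module, edges in edges_by_module.items():
            edges.to_csv(out / f"edges_{module}.tsv", sep="\t", index=False)
            if len(edges) == 0:
                report.warnings.append(f"module {module} exports no edges at "
                                       f"threshold {config.export_threshold}")
                continue
            pg = pgx.compress(edges)
            pg.to_json(out / f"powergraph_{module}.json")
            ratios[module] = pgx.compression_ratio(pg)
            # merge into one power graph over the disjoint module networks
            rename = {pid: f"{module}:{pid}" for pid in pg.power_nodes}
            pg_all.power_nodes.update({rename[p]: s for p, s in pg.power_nodes.items()})
            pg_all.power_edges.extend((rename[a], rename[b]) for a, b in pg.power_edges)
            pg_all.residual_edges.extend(pg.residual_edges)
            pg_all.n_original_edges += pg.n_original_edges
            union_edges.append(edges)
        report.add_stage("powergraph", compression_ratios=ratios)

        if union_edges and config.guides_tsv:
            edges = pd.concat(union_edges, ignore_index=True)
            guides_df = pd.read_csv(_require(config, "guides_tsv"), sep="\t")
            guides = dict(zip(guides_df.iloc[:, 0], guides_df.iloc[:, 1]))
            annotations = (AnnotationTable.from_tsv(config.annotations_tsv)
                           if config.annotations_tsv else AnnotationTable())
            de_flags = {}
            if config.de_tsv and Path(config.de_tsv).exists():
                de_df = pd.read_csv(config.de_tsv, sep="\t", index_col=0)
                de_flags = de_df["is_de"].astype(bool).to_dict()
            # hubs are identified per module sub-network, then pooled
            hubs = []
            for module_edges in union_edges:
                hubs.extend(cx.hub_genes(module_edges, method=config.hub_method,
                                         top_k=config.top_hubs))
            reports = screen_candidates(
                edges, pg_all, guides, annotations, de_flags, hubs=hubs,
                distance_max=config.distance_max,
                correlation_threshold=config.export_threshold,
                top_hubs=config.top_hubs, hub_method=config.hub_method,
            )
            reports_frame(reports).to_csv(out / "candidates.tsv", sep="\t", index=False)
            n_pass = sum(r.passes_mandatory for r in reports)
            report.add_stage("candidate-screen", evaluated=len(reports), passing=n_pass)
    except PipelineError:
        failed_marker.write_text("pipeline failed; see log")
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with stage context
        failed_marker.write_text(str(exc))
        stage = report.stages[-1]["stage"] if report.stages else "load-inputs"
        raise PipelineError(stage, str(exc)) from exc

    report.to_json(out / "run_report.json")
    return report
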