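"""End-to-end pipeline driver.

A single YAML (or dict) configuration drives the whole analysis:
optionally simulate a planted circuit, then normalize, call DE per
contrast, build the contrast TRNs, extract and merge pathway sub-TRNs,
compare the contrasts and run gene-set enrichment. Every stage logs to
standard error with a timer; the report contains a full config echo,
per-stage record counts, the file manifest and all warnings, and is a pure
function of (inputs, config, seed).

Example configuration::

    seed: 1
    outdir: results/run1
    reference_condition: reference
    simulate:
      n_genes: 2000
      n_tfs: 50
      n_direct_targets: 61
      repression_fraction: 0.7
      effect_log2: 2.0
      dispersion: 0.05
    thresholds:
      padj_threshold: 0.05
      fc_threshold: 2.0
      rho_threshold: 0.25
    subnet:
      include_neighbor_edges: false

With no ``simulate`` section, an ``inputs`` section must point at the five
input files (counts, design, catalog, direct_targets, gene_sets).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as tio
from . import synthetic
from .config import AnalysisConfig
from .diffexpr import de_union, normalize_size_factors, test_differential_expression
from .errors import ConfigurationError, StageError
from .network import build_trn
from .pathways import compare_contrasts, extract_pathway_subtrn, fisher_enrich, merge_subtrns

logger = logging.getLogger(__name__)

_INPUT_KEYS = ("counts", "design", "catalog", "direct_targets", "gene_sets")

_SIMULATE_KEYS = {
    "n_genes", "n_tfs", "n_direct_targets", "repression_fraction",
    "effect_log2", "cascade_targets_per_tf", "dosage", "dispersion",
    "baseline_log_mean", "baseline_log_sd",
}


@dataclass
class PipelineReport:
    """Machine-readable record of one pipeline run."""

    config: dict
    stages: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        payload = {"config": self.config, "stages": self.stages,
                   "manifest": self.manifest, "warnings": self.warnings}
        return json.dumps(payload, indent=1, sort_keys=True, default=str) + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


class _WarningCollector(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record):  # noqa: D102
        self.messages.append(record.getMessage())


def load_config(source: str | Path | dict) -> dict:
    if isinstance(source, dict):
        return dict(source)
    with open(source) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"configuration {source} is not a mapping")
    return cfg


def _validate_config(cfg: dict) -> None:
    if "outdir" not in cfg:
        raise ConfigurationError("configuration needs an 'outdir'")
    if "simulate" not in cfg:
        inputs = cfg.get("inputs") or {}
        missing = [k for k in _INPUT_KEYS if k not in inputs]
        if missing:
            raise ConfigurationError(
                f"no 'simulate' section and missing input path(s): {missing}")
        absent = [k for k in _INPUT_KEYS if not Path(inputs[k]).exists()]
        if absent:
            raise ConfigurationError(
                f"input file(s) do not exist: "
                f"{[str(inputs[k]) for k in absent]}")
    else:
        unknown = set(cfg["simulate"] or {}) - _SIMULATE_KEYS
        if unknown:
            raise ConfigurationError(
                f"unknown simulate option(s): {sorted(unknown)}")


class _Stage:
    """Context manager logging a stage timer and converting failures."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc is not None:
            logger.error("stage %s: failed after %.2fs", self.name, dt)
            raise StageError(self.name, exc) from exc
        logger.info("stage %s: done in %.2fs", self.name, dt)
        return False


def run_pipeline(config: str | Path | dict) -> PipelineReport:
    """Run every stage; returns the report (also written to the outdir)."""
    cfg = load_config(config)
    _validate_config(cfg)
    seed = int(cfg.get("seed", 0))
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    analysis = AnalysisConfig(**(cfg.get("thresholds") or {}))
    reference = cfg.get("reference_condition", "reference")
    include_neighbor_edges = bool(
        (cfg.get("subnet") or {}).get("include_neighbor_edges", False))
    top_k = int((cfg.get("enrich") or {}).get("top_k", 10))

    report = PipelineReport(config={**cfg, "thresholds": analysis.to_dict(),
                                    "seed": seed})
    collector = _WarningCollector()
    pkg_logger = logging.getLogger("trncontrast")
    pkg_logger.addHandler(collector)
    try:
        # ---- simulate or load ------------------------------------------
        if "simulate" in cfg:
            with _Stage("simulate"):
                sim = dict(cfg["simulate"] or {})
                truth = synthetic.generate_truth(seed=seed, **sim)
                design = synthetic.SampleDesign.default()
                counts = synthetic.simulate_counts(truth, design, seed=seed + 1)
                manifest = synthetic.write_fixture_bundle(
                    truth, counts, design, outdir / "fixtures")
                inputs = {k: manifest[k] for k in _INPUT_KEYS}
                report.manifest.update(
                    {f"fixture_{k}": str(Path(v).relative_to(outdir))
                     for k, v in manifest.items()})
                report.stages["simulate"] = {
                    "n_genes": truth.n_genes,
                    "n_tfs": len(truth.tf_ids),
                    "n_direct_edges": len(truth.direct_edges),
                    "n_cascade_edges": len(truth.cascade_edges),
                    "hub_id": truth.hub_id,
                }
        else:
            inputs = cfg["inputs"]

        with _Stage("load"):
            counts = tio.read_expression_matrix(inputs["counts"], raw=True)
            design = tio.read_sample_design(inputs["design"])
            counts.check_design(design)
            catalog = tio.read_regulation_catalog(inputs["catalog"])
            direct = tio.read_direct_targets(inputs["direct_targets"])
            gene_sets = tio.read_gene_sets(inputs["gene_sets"])
            report.stages["load"] = {
                "genes": counts.shape[0], "samples": counts.shape[1],
                "catalog_edges": len(catalog),
                "direct_targets": len(direct),
                "gene_sets": len(gene_sets),
            }

        if reference not in design.conditions:
            raise ConfigurationError(
                f"reference condition {reference!r} absent from the design")
        contrast_conditions = [c for c in design.conditions if c != reference]

        # ---- normalize --------------------------------------------------
        with _Stage("normalize"):
            factors, norm = normalize_size_factors(counts)
            report.stages["normalize"] = {
                "size_factors": {s: round(float(f), 6)
                                 for s, f in factors.items()},
            }

        # ---- differential expression ------------------------------------
        de_by_contrast = {}
        with _Stage("diffexpr"):
            stage: dict = {}
            for cond in contrast_conditions:
                de = test_differential_expression(
                    norm, design, (reference, cond), analysis)
                de_by_contrast[cond] = de
                path = outdir / f"de_{cond}.tsv"
                tio.write_de_table(de, path)
                report.manifest[f"de_{cond}"] = str(path.relative_to(outdir))
                stage[cond] = {"tested": len(de.table),
                               "up": len(de.up_genes),
                               "down": len(de.down_genes)}
            report.stages["diffexpr"] = stage

        union = de_union(*de_by_contrast.values())

        # ---- TRN per contrast -------------------------------------------
        trns = {}
        with _Stage("network"):
            stage = {}
            for cond, de in de_by_contrast.items():
                from .network import assemble_candidate_edges
                candidates = assemble_candidate_edges(catalog, de, direct)
                trn = build_trn(norm, design, catalog, direct, de, analysis)
                trns[cond] = trn
                for fmt, suffix in (("graphml", "graphml"), ("sif", "sif"),
                                    ("edge-table", "edges.tsv")):
                    path = outdir / f"trn_{cond}.{suffix}"
                    tio.write_network(trn, path, fmt)
                    report.manifest[f"trn_{cond}_{fmt}"] = str(path.relative_to(outdir))
                stage[cond] = {"candidate_edges": len(candidates),
                               "retained_edges": trn.n_edges,
                               "nodes": trn.n_nodes}
            report.stages["network"] = stage

        # ---- pathway sub-TRNs -------------------------------------------
        pathway_hubs: dict[str, dict] = {}
        with _Stage("subnet"):
            stage = {}
            for cond, trn in trns.items():
                subtrns = []
                per_pathway = {}
                for name in gene_sets:
                    sub = extract_pathway_subtrn(
                        trn, gene_sets[name], union, pathway_name=name,
                        include_neighbor_edges=include_neighbor_edges)
                    subtrns.append(sub)
                    per_pathway[name] = {
                        "seeds": len(sub.seeds), "nodes": sub.n_nodes,
                        "edges": sub.n_edges, "hub": sub.hub_id}
                    path = outdir / f"subtrn_{cond}_{name}.graphml"
                    tio.write_network(sub, path, "graphml")
                    report.manifest[f"subtrn_{cond}_{name}"] = str(path.relative_to(outdir))
                pathway_hubs[cond] = {name: per_pathway[name]["hub"]
                                      for name in per_pathway}
                if subtrns:
                    merged = merge_subtrns(subtrns)
                    path = outdir / f"merged_subtrn_{cond}.graphml"
                    tio.write_network(merged, path, "graphml")
                    report.manifest[f"merged_subtrn_{cond}"] = str(path.relative_to(outdir))
                    per_pathway["_merged"] = {"nodes": merged.n_nodes,
                                              "edges": merged.n_edges}
                stage[cond] = per_pathway
            report.stages["subnet"] = stage

        # ---- contrast comparison ----------------------------------------
        if len(contrast_conditions) >= 2:
            with _Stage("compare"):
                a, b = contrast_conditions[:2]
                comparison = compare_contrasts(
                    trns[a], trns[b], de_by_contrast[a], de_by_contrast[b],
                    direct, pathway_hubs=pathway_hubs)
                path = outdir / "comparison.json"
                path.write_text(json.dumps(comparison.to_dict(), indent=1,
                                           sort_keys=True) + "\n")
                report.manifest["comparison"] = str(path.relative_to(outdir))
                report.stages["compare"] = comparison.to_dict()

        # ---- enrichment --------------------------------------------------
        with _Stage("enrich"):
            universe = set(counts.gene_ids)
            stage = {}
            for cond, de in de_by_contrast.items():
                for direction, genes in (("up", de.up_genes),
                                         ("down", de.down_genes)):
                    rows = fisher_enrich(genes, universe, gene_sets,
                                         top_k=top_k)
                    path = outdir / f"enrichment_{cond}_{direction}.tsv"
                    with open(path, "w") as fh:
                        fh.write("set\tk\tK\tn\tN\tpvalue\tpadj\n")
                        for r in rows:
                            fh.write(f"{r.name}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                                     f"{r.pvalue:.17g}\t{r.padj:.17g}\n")
                    report.manifest[f"enrichment_{cond}_{direction}"] = str(path.relative_to(outdir))
                    stage[f"{cond}_{direction}"] = {
                        "tested_sets": len(gene_sets),
                        "reported": len(rows),
                        "top_set": rows[0].name if rows else None,
                    }
            report.stages["enrich"] = stage
    finally:
        pkg_logger.removeHandler(collector)

    report.warnings = sorted(set(collector.messages))
    report_path = outdir / "report.json"
    report.write(report_path)
    report.manifest["report"] = str(report_path.relative_to(outdir))
    return report
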