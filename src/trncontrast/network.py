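"""Contrast TRN assembly: catalog gating, ChIP-target edges, correlation filter.

A candidate edge enters the network in one of two ways: a motif-evidence
catalog edge whose TF and target are both differentially expressed in the
contrast, or a ChIP-evidence edge from the hub to each of its differentially
expressed direct targets. Candidates are then filtered by the signed
Spearman correlation of the two genes' log2 normalized profiles across all
samples (both conditions pooled): an edge survives only if |rho| reaches the
threshold (0.25 by default, inclusive). Surviving edges carry rho and its
sign; nodes carry their DE flag, direct-target status, and degree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .diffexpr import DEResult, NOT_DE
from .matrix import ExpressionMatrix, SampleDesign

logger = logging.getLogger(__name__)

CHIP = "chip"
MOTIF = "motif"
POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class RegulationCatalog:
    """Directed TF -> target pairs predicted by motif scanning."""

    edges: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges in regulation catalog")
        bad = [e for e in self.edges if e[0] == e[1]]
        if bad:
            raise ValueError(f"self-edges in regulation catalog: {bad}")

    @property
    def tf_ids(self) -> frozenset:
        return frozenset(tf for tf, _ in self.edges)

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class DirectTargetSet:
    """ChIP-derived direct targets of the hub TF."""

    hub_id: str
    target_ids: frozenset

    def __post_init__(self):
        if self.hub_id in self.target_ids:
            raise ValueError("hub cannot be its own direct target")

    def __len__(self) -> int:
        return len(self.target_ids)


@dataclass(frozen=True)
class RegulatoryEdge:
    regulator: str
    target: str
    evidence: str                 # "chip" or "motif"
    rho: float | None = None      # Spearman correlation across all samples
    sign: str | None = None       # "positive" / "negative", derived from rho

    def __post_init__(self):
        if self.evidence not in (CHIP, MOTIF):
            raise ValueError(f"unknown evidence class {self.evidence!r}")
        if self.regulator == self.target:
            raise ValueError("self-edges are not allowed")


class TRN:
    """Annotated contrast network over a :class:`networkx.DiGraph`.

    Node attributes: ``de_flag``, ``is_direct_target``, ``degree``.
    Edge attributes: ``evidence``, ``rho``, ``sign``.
    """

    def __init__(self, graph: nx.DiGraph, contrast: tuple[str, str],
                 hub_id: str | None = None):
        self.graph = graph
        self.contrast = contrast
        self.hub_id = hub_id

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self.graph.nodes))

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(sorted(self.graph.edges))

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_list(self) -> list[RegulatoryEdge]:
        out = []
        for u, v in self.edges:
            d = self.graph.edges[u, v]
            out.append(RegulatoryEdge(u, v, d["evidence"], d.get("rho"),
                                      d.get("sign")))
        return out

    def node_table(self) -> pd.DataFrame:
        rows = []
        for n in self.nodes:
            d = self.graph.nodes[n]
            rows.append({"gene_id": n, "de_flag": d.get("de_flag", NOT_DE),
                         "is_direct_target": bool(d.get("is_direct_target")),
                         "degree": int(d.get("degree", 0))})
        return pd.DataFrame(rows, columns=["gene_id", "de_flag",
                                           "is_direct_target", "degree"])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"TRN(contrast={self.contrast}, {self.n_nodes} nodes, "
                f"{self.n_edges} edges)")


def spearman_rho(x, y) -> float:
    """Spearman correlation (Pearson on average ranks); NaN when either
    profile is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and equally long")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def assemble_candidate_edges(
    catalog: RegulationCatalog,
    de: DEResult,
    direct: DirectTargetSet,
) -> list[RegulatoryEdge]:
    """Candidate edges before the correlation filter.

    Catalog edges require both endpoints DE in this contrast; hub->target
    ChIP edges require only the target to be DE. When both sources yield
    the same pair, the ChIP evidence class wins.
    """
    de_genes = de.de_genes
    edges: dict[tuple[str, str], str] = {}
    for tf, target in catalog.edges:
        if tf in de_genes and target in de_genes:
            edges[(tf, target)] = MOTIF
    for target in direct.target_ids:
        if target in de_genes:
            edges[(direct.hub_id, target)] = CHIP
    return [RegulatoryEdge(r, t, ev) for (r, t), ev in sorted(edges.items())]


def filter_edges_by_correlation(
    candidates: list[RegulatoryEdge],
    expr: ExpressionMatrix,
    config: AnalysisConfig | None = None,
) -> list[RegulatoryEdge]:
    """Retain edges whose endpoints' log2 profiles correlate strongly enough.

    ``expr`` must cover *all* samples of the experiment (the correlation is
    computed across every condition pooled). Edges with an undefined
    correlation (a constant profile) are dropped with a warning.
    """
    if config is None:
        config = AnalysisConfig()
    logmat = expr.log2(config.pseudocount)
    thr = config.rho_threshold
    retained: list[RegulatoryEdge] = []
    for edge in candidates:
        for gene in (edge.regulator, edge.target):
            if gene not in logmat.index:
                raise KeyError(f"no expression profile for gene {gene!r}")
        rho = spearman_rho(logmat.loc[edge.regulator].to_numpy(),
                           logmat.loc[edge.target].to_numpy())
        if np.isnan(rho):
            logger.warning(
                "edge %s->%s dropped: correlation undefined (constant profile)",
                edge.regulator, edge.target)
            continue
        if config.correlation_inclusive:
            keep = rho >= thr or rho <= -thr
        else:
            keep = rho > thr or rho < -thr
        if keep:
            sign = POSITIVE if rho >= 0 else NEGATIVE
            retained.append(replace(edge, rho=rho, sign=sign))
    return retained


def build_trn(
    expr: ExpressionMatrix,
    design: SampleDesign,
    catalog: RegulationCatalog,
    direct: DirectTargetSet,
    de: DEResult,
    config: AnalysisConfig | None = None,
) -> TRN:
    """Assemble, filter and annotate the TRN for one contrast.

    The node set is the endpoints of retained edges, plus every DE direct
    target of the hub (even if its edge fell to the correlation filter),
    plus the hub itself.
    """
    if config is None:
        config = AnalysisConfig()
    expr.check_design(design)
    candidates = assemble_candidate_edges(catalog, de, direct)
    retained = filter_edges_by_correlation(candidates, expr, config)

    nodes: set[str] = {direct.hub_id}
    nodes |= {t for t in direct.target_ids if t in de.de_genes}
    for e in retained:
        nodes.add(e.regulator)
        nodes.add(e.target)

    g = nx.DiGraph()
    for n in sorted(nodes):
        g.add_node(n,
                   de_flag=de.flag_of(n),
                   is_direct_target=(n in direct.target_ids))
    for e in sorted(retained, key=lambda e: (e.regulator, e.target)):
        g.add_edge(e.regulator, e.target, evidence=e.evidence,
                   rho=float(e.rho), sign=e.sign)
    for n in g.nodes:
        g.nodes[n]["degree"] = g.in_degree(n) + g.out_degree(n)
    return TRN(g, contrast=de.contrast, hub_id=direct.hub_id)


def build_trns(
    expr: ExpressionMatrix,
    design: SampleDesign,
    catalog: RegulationCatalog,
    direct: DirectTargetSet,
    de_by_contrast: dict[str, DEResult],
    config: AnalysisConfig | None = None,
) -> dict[str, TRN]:
    """One TRN per contrast, each gated on its own DE flags."""
    return {label: build_trn(expr, design, catalog, direct, de, config)
            for label, de in de_by_contrast.items()}
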