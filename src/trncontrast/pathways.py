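"""Pathway-seeded sub-networks, contrast comparison, enrichment, heatmaps.

A sub-TRN is seeded by the pathway members that are differentially expressed
in at least one contrast and present in the parent network; its nodes are
the seeds plus their direct upstream and downstream neighbors, and by
default only edges touching a seed are kept (the full induced subgraph is
available behind a switch). The sub-network's hub is its maximum-degree
node, ties broken lexicographically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DEResult, DOWN, UP
from .matrix import ExpressionMatrix, SampleDesign
from .network import TRN, DirectTargetSet
from .diffexpr import adjust_benjamini_hochberg

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathwayGeneSets:
    """Named gene sets (GMT-style)."""

    sets: dict[str, frozenset]

    @classmethod
    def from_lists(cls, d: dict) -> "PathwayGeneSets":
        return cls({name: frozenset(members) for name, members in d.items()})

    def __getitem__(self, name: str) -> frozenset:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


@dataclass(frozen=True)
class SubTRN:
    """Pathway-centered neighborhood of a contrast TRN."""

    pathway: str
    contrast: tuple[str, str]
    seeds: frozenset
    graph: nx.DiGraph
    hub_id: str | None

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


def _max_degree_hub(graph: nx.DiGraph) -> str | None:
    if graph.number_of_nodes() == 0:
        return None
    return min(graph.nodes,
               key=lambda n: (-(graph.in_degree(n) + graph.out_degree(n)), n))


def extract_pathway_subtrn(
    trn: TRN,
    pathway: frozenset | set,
    de_union: frozenset | set,
    pathway_name: str = "",
    include_neighbor_edges: bool = False,
) -> SubTRN:
    """Neighborhood of the pathway genes that are DE in >= 1 contrast.

    ``de_union`` is the union of DE genes over every contrast, matching the
    convention that a pathway gene seeds the view as soon as it responds in
    either perturbation.
    """
    seeds = frozenset(pathway) & frozenset(de_union) & set(trn.graph.nodes)
    nodes: set = set(seeds)
    for s in seeds:
        nodes.update(trn.graph.predecessors(s))
        nodes.update(trn.graph.successors(s))
    g = nx.DiGraph()
    for n in sorted(nodes):
        g.add_node(n, **dict(trn.graph.nodes[n]), is_seed=(n in seeds))
    for u, v in sorted(trn.graph.edges):
        if u in nodes and v in nodes:
            if include_neighbor_edges or u in seeds or v in seeds:
                g.add_edge(u, v, **dict(trn.graph.edges[u, v]))
    for n in g.nodes:
        g.nodes[n]["degree"] = g.in_degree(n) + g.out_degree(n)
    return SubTRN(pathway=pathway_name, contrast=trn.contrast,
                  seeds=seeds, graph=g, hub_id=_max_degree_hub(g))


def merge_subtrns(subtrns: list[SubTRN]) -> TRN:
    """Union of sub-TRNs from one contrast, nodes annotated with the sorted
    list of pathways they belong to."""
    if not subtrns:
        raise ValueError("need at least one sub-TRN to merge")
    contrasts = {s.contrast for s in subtrns}
    if len(contrasts) > 1:
        raise ValueError(f"cannot merge sub-TRNs from different contrasts: "
                         f"{sorted(contrasts)}")
    g = nx.DiGraph()
    membership: dict[str, set] = {}
    for s in subtrns:
        for n in sorted(s.graph.nodes):
            if n not in g:
                attrs = {k: v for k, v in s.graph.nodes[n].items()
                         if k != "is_seed"}
                g.add_node(n, **attrs)
            membership.setdefault(n, set()).add(s.pathway)
        for u, v in sorted(s.graph.edges):
            if not g.has_edge(u, v):
                g.add_edge(u, v, **dict(s.graph.edges[u, v]))
    for n, paths in membership.items():
        g.nodes[n]["pathways"] = ";".join(sorted(paths))
    for n in g.nodes:
        g.nodes[n]["degree"] = g.in_degree(n) + g.out_degree(n)
    return TRN(g, contrast=subtrns[0].contrast, hub_id=_max_degree_hub(g))


def _sym_diff_fraction(a: frozenset, b: frozenset) -> float:
    union = a | b
    if not union:
        return 0.0
    return len(a ^ b) / len(union)


def _jaccard(a, b) -> float:
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


@dataclass(frozen=True)
class ContrastComparison:
    """Set-algebra summary of two perturbation contrasts."""

    label_a: str
    label_b: str
    per_contrast: dict[str, dict]
    shared_up: int
    shared_down: int
    specific_fraction_up: float
    specific_fraction_down: float
    specific_fraction_all: float
    node_jaccard: float
    edge_jaccard: float
    pathway_hubs: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "label_a": self.label_a,
            "label_b": self.label_b,
            "per_contrast": self.per_contrast,
            "shared_up": self.shared_up,
            "shared_down": self.shared_down,
            "specific_fraction_up": self.specific_fraction_up,
            "specific_fraction_down": self.specific_fraction_down,
            "specific_fraction_all": self.specific_fraction_all,
            "node_jaccard": self.node_jaccard,
            "edge_jaccard": self.edge_jaccard,
            "pathway_hubs": self.pathway_hubs,
        }


def compare_contrasts(
    trn_a: TRN,
    trn_b: TRN,
    de_a: DEResult,
    de_b: DEResult,
    direct: DirectTargetSet,
    pathway_hubs: dict[str, dict] | None = None,
) -> ContrastComparison:
    """Compare two contrasts' DE sets and network topology.

    Both DE results must be computed against the same reference condition.
    ``pathway_hubs`` may carry {contrast label: {pathway: hub}} from the
    sub-TRN stage and is echoed into the report.
    """
    if de_a.contrast[0] != de_b.contrast[0]:
        raise ValueError("contrasts must share the reference condition")
    label_a, label_b = de_a.contrast[1], de_b.contrast[1]

    per = {}
    for label, de, trn in ((label_a, de_a, trn_a), (label_b, de_b, trn_b)):
        up, down = de.up_genes, de.down_genes
        per[label] = {
            "n_up": len(up),
            "n_down": len(down),
            "direct_up": len(up & direct.target_ids),
            "direct_down": len(down & direct.target_ids),
            "trn_nodes": trn.n_nodes,
            "trn_edges": trn.n_edges,
        }

    up_a, up_b = de_a.up_genes, de_b.up_genes
    down_a, down_b = de_a.down_genes, de_b.down_genes
    return ContrastComparison(
        label_a=label_a,
        label_b=label_b,
        per_contrast=per,
        shared_up=len(up_a & up_b),
        shared_down=len(down_a & down_b),
        specific_fraction_up=_sym_diff_fraction(up_a, up_b),
        specific_fraction_down=_sym_diff_fraction(down_a, down_b),
        specific_fraction_all=_sym_diff_fraction(de_a.de_genes, de_b.de_genes),
        node_jaccard=_jaccard(trn_a.nodes, trn_b.nodes),
        edge_jaccard=_jaccard(trn_a.edges, trn_b.edges),
        pathway_hubs=pathway_hubs or {},
    )


@dataclass(frozen=True)
class EnrichmentRow:
    """One gene set's over-representation result."""

    name: str
    k: int        # overlap
    K: int        # set size (within the universe)
    n: int        # query list size
    N: int        # universe size
    pvalue: float
    padj: float


def fisher_enrich(
    gene_list,
    universe,
    sets: PathwayGeneSets,
    top_k: int = 10,
) -> list[EnrichmentRow]:
    """One-sided over-representation test per set (hypergeometric upper
    tail, equivalent to one-sided Fisher's exact), BH-adjusted across sets,
    sorted by p-value and truncated to the top ``top_k`` rows.

    Query genes and set members outside the universe are clipped with a
    warning.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("the gene universe is empty")
    query = frozenset(gene_list)
    outside = query - universe
    if outside:
        logger.warning("%d query gene(s) outside the universe were clipped",
                       len(outside))
        query &= universe
    if not query:
        return []

    N, n = len(universe), len(query)
    names, pvals, ks, Ks = [], [], [], []
    for name, members in sets.items():
        clipped = frozenset(members) & universe
        if len(clipped) < len(frozenset(members)):
            logger.warning("set %r: %d member(s) outside the universe clipped",
                           name, len(frozenset(members)) - len(clipped))
        K = len(clipped)
        k = len(query & clipped)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        names.append(name)
        pvals.append(min(max(p, 0.0), 1.0))
        ks.append(k)
        Ks.append(K)
    if not names:
        return []
    padj = adjust_benjamini_hochberg(np.array(pvals))
    rows = [EnrichmentRow(name=names[i], k=ks[i], K=Ks[i], n=n, N=N,
                          pvalue=pvals[i], padj=float(padj[i]))
            for i in range(len(names))]
    rows.sort(key=lambda r: (r.pvalue, r.name))
    return rows[:top_k]


def condition_scaled_matrix(
    expr: ExpressionMatrix,
    design: SampleDesign,
    genes,
) -> pd.DataFrame:
    """Condition-mean expression per gene, z-scored within each row.

    Values are averaged within each condition (columns ordered as in the
    design), then each row is centered and divided by its sample standard
    deviation; rows with zero deviation map to all-zeros. This is the
    matrix behind condition-level expression heatmaps.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in expr.data.index]
    if missing:
        raise KeyError(f"genes absent from the expression matrix: {missing}")
    conds = design.conditions
    means = pd.DataFrame(
        {c: expr.data.loc[genes, list(design.samples_for(c))].mean(axis=1)
         for c in conds},
        index=genes,
    )
    centered = means.sub(means.mean(axis=1), axis=0)
    sd = means.std(axis=1, ddof=1)
    out = centered.div(sd.where(sd > 0, np.inf), axis=0)
    return out
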