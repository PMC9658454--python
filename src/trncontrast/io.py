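"""Readers and writers for the tabular-text interchange formats.

All tables are tab-separated with a header row; gene identifiers are opaque,
case-sensitive strings. Networks export to GraphML (full attributes), SIF
(regulator, evidence, target) and a flat edge table. Gene sets use GMT
(set name, description, members).
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import ParseError
from .matrix import ExpressionMatrix, SampleDesign
from .network import TRN, DirectTargetSet, RegulationCatalog
from .pathways import PathwayGeneSets, SubTRN

logger = logging.getLogger(__name__)

NETWORK_FORMATS = ("graphml", "sif", "edge-table")


# ---------------------------------------------------------------- matrices

def read_expression_matrix(path: str | Path, raw: bool = True) -> ExpressionMatrix:
    """Read a gene-by-sample TSV (first column gene_id, header of samples)."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError("empty expression matrix file", str(path), 1)
    header = lines[0].split("\t")
    if len(header) < 2:
        raise ParseError("expected a gene_id column plus sample columns",
                         str(path), 1)
    samples = header[1:]
    genes: list[str] = []
    seen: set[str] = set()
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(header):
            raise ParseError(
                f"ragged row: {len(cells)} cells, expected {len(header)}",
                str(path), lineno)
        gene = cells[0]
        if gene in seen:
            raise ParseError(f"duplicate gene identifier {gene!r}",
                             str(path), lineno)
        seen.add(gene)
        try:
            rows.append([float(c) for c in cells[1:]])
        except ValueError as exc:
            raise ParseError(f"non-numeric cell for gene {gene!r}: {exc}",
                             str(path), lineno) from None
        genes.append(gene)
    data = pd.DataFrame(rows, index=genes, columns=samples)
    return ExpressionMatrix(data, raw=raw)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene_id")


# ----------------------------------------------------------------- designs

def read_sample_design(path: str | Path) -> SampleDesign:
    """Read a two-column sample/condition sheet."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     na_filter=False)
    for col in ("sample", "condition"):
        if col not in df.columns:
            raise ParseError(f"missing column {col!r}", str(path), 1)
    samples = tuple(df["sample"])
    cond = dict(zip(df["sample"], df["condition"]))
    return SampleDesign(samples, cond)


def write_sample_design(design: SampleDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- catalogs

_CATALOG_HEADERS = {("tf_id", "target_id"), ("tf", "target"),
                    ("regulator", "target")}


def read_regulation_catalog(path: str | Path) -> RegulationCatalog:
    """Read TF -> target pairs (two tab-separated columns, optional header).

    Self-edges are dropped with a warning; duplicates are deduplicated.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    start = 0
    if lines:
        first = tuple(c.strip().lower() for c in lines[0].split("\t")[:2])
        if first in _CATALOG_HEADERS:
            start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        cells = line.split("\t")
        if len(cells) < 2:
            raise ParseError("expected two tab-separated identifier columns",
                             str(path), lineno)
        tf, target = cells[0].strip(), cells[1].strip()
        if tf == target:
            logger.warning("%s:%d: self-edge %s->%s dropped",
                           path, lineno, tf, target)
            continue
        pair = (tf, target)
        if pair in seen:
            continue
        seen.add(pair)
        edges.append(pair)
    if not edges:
        logger.warning("regulation catalog %s is empty", path)
    return RegulationCatalog(tuple(edges))


def write_regulation_catalog(edges, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tf_id\ttarget_id\n")
        for tf, target in edges:
            fh.write(f"{tf}\t{target}\n")


def read_direct_targets(path: str | Path) -> DirectTargetSet:
    """Read the hub's ChIP-derived target list (columns hub_id, target_id)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     na_filter=False)
    for col in ("hub_id", "target_id"):
        if col not in df.columns:
            raise ParseError(f"missing column {col!r}", str(path), 1)
    hubs = df["hub_id"].unique().tolist()
    if len(df) == 0:
        raise ParseError("direct-target list is empty", str(path), 1)
    if len(hubs) != 1:
        raise ParseError(f"expected a single hub, found {hubs}", str(path), 1)
    hub = hubs[0]
    targets = set(df["target_id"])
    if hub in targets:
        logger.warning("%s: hub %s listed as its own target; dropped", path, hub)
        targets.discard(hub)
    return DirectTargetSet(hub_id=hub, target_ids=frozenset(targets))


def write_direct_targets(hub_id: str, target_ids, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("hub_id\ttarget_id\n")
        for t in target_ids:
            fh.write(f"{hub_id}\t{t}\n")


# --------------------------------------------------------------- gene sets

def read_gene_sets(path: str | Path) -> PathwayGeneSets:
    """Read a GMT file (name, description, then one member per column)."""
    path = Path(path)
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    sets: dict[str, frozenset] = {}
    for lineno, line in enumerate(lines, start=1):
        cells = line.split("\t")
        if len(cells) < 3:
            raise ParseError(
                f"GMT record needs name, description and >=1 member "
                f"(got {len(cells)} column(s))", str(path), lineno)
        name = cells[0].strip()
        if name in sets:
            raise ParseError(f"duplicate gene-set name {name!r}",
                             str(path), lineno)
        members = frozenset(c.strip() for c in cells[2:] if c.strip())
        sets[name] = members
    if not sets:
        logger.warning("gene-set file %s is empty", path)
    return PathwayGeneSets(sets)


def write_gene_sets(sets, path: str | Path, description: str = "na") -> None:
    items = sets.items() if hasattr(sets, "items") else sets
    with open(path, "w") as fh:
        for name, members in items:
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


# --------------------------------------------------------------- DE tables

_DE_COLUMNS = ["gene_id", "baseMeanA", "baseMeanB", "log2fc", "pvalue",
               "padj", "de_flag"]


def write_de_table(de, path: str | Path) -> None:
    t = de.table.copy()
    t.insert(0, "gene_id", t.index)
    with open(path, "w") as fh:
        fh.write(f"# contrast: {de.contrast[0]} vs {de.contrast[1]}\n")
        t.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_de_table(path: str | Path):
    from .diffexpr import DEResult

    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# contrast:"):
            raise ParseError("missing '# contrast:' header line", str(path), 1)
        cond_a, _, cond_b = first.removeprefix("# contrast:").strip().partition(" vs ")
        df = pd.read_csv(fh, sep="\t", dtype={"gene_id": str, "de_flag": str},
                         keep_default_na=False)
    missing = [c for c in _DE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing column(s) {missing}", str(path), 2)
    df = df.set_index("gene_id")
    return DEResult(contrast=(cond_a, cond_b), table=df)


# ---------------------------------------------------------------- networks

def _export_graph(net: TRN | SubTRN) -> nx.DiGraph:
    """Copy with attribute values coerced to GraphML-safe primitives."""
    g = nx.DiGraph()
    for n in sorted(net.graph.nodes):
        attrs = {k: (bool(v) if isinstance(v, bool) else v)
                 for k, v in net.graph.nodes[n].items() if v is not None}
        g.add_node(n, **attrs)
    for u, v in sorted(net.graph.edges):
        attrs = {k: w for k, w in net.graph.edges[u, v].items()
                 if w is not None}
        g.add_edge(u, v, **attrs)
    return g


def write_network(net: TRN | SubTRN, path: str | Path,
                  fmt: str = "graphml") -> None:
    """Write a (sub-)network as GraphML, SIF or a flat edge table."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(_export_graph(net), path, named_key_ids=True)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v in sorted(net.graph.edges):
                ev = net.graph.edges[u, v].get("evidence", "regulates")
                fh.write(f"{u}\t{ev}\t{v}\n")
    elif fmt == "edge-table":
        with open(path, "w") as fh:
            fh.write("regulator\ttarget\tevidence\trho\tsign\n")
            for u, v in sorted(net.graph.edges):
                d = net.graph.edges[u, v]
                rho = d.get("rho")
                fh.write("\t".join([
                    u, v, str(d.get("evidence", "")),
                    "" if rho is None else f"{rho:.17g}",
                    str(d.get("sign", "")),
                ]) + "\n")
    else:
        raise ValueError(f"unknown network format {fmt!r}; "
                         f"expected one of {NETWORK_FORMATS}")


def read_network_graphml(path: str | Path, contrast: tuple[str, str] = ("", ""),
                         hub_id: str | None = None) -> TRN:
    g = nx.read_graphml(Path(path))
    return TRN(nx.DiGraph(g), contrast=contrast, hub_id=hub_id)
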