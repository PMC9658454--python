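"""Planted regulatory circuits and negative-binomial count simulation.

The generator emulates a three-condition perturbation experiment on a hub
transcription factor: a wild-type reference, a hypomorphic allele expressing
the hub at a reduced dosage, and a null allele with no functional hub. The
hub directly regulates a set of target genes (mostly repressively, mirroring
a repressor TF whose ChIP-defined targets de-repress when it is lost), and a
sparse cascade of downstream TFs regulates further genes.

Mean model
----------
Each gene has a baseline mean ``mu_g`` drawn log-normally. In a condition
with hub dosage ``d`` (reference 1.0, hypomorph 0.3, null 0.0):

* the hub's own mean is ``mu_hub * d``;
* a hub target with edge sign ``s`` (+1 activation, -1 repression) and
  effect ``beta`` (log2 units) has mean ``mu * 2**(-s * beta * (1 - d))``,
  i.e. losing a repressor raises the target four-fold when ``beta = 2``;
* a cascade target responds to its TF's perturbation: if the TF is itself a
  hub target with sign ``s_h``, the cascade target shifts by
  ``-s_h * s * beta * (1 - d)`` log2 units; cascades whose TF is not
  perturbed stay at baseline. Cascade depth is one level by construction.

Counts are drawn negative-binomially with variance ``mu + alpha * mu**2``
(``alpha`` the dispersion); ``alpha = 0`` degenerates to Poisson. Per-sample
library-size factors drawn uniformly from ``lib_size_range`` scale every
mean to exercise normalization downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .matrix import (CONDITIONS, HYPOMORPH, NULL, REFERENCE, ExpressionMatrix,
                     SampleDesign)

DEFAULT_DOSAGE = {REFERENCE: 1.0, HYPOMORPH: 0.3, NULL: 0.0}

#: pathway-set names for the five developmental events the analysis tracks
DEFAULT_PATHWAY_NAMES = (
    "chloroplast_development",
    "oxidation_reduction",
    "cell_cycle",
    "meiosis",
    "tapetum_differentiation",
)


class PlantedEdge(NamedTuple):
    regulator: str
    target: str
    sign: int          # +1 activation, -1 repression
    effect: float      # log2 units, >= 0


def _gene_id(i: int) -> str:
    return f"G{i:06d}"


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth circuit: who regulates whom, how strongly, and the
    experimental dosage/dispersion regime."""

    hub_id: str
    direct_edges: tuple[PlantedEdge, ...]
    cascade_edges: tuple[PlantedEdge, ...]
    tf_ids: frozenset[str]
    n_genes: int
    dosage: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DOSAGE))
    dispersion: float = 0.05
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.hub_id not in self.tf_ids:
            raise ValueError("hub must be among the TF identifiers")
        all_edges = self.direct_edges + self.cascade_edges
        pairs = [(e.regulator, e.target) for e in all_edges]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (regulator, target) pairs")
        if any(r == t for r, t in pairs):
            raise ValueError("self-edges are not allowed")
        if any(e.effect < 0 for e in all_edges):
            raise ValueError("edge effects must be nonnegative")
        if any(e.sign not in (-1, 1) for e in all_edges):
            raise ValueError("edge signs must be +1 or -1")
        if self.dosage.get(REFERENCE) != 1.0:
            raise ValueError("reference dosage must be 1.0")
        if any(not (0.0 <= d <= 1.0) for d in self.dosage.values()):
            raise ValueError("dosages must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(_gene_id(i) for i in range(1, self.n_genes + 1))

    @property
    def direct_target_ids(self) -> frozenset[str]:
        return frozenset(e.target for e in self.direct_edges)

    def baseline_means(self) -> pd.Series:
        """Per-gene baseline means, a deterministic function of the truth seed."""
        rng = np.random.default_rng(self.seed)
        mu = rng.lognormal(self.baseline_log_mean, self.baseline_log_sd,
                           self.n_genes)
        return pd.Series(mu, index=list(self.gene_ids))

    def condition_means(self, condition: str) -> pd.Series:
        """Expected (pre-library-size) counts per gene in one condition."""
        if condition not in self.dosage:
            raise ConfigurationError(f"condition {condition!r} has no dosage")
        d = self.dosage[condition]
        mu = self.baseline_means().copy()
        shift = pd.Series(0.0, index=mu.index)
        hub_sign = {e.target: e.sign for e in self.direct_edges}
        for e in self.direct_edges:
            shift[e.target] += -e.sign * e.effect * (1.0 - d)
        for e in self.cascade_edges:
            s_h = hub_sign.get(e.regulator)
            if s_h is not None:
                shift[e.target] += -s_h * e.sign * e.effect * (1.0 - d)
        mu *= np.power(2.0, shift)
        mu[self.hub_id] = self.baseline_means()[self.hub_id] * d
        return mu

    def to_dict(self) -> dict:
        out = asdict(self)
        out["tf_ids"] = sorted(self.tf_ids)
        out["direct_edges"] = [list(e) for e in self.direct_edges]
        out["cascade_edges"] = [list(e) for e in self.cascade_edges]
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(
            hub_id=d["hub_id"],
            direct_edges=tuple(PlantedEdge(r, t, int(s), float(b))
                               for r, t, s, b in d["direct_edges"]),
            cascade_edges=tuple(PlantedEdge(r, t, int(s), float(b))
                                for r, t, s, b in d["cascade_edges"]),
            tf_ids=frozenset(d["tf_ids"]),
            n_genes=int(d["n_genes"]),
            dosage=dict(d["dosage"]),
            dispersion=float(d["dispersion"]),
            baseline_log_mean=float(d["baseline_log_mean"]),
            baseline_log_sd=float(d["baseline_log_sd"]),
            seed=int(d["seed"]),
        )


def generate_truth(
    n_genes: int = 2000,
    n_tfs: int = 50,
    n_direct_targets: int = 61,
    repression_fraction: float = 0.7,
    effect_log2: float = 2.0,
    seed: int = 0,
    *,
    cascade_targets_per_tf: int = 3,
    dosage: dict[str, float] | None = None,
    dispersion: float = 0.05,
    baseline_log_mean: float = 4.0,
    baseline_log_sd: float = 1.0,
) -> SyntheticTruth:
    """Draw a planted circuit.

    The hub gets exactly ``n_direct_targets`` edges, of which
    ``round(repression_fraction * n_direct_targets)`` are repressive. The
    remaining TFs are drawn preferentially from the hub's targets (so their
    own regulons respond to the perturbation) and each regulates
    ``cascade_targets_per_tf`` further genes.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    if n_tfs < 1:
        raise ValueError("need at least one TF (the hub)")
    if not (0.0 <= repression_fraction <= 1.0):
        raise ValueError("repression_fraction must be in [0, 1]")
    if n_direct_targets > n_genes - 1:
        raise ValueError("n_direct_targets must leave room for the hub")
    if effect_log2 < 0:
        raise ValueError("effect_log2 must be nonnegative")
    if n_tfs > n_genes:
        raise ValueError("cannot have more TFs than genes")

    rng = np.random.default_rng(seed)
    genes = np.array([_gene_id(i) for i in range(1, n_genes + 1)])
    hub = str(rng.choice(genes))
    non_hub = genes[genes != hub]

    targets = rng.choice(non_hub, size=n_direct_targets, replace=False)
    n_neg = int(round(repression_fraction * n_direct_targets))
    signs = np.array([-1] * n_neg + [1] * (n_direct_targets - n_neg))
    rng.shuffle(signs)
    direct = tuple(PlantedEdge(hub, str(t), int(s), float(effect_log2))
                   for t, s in zip(targets, signs))

    # non-hub TFs: prefer hub targets so the cascade is perturbation-responsive
    n_other_tfs = n_tfs - 1
    pool = list(targets)
    rest = [g for g in non_hub if g not in set(targets)]
    if n_other_tfs <= len(pool):
        other_tfs = list(rng.choice(np.array(pool), size=n_other_tfs,
                                    replace=False)) if n_other_tfs else []
    else:
        extra = rng.choice(np.array(rest), size=n_other_tfs - len(pool),
                           replace=False)
        other_tfs = pool + list(extra)
    tf_ids = frozenset([hub] + [str(t) for t in other_tfs])

    cascade: list[PlantedEdge] = []
    seen: set[tuple[str, str]] = set()
    for tf in other_tfs:
        tf = str(tf)
        candidates = non_hub[non_hub != tf]
        chosen = rng.choice(candidates, size=min(cascade_targets_per_tf,
                                                 len(candidates)),
                            replace=False)
        for tgt in chosen:
            pair = (tf, str(tgt))
            if pair in seen:
                continue
            seen.add(pair)
            sign = -1 if rng.random() < repression_fraction else 1
            cascade.append(PlantedEdge(tf, str(tgt), sign, float(effect_log2)))

    return SyntheticTruth(
        hub_id=hub,
        direct_edges=direct,
        cascade_edges=tuple(cascade),
        tf_ids=tf_ids,
        n_genes=n_genes,
        dosage=dict(dosage) if dosage is not None else dict(DEFAULT_DOSAGE),
        dispersion=dispersion,
        baseline_log_mean=baseline_log_mean,
        baseline_log_sd=baseline_log_sd,
        seed=seed,
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """NB draws with variance mu + dispersion * mu^2; Poisson when dispersion=0."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if dispersion <= 0:
        out[pos] = rng.poisson(mean[pos])
    else:
        n = 1.0 / dispersion
        p = n / (n + mean[pos])
        out[pos] = rng.negative_binomial(n, p)
    return out


def simulate_counts(
    truth: SyntheticTruth,
    design: SampleDesign | None = None,
    lib_size_range: tuple[float, float] = (0.8, 1.2),
    seed: int = 0,
) -> ExpressionMatrix:
    """Simulate the count matrix for every sample in the design.

    Baseline means are a function of ``truth.seed``; sampling noise and
    library-size factors are a function of ``seed``, so one circuit can be
    re-sequenced under independent noise realizations.
    """
    if design is None:
        design = SampleDesign.default()
    lo, hi = lib_size_range
    if not (0 < lo <= hi):
        raise ValueError("lib_size_range must be positive with lo <= hi")
    unknown = [c for c in design.conditions if c not in truth.dosage]
    if unknown:
        raise ConfigurationError(
            f"design conditions without a dosage in the truth: {unknown}")

    rng = np.random.default_rng(seed)
    cond_means = {c: truth.condition_means(c).to_numpy()
                  for c in design.conditions}
    lib = rng.uniform(lo, hi, size=len(design.samples))

    columns = {}
    for j, sample in enumerate(design.samples):
        mu = cond_means[design.condition_of[sample]] * lib[j]
        columns[sample] = _nb_draw(rng, mu, truth.dispersion)
    data = pd.DataFrame(columns, index=list(truth.gene_ids))
    return ExpressionMatrix(data, raw=True)


def _assign_pathway_sets(truth: SyntheticTruth, n_sets: int,
                         genes_per_set: int) -> dict[str, list[str]]:
    """Deterministically carve pathway sets out of the perturbed genes."""
    pool = sorted(set(e.target for e in truth.direct_edges)
                  | set(e.target for e in truth.cascade_edges))
    rng = np.random.default_rng(truth.seed + 1)
    rng.shuffle(pool)
    names = DEFAULT_PATHWAY_NAMES[:n_sets]
    sets: dict[str, list[str]] = {name: [] for name in names}
    for i, gene in enumerate(pool):
        name = names[i % len(names)]
        if len(sets[name]) < genes_per_set:
            sets[name].append(gene)
    return {name: sorted(members) for name, members in sets.items()}


def write_fixture_bundle(
    truth: SyntheticTruth,
    matrix: ExpressionMatrix,
    design: SampleDesign,
    outdir: str | Path,
    *,
    genes_per_set: int = 12,
) -> dict[str, Path]:
    """Write every file the downstream pipeline reads; returns the manifest.

    Files: count matrix and design sheet (TSV), motif-evidence regulation
    catalog from the cascade edges, ChIP-evidence direct-target list for the
    hub, pathway gene sets (GMT, five developmental events), and the truth
    itself (JSON). Pathway sets with no eligible members are omitted rather
    than written empty.
    """
    from . import io as tio  # local import to avoid a cycle at import time

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}

    manifest["counts"] = outdir / "counts.tsv"
    tio.write_expression_matrix(matrix, manifest["counts"])
    manifest["design"] = outdir / "design.tsv"
    tio.write_sample_design(design, manifest["design"])

    manifest["catalog"] = outdir / "regulation_catalog.tsv"
    cascade_pairs = sorted((e.regulator, e.target) for e in truth.cascade_edges)
    tio.write_regulation_catalog(cascade_pairs, manifest["catalog"])

    manifest["direct_targets"] = outdir / "direct_targets.tsv"
    tio.write_direct_targets(truth.hub_id, sorted(truth.direct_target_ids),
                             manifest["direct_targets"])

    manifest["gene_sets"] = outdir / "pathways.gmt"
    sets = _assign_pathway_sets(truth, len(DEFAULT_PATHWAY_NAMES), genes_per_set)
    nonempty = {k: v for k, v in sets.items() if v}
    tio.write_gene_sets(nonempty, manifest["gene_sets"])

    manifest["truth"] = outdir / "truth.json"
    with open(manifest["truth"], "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
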