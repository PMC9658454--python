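"""Shared fixtures: small planted circuits and a bank of default-scale runs."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

import trncontrast as tc


@pytest.fixture()
def default_design() -> tc.SampleDesign:
    return tc.SampleDesign.default()


@pytest.fixture()
def small_truth() -> tc.SyntheticTruth:
    return tc.generate_truth(n_genes=300, n_tfs=10, n_direct_targets=20,
                             seed=7)


@pytest.fixture()
def small_norm(small_truth, default_design):
    counts = tc.simulate_counts(small_truth, default_design, seed=11)
    _, norm = tc.normalize_size_factors(counts)
    return norm


@dataclass
class SeededRun:
    """One default-scale simulated experiment, fully analyzed."""

    truth: tc.SyntheticTruth
    design: tc.SampleDesign
    counts: tc.ExpressionMatrix
    norm: tc.ExpressionMatrix
    de: dict            # condition -> DEResult
    trn: dict           # condition -> TRN
    direct: tc.DirectTargetSet
    catalog: tc.RegulationCatalog


def analyze_seed(seed: int, **truth_kwargs) -> SeededRun:
    """Simulate and analyze one experiment at generator defaults."""
    truth = tc.generate_truth(seed=seed, **truth_kwargs)
    design = tc.SampleDesign.default()
    counts = tc.simulate_counts(truth, design, seed=seed + 10_000)
    _, norm = tc.normalize_size_factors(counts)
    catalog = tc.RegulationCatalog(
        tuple((e.regulator, e.target) for e in truth.cascade_edges))
    direct = tc.DirectTargetSet(truth.hub_id, truth.direct_target_ids)
    de = {}
    trn = {}
    for cond in ("hypomorph", "null"):
        de[cond] = tc.test_differential_expression(
            norm, design, ("reference", cond))
        trn[cond] = tc.build_trn(norm, design, catalog, direct, de[cond])
    return SeededRun(truth, design, counts, norm, de, trn, direct, catalog)


@pytest.fixture(scope="session")
def ten_seed_runs() -> list[SeededRun]:
    """Ten independent experiments at generator defaults (2000 genes,
    50 TFs, 61 direct targets, effect 2.0, dispersion 0.05, dosages
    1.0/0.3/0.0)."""
    return [analyze_seed(seed) for seed in range(10)]


def random_expression(rng: np.random.Generator, genes: list[str],
                      samples: int = 9, ties: bool = True) -> tc.ExpressionMatrix:
    """Random nonnegative expression with occasional ties, raw counts."""
    x = rng.poisson(30.0, size=(len(genes), samples)).astype(float)
    if ties:
        mask = rng.random(x.shape) < 0.2
        x[mask] = np.round(x[mask] / 5) * 5
    return tc.ExpressionMatrix(
        pd.DataFrame(x, index=genes,
                     columns=[f"s{i}" for i in range(samples)]),
        raw=True)
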