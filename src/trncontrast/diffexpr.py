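"""Normalization and differential-expression calls per contrast.

Counts are normalized by median-of-ratios size factors (each sample's factor
is the median, over genes expressed in every sample, of its counts divided
by the gene's geometric mean). Per-contrast testing runs on
log2(normalized + pseudocount) values through one of two engines behind the
same interface:

``moderated`` (default)
    A trended empirical-Bayes pooled-variance t-test: gene-wise residual
    variances are smoothed against mean log-expression (lowess), the prior
    degrees of freedom are estimated by moments on log-variances, and each
    gene's variance is squeezed toward the trend before forming the t
    statistic. With 2-4 replicates per group this borrowing of strength is
    what makes FDR-controlled calls possible at all.

``welch``
    A per-gene two-sided Welch t-test. Kept for its transparency; with
    these replicate numbers it has essentially no power after multiple-
    testing adjustment, so it suits large-replicate designs only.

A gene is called DE when padj < 0.05 and linear fold change exceeds 2
(|log2FC| > 1), both strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .config import AnalysisConfig
from .errors import NormalizationError
from .matrix import ExpressionMatrix, SampleDesign

UP = "up"
DOWN = "down"
NOT_DE = "not_de"


@dataclass(frozen=True)
class DEResult:
    """Per-gene differential-expression statistics for one contrast.

    ``contrast`` is ``(condition_A, condition_B)``; log2fc is B over A, so
    with A the wild-type reference, positive log2fc means up in the mutant.
    ``table`` is indexed by gene with columns baseMeanA, baseMeanB, log2fc,
    pvalue, padj, de_flag.
    """

    contrast: tuple[str, str]
    table: pd.DataFrame

    @property
    def de_genes(self) -> frozenset:
        return frozenset(self.table.index[self.table["de_flag"] != NOT_DE])

    @property
    def up_genes(self) -> frozenset:
        return frozenset(self.table.index[self.table["de_flag"] == UP])

    @property
    def down_genes(self) -> frozenset:
        return frozenset(self.table.index[self.table["de_flag"] == DOWN])

    def flag_of(self, gene: str) -> str:
        if gene in self.table.index:
            return str(self.table.at[gene, "de_flag"])
        return NOT_DE


def normalize_size_factors(
    counts: ExpressionMatrix,
) -> tuple[pd.Series, ExpressionMatrix]:
    """Median-of-ratios size factors and the normalized matrix.

    Only genes with nonzero counts in every sample contribute to the
    medians (their geometric mean is finite and positive).
    """
    if not counts.raw:
        raise ValueError("size factors are defined on raw counts")
    x = counts.data.to_numpy(dtype=float)
    expressed = (x > 0).all(axis=1)
    if not expressed.any():
        raise NormalizationError(
            "no gene has nonzero counts in every sample; "
            "size factors are undefined")
    logx = np.log(x[expressed])
    log_gm = logx.mean(axis=1)
    ratios = np.exp(logx - log_gm[:, None])
    factors = np.median(ratios, axis=0)
    fac = pd.Series(factors, index=counts.data.columns, name="size_factor")
    norm = ExpressionMatrix(counts.data / factors, raw=False)
    return fac, norm


def adjust_benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving.

    Implements min over j >= i of m * p_(j) / j on the sorted p-values,
    clipped to 1, then undoes the sort.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a one-dimensional p-value vector")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = m * p[order] / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _welch_pvalues(la: np.ndarray, lb: np.ndarray) -> np.ndarray:
    """Two-sided Welch t on log2 values; degenerate variances handled."""
    va = la.var(axis=1, ddof=1)
    vb = lb.var(axis=1, ddof=1)
    both_const = (va == 0) & (vb == 0)
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), \
            warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(lb, la, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    equal_means = np.isclose(la.mean(axis=1), lb.mean(axis=1))
    p[both_const & equal_means] = 1.0
    p[both_const & ~equal_means] = 0.0
    return np.nan_to_num(p, nan=1.0)


def _fit_inverse_chisq_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to residual variances.

    Returns (prior df d0, prior variance s0sq); d0 = inf means the
    variances are consistent with a single common value.
    """
    s2 = s2[s2 > 0]
    if s2.size < 2:
        return np.inf, float(s2.mean()) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = e.var(ddof=1) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(e.mean()))
    lo, hi = 1e-3, 1e8
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if special.polygamma(1, mid / 2.0) > evar:
            lo = mid
        else:
            hi = mid
    d0 = float(np.sqrt(lo * hi))
    s0 = float(np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0


def _moderated_pvalues(la: np.ndarray, lb: np.ndarray) -> np.ndarray:
    """Trended empirical-Bayes pooled-variance t-test on log2 values."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    n1, n2 = la.shape[1], lb.shape[1]
    df = n1 + n2 - 2
    m1, m2 = la.mean(axis=1), lb.mean(axis=1)
    ss = ((la - m1[:, None]) ** 2).sum(axis=1) + ((lb - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / df
    n_genes = la.shape[0]

    floor = 1e-10
    if n_genes >= 10:
        amean = np.concatenate([la, lb], axis=1).mean(axis=1)
        trend = lowess(np.log(np.maximum(s2, floor)), amean, frac=0.5,
                       return_sorted=False)
        # E[log s^2] understates log sigma^2 by psi(df/2) - log(df/2);
        # undo that bias so the trend estimates the variance itself
        bias = float(special.digamma(df / 2.0) - np.log(df / 2.0))
        s0sq = np.maximum(np.exp(trend - bias), floor)
        d0, _ = _fit_inverse_chisq_prior(s2 / s0sq, df)
    else:
        d0, s0 = _fit_inverse_chisq_prior(s2, df)
        s0sq = np.full(n_genes, max(s0, floor))

    if np.isfinite(d0):
        post = (d0 * s0sq + df * s2) / (d0 + df)
        df_total = d0 + df
    else:
        post = s0sq
        df_total = np.inf
    se = np.sqrt(post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m2 - m1) / se
    t = np.nan_to_num(t, nan=0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return p


def test_differential_expression(
    norm: ExpressionMatrix,
    design: SampleDesign,
    contrast: tuple[str, str],
    config: AnalysisConfig | None = None,
) -> DEResult:
    """Test every gene for differential expression between two conditions.

    Genes with zero counts in both groups are dropped before testing.
    The returned table already carries BH-adjusted p-values and DE flags.
    """
    if config is None:
        config = AnalysisConfig()
    cond_a, cond_b = contrast
    samples_a = design.samples_for(cond_a)
    samples_b = design.samples_for(cond_b)
    for cond, smp in ((cond_a, samples_a), (cond_b, samples_b)):
        if len(smp) < 2:
            raise ValueError(
                f"condition {cond!r} has {len(smp)} replicate(s); "
                "at least 2 are required for within-group degrees of freedom")
    missing = [s for s in samples_a + samples_b if s not in norm.data.columns]
    if missing:
        raise ValueError(f"samples missing from the matrix: {missing}")

    a = norm.data[list(samples_a)].to_numpy(dtype=float)
    b = norm.data[list(samples_b)].to_numpy(dtype=float)
    keep = (a.sum(axis=1) + b.sum(axis=1)) > 0
    genes = norm.data.index[keep]
    a, b = a[keep], b[keep]

    pc = config.pseudocount
    la, lb = np.log2(a + pc), np.log2(b + pc)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = np.log2((mean_b + pc) / (mean_a + pc))

    if config.engine == "welch":
        pvalue = _welch_pvalues(la, lb)
    else:
        pvalue = _moderated_pvalues(la, lb)
    pvalue = np.clip(pvalue, 0.0, 1.0)
    padj = adjust_benjamini_hochberg(pvalue)

    table = pd.DataFrame(
        {"baseMeanA": mean_a, "baseMeanB": mean_b, "log2fc": log2fc,
         "pvalue": pvalue, "padj": padj, "de_flag": NOT_DE},
        index=genes,
    )
    result = DEResult(contrast=(cond_a, cond_b), table=table)
    return flag_de(result, config)


def flag_de(result: DEResult, config: AnalysisConfig | None = None) -> DEResult:
    """Set up/down/not_de flags with strict thresholds.

    up:   padj < padj_threshold and linear FC > fc_threshold
    down: padj < padj_threshold and linear FC < 1/fc_threshold
    """
    if config is None:
        config = AnalysisConfig()
    lfc_cut = np.log2(config.fc_threshold)
    t = result.table.copy()
    sig = t["padj"] < config.padj_threshold
    flags = np.where(sig & (t["log2fc"] > lfc_cut), UP,
                     np.where(sig & (t["log2fc"] < -lfc_cut), DOWN, NOT_DE))
    t["de_flag"] = flags
    return DEResult(contrast=result.contrast, table=t)


def de_union(*results: DEResult) -> frozenset:
    """Genes DE in at least one of the given contrasts."""
    out: set = set()
    for r in results:
        out |= r.de_genes
    return frozenset(out)
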