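"""Analysis thresholds shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, asdict


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds for differential-expression calls and edge retention.

    Attributes
    ----------
    padj_threshold
        BH-adjusted p-value cutoff; a gene is differentially expressed only
        if padj is strictly below this.
    fc_threshold
        Linear fold-change cutoff; DE requires linear |FC| strictly above
        this (equivalently |log2FC| > log2(fc_threshold)).
    rho_threshold
        Absolute Spearman correlation required to retain a regulatory edge.
    correlation_inclusive
        If True (default) an edge with |rho| exactly equal to the threshold
        is retained; if False the comparison is strict.
    pseudocount
        Added before every log2 transform of expression values.
    engine
        Differential-expression engine: ``"moderated"`` (trended
        empirical-Bayes pooled-variance t, the default) or ``"welch"``
        (per-gene Welch t on log2 values).
    """

    padj_threshold: float = 0.05
    fc_threshold: float = 2.0
    rho_threshold: float = 0.25
    correlation_inclusive: bool = True
    pseudocount: float = 1.0
    engine: str = "moderated"

    def __post_init__(self):
        if not (0 < self.padj_threshold <= 1):
            raise ValueError("padj_threshold must be in (0, 1]")
        if self.fc_threshold <= 0:
            raise ValueError("fc_threshold must be positive")
        if not (0 < self.rho_threshold <= 1):
            raise ValueError("rho_threshold must be in (0, 1]")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.engine not in ("moderated", "welch"):
            raise ValueError(f"unknown engine {self.engine!r}")

    def to_dict(self) -> dict:
        return asdict(self)
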