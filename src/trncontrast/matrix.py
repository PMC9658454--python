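"""Expression-matrix and sample-design containers.

The experiment layout mirrors a three-condition perturbation study of a hub
transcription factor: a wild-type reference, a hypomorphic allele in which the
hub is still expressed at reduced dosage, and a null allele in which it is
absent. The canonical design has 3, 4 and 2 biological replicates for the
three conditions respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REFERENCE = "reference"
HYPOMORPH = "hypomorph"
NULL = "null"
CONDITIONS = (REFERENCE, HYPOMORPH, NULL)

#: replicate counts for (reference, hypomorph, null)
DEFAULT_REPLICATES = {REFERENCE: 3, HYPOMORPH: 4, NULL: 2}


@dataclass(frozen=True)
class SampleDesign:
    """Ordered samples and their condition labels.

    Parameters
    ----------
    samples
        Ordered, unique sample identifiers.
    condition_of
        Mapping sample -> condition label. Every sample must appear exactly
        once; conditions are arbitrary labels, but the default design uses
        ``reference`` / ``hypomorph`` / ``null``.
    """

    samples: tuple[str, ...]
    condition_of: dict[str, str] = field(compare=True)

    def __post_init__(self):
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers in design")
        missing = [s for s in self.samples if s not in self.condition_of]
        if missing:
            raise ValueError(f"samples without a condition: {missing}")
        extra = set(self.condition_of) - set(self.samples)
        if extra:
            raise ValueError(f"conditions given for unknown samples: {sorted(extra)}")

    @classmethod
    def default(cls) -> "SampleDesign":
        """The canonical 3/4/2 design over reference/hypomorph/null."""
        return cls.from_replicates(DEFAULT_REPLICATES)

    @classmethod
    def from_replicates(cls, replicates: dict[str, int]) -> "SampleDesign":
        samples: list[str] = []
        cond: dict[str, str] = {}
        for condition, n in replicates.items():
            if n < 0:
                raise ValueError(f"negative replicate count for {condition!r}")
            for i in range(1, n + 1):
                name = f"{condition}_{i}"
                samples.append(name)
                cond[name] = condition
        return cls(tuple(samples), cond)

    @property
    def conditions(self) -> tuple[str, ...]:
        """Condition labels in order of first appearance."""
        seen: list[str] = []
        for s in self.samples:
            c = self.condition_of[s]
            if c not in seen:
                seen.append(c)
        return tuple(seen)

    def samples_for(self, condition: str) -> tuple[str, ...]:
        return tuple(s for s in self.samples if self.condition_of[s] == condition)

    @property
    def replicate_counts(self) -> dict[str, int]:
        return {c: len(self.samples_for(c)) for c in self.conditions}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample": list(self.samples),
             "condition": [self.condition_of[s] for s in self.samples]}
        )


class ExpressionMatrix:
    """Gene-by-sample matrix of nonnegative expression values.

    ``raw=True`` marks integer counts straight from quantification;
    normalized or otherwise transformed matrices carry ``raw=False``.
    """

    def __init__(self, data: pd.DataFrame, raw: bool = True):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        values = data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("expression values must be finite")
        if (values < 0).any():
            raise ValueError("expression values must be nonnegative")
        if raw and not np.allclose(values, np.round(values)):
            raise ValueError("raw counts must be integer-valued")
        self.data = data.astype(int) if raw else data.astype(float)
        self.raw = raw

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def log2(self, pseudocount: float = 1.0) -> pd.DataFrame:
        """log2(value + pseudocount), as a DataFrame aligned with the matrix."""
        return np.log2(self.data + pseudocount)

    def check_design(self, design: SampleDesign) -> None:
        """Verify the design covers exactly this matrix's samples, in order."""
        if tuple(design.samples) != self.sample_ids:
            raise ValueError(
                "sample design does not match matrix columns: "
                f"{design.samples} vs {self.sample_ids}"
            )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kind = "raw counts" if self.raw else "normalized"
        return f"ExpressionMatrix({self.shape[0]} genes x {self.shape[1]} samples, {kind})"
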