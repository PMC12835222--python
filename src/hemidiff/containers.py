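"""Core in-memory containers shared across the pipeline.

The pipeline moves between three representations of the same gene x sample
grid: raw integer counts, normalization factors attached to those counts,
and real-valued expression matrices on a named scale (``cpm``, ``log2cpm``
or ``corrected``).  All of them keep genes on rows and samples on columns
and carry stable string identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "NormFactors",
    "GeneSetCollection",
]


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} identifiers: {dups[:5]}")


@dataclass
class CountMatrix:
    """Gene x sample matrix of nonnegative integer counts."""

    gene_ids: pd.Index
    sample_ids: pd.Index
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = pd.Index(self.gene_ids, dtype=object)
        self.sample_ids = pd.Index(self.sample_ids, dtype=object)
        self.counts = np.asarray(self.counts)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if np.issubdtype(self.counts.dtype, np.floating):
            if not np.all(self.counts == np.round(self.counts)):
                bad = np.argwhere(self.counts != np.round(self.counts))
                cells = [
                    (self.gene_ids[i], self.sample_ids[j]) for i, j in bad[:5]
                ]
                raise ValueError(f"non-integer count entries at {cells}")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            bad = np.argwhere(self.counts < 0)
            cells = [(self.gene_ids[i], self.sample_ids[j]) for i, j in bad[:5]]
            raise ValueError(f"negative count entries at {cells}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.gene_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(df.index, df.columns, df.to_numpy())

    def subset_genes(self, genes) -> "CountMatrix":
        idx = self.gene_ids.get_indexer(pd.Index(genes))
        if (idx < 0).any():
            missing = list(pd.Index(genes)[idx < 0][:5])
            raise KeyError(f"genes not present: {missing}")
        return CountMatrix(pd.Index(genes), self.sample_ids, self.counts[idx])

    def subset_samples(self, samples) -> "CountMatrix":
        idx = self.sample_ids.get_indexer(pd.Index(samples))
        if (idx < 0).any():
            missing = list(pd.Index(samples)[idx < 0][:5])
            raise KeyError(f"samples not present: {missing}")
        return CountMatrix(self.gene_ids, pd.Index(samples), self.counts[:, idx])

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.gene_ids.equals(other.gene_ids)
            and self.sample_ids.equals(other.sample_ids)
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class ExpressionMatrix:
    """Real-valued expression on a declared scale.

    ``scale`` is one of ``cpm``, ``log2cpm`` or ``corrected``.  Statistical
    testing happens only on ``log2cpm``; ``corrected`` is an exp-scale
    display matrix with nuisance structure regressed out.
    """

    gene_ids: pd.Index
    sample_ids: pd.Index
    values: np.ndarray
    scale: str

    VALID_SCALES = ("cpm", "log2cpm", "corrected")

    def __post_init__(self) -> None:
        self.gene_ids = pd.Index(self.gene_ids, dtype=object)
        self.sample_ids = pd.Index(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in self.VALID_SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("expression matrix shape mismatch")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.sample_ids
        )

    def subset_genes(self, genes) -> "ExpressionMatrix":
        idx = self.gene_ids.get_indexer(pd.Index(genes))
        if (idx < 0).any():
            missing = list(pd.Index(genes)[idx < 0][:5])
            raise KeyError(f"genes not present: {missing}")
        return ExpressionMatrix(
            pd.Index(genes), self.sample_ids, self.values[idx], self.scale
        )

    def subset_samples(self, samples) -> "ExpressionMatrix":
        idx = self.sample_ids.get_indexer(pd.Index(samples))
        if (idx < 0).any():
            missing = list(pd.Index(samples)[idx < 0][:5])
            raise KeyError(f"samples not present: {missing}")
        return ExpressionMatrix(
            self.gene_ids, pd.Index(samples), self.values[:, idx], self.scale
        )


@dataclass
class NormFactors:
    """Per-sample TMM scaling factors, geometric mean constrained to 1."""

    sample_ids: pd.Index
    factors: np.ndarray
    reference_sample: str

    def __post_init__(self) -> None:
        self.sample_ids = pd.Index(self.sample_ids, dtype=object)
        self.factors = np.asarray(self.factors, dtype=float)
        if np.any(self.factors <= 0):
            raise ValueError("scaling factors must be positive")
        gm = np.exp(np.mean(np.log(self.factors)))
        if abs(gm - 1.0) > 1e-8:
            raise ValueError(f"geometric mean of factors is {gm}, expected 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "factor": self.factors}
        )


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions, GMT-style."""

    sets: dict = field(default_factory=dict)
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            self.descriptions.setdefault(name, "")

    def __getitem__(self, name: str):
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def names(self):
        return list(self.sets)
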