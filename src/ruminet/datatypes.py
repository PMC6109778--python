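"""Core containers shared across the pipeline.

Counts and phenotypes are thin, validated wrappers around numpy/pandas
objects rather than free-floating DataFrames, so that invariants (unique
identifiers, non-negative counts, positive library sizes) are enforced once
at construction and every downstream stage can rely on them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: phenotype columns the pipeline knows how to interpret
KNOWN_PHENOTYPES = (
    "ch4_production",  # g/day
    "ch4_yield",       # g/day per kg DMI
    "dmi",             # kg/day
    "acetate",         # mM
    "butyrate",        # mM
    "propionate",      # mM
    "mrt",             # hours; measured in the AUS-like experiment only
    "muscle_depth",    # mm; optional
)


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _check_unique(ids, kind: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {kind} id {i!r}")
        seen.add(i)


@dataclass
class CountMatrix:
    """Raw gene x sample counts with per-sample library sizes.

    ``library_sizes`` defaults to the column sums; a user-supplied override
    is allowed (e.g. to mimic externally computed totals) but must be
    strictly positive.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    library_sizes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_ids = list(map(str, self.gene_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape != (
            len(self.gene_ids),
            len(self.sample_ids),
        ):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.gene_ids) == 0:
            raise ValidationError("no genes")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                bad = np.argwhere(np.mod(self.counts, 1) != 0)[0]
                raise ValidationError(
                    f"non-integer count at gene {self.gene_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            bad = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(np.int64)
        else:
            self.library_sizes = np.asarray(self.library_sizes, dtype=np.int64)
        if self.library_sizes.shape != (len(self.sample_ids),):
            raise ValidationError("library_sizes length does not match samples")
        if np.any(self.library_sizes <= 0):
            bad = int(np.argmax(self.library_sizes <= 0))
            raise ValidationError(
                f"non-positive library size for sample {self.sample_ids[bad]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_genes(self, genes: list[str]) -> "CountMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise ValidationError(f"unknown genes: {missing[:5]}")
        rows = [index[g] for g in genes]
        return CountMatrix(
            gene_ids=list(genes),
            sample_ids=list(self.sample_ids),
            counts=self.counts[rows, :],
            library_sizes=self.library_sizes.copy(),
        )

    def subset_samples(self, samples: list[str]) -> "CountMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in index]
        if missing:
            raise ValidationError(f"unknown samples: {missing[:5]}")
        cols = [index[s] for s in samples]
        return CountMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=list(samples),
            counts=self.counts[:, cols],
            library_sizes=self.library_sizes[cols],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class ExpressionMatrix:
    """log2-scale expression values; same axes as the source counts.

    ``provenance`` records the normalization chain, e.g.
    ``["logcpm", "quantile_joint", "muscle_normalized"]``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    provenance: list[str] = field(default_factory=list)
    dataset_labels: list[str] | None = None  # per-sample, for joint matrices

    def __post_init__(self) -> None:
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError("values shape does not match gene/sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite expression values")
        if self.dataset_labels is not None and len(self.dataset_labels) != len(
            self.sample_ids
        ):
            raise ValidationError("dataset_labels length does not match samples")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        index = self.gene_index()
        rows = [index[g] for g in genes]
        return ExpressionMatrix(
            gene_ids=list(genes),
            sample_ids=list(self.sample_ids),
            values=self.values[rows, :],
            provenance=list(self.provenance),
            dataset_labels=None if self.dataset_labels is None else list(self.dataset_labels),
        )

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [index[s] for s in samples]
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=list(samples),
            values=self.values[:, cols],
            provenance=list(self.provenance),
            dataset_labels=None
            if self.dataset_labels is None
            else [self.dataset_labels[c] for c in cols],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class PhenotypeTable:
    """Per-sample phenotype records for one experiment.

    Stored as a DataFrame indexed by sample id. Missing values are NaN and
    are dropped pairwise by downstream analyses — never silently zeroed.
    """

    data: pd.DataFrame
    dataset: str = "A"
    extras: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        # consistency of derived trait: yield should be production / intake
        cols = self.data.columns
        if {"ch4_production", "ch4_yield", "dmi"} <= set(cols):
            with np.errstate(invalid="ignore", divide="ignore"):
                implied = self.data["ch4_production"] / self.data["dmi"]
            rel = np.abs(implied - self.data["ch4_yield"]) / np.abs(implied)
            bad = rel.dropna() > 0.05
            if bad.any():
                warnings.warn(
                    f"ch4_yield inconsistent with ch4_production/dmi (>5%) for "
                    f"{int(bad.sum())} samples, e.g. {bad.index[bad][0]!r}; "
                    "values kept as provided",
                    stacklevel=2,
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def has(self, phenotype: str) -> bool:
        return phenotype in self.data.columns and self.data[phenotype].notna().any()

    def column(self, phenotype: str) -> pd.Series:
        if phenotype not in self.data.columns:
            raise KeyError(f"phenotype {phenotype!r} not present")
        return self.data[phenotype]

    def aligned(self, sample_ids: list[str]) -> "PhenotypeTable":
        orphans = [s for s in sample_ids if s not in self.data.index]
        if orphans:
            raise ValidationError(f"samples missing from phenotype table: {orphans[:5]}")
        return PhenotypeTable(
            data=self.data.loc[sample_ids].copy(), dataset=self.dataset, extras=list(self.extras)
        )
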