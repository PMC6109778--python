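"""Count normalization: CPM filtering, log-CPM transform, joint quantile
normalization and muscle-signature centering.

The log-CPM transform is ``log2((count + 0.5) / (library_size + 1) * 1e6)``,
the standard variance-stabilizing transform for bulk RNA-seq counts prior to
linear modelling. Precision weights are deliberately not computed: every
downstream use here is Pearson correlation or OLS of the transformed values,
which needs only the transform itself.

Quantile normalization forces all samples (across both experiments) onto one
shared empirical distribution by rank-mean substitution; tied values within
a sample receive the mean of the quantile values their ranks span.

Muscle-signature normalization subtracts, per sample, the mean log
expression of a structural-muscle gene set from every gene. Because a
full-thickness rumen-wall biopsy mixes epithelium with smooth muscle, the
muscle-gene mean tracks the muscle proportion of the sample; centering on it
removes tissue-composition variation and leaves within-sample gene
differences untouched.
"""

from __future__ import annotations

import numpy as np

from .datatypes import CountMatrix, ExpressionMatrix, ValidationError


def cpm(counts: CountMatrix) -> np.ndarray:
    """Counts per million: ``count / library_size * 1e6`` per cell."""
    lib = counts.library_sizes
    if np.any(lib <= 0):
        bad = int(np.argmax(lib <= 0))
        raise ValidationError(f"zero library size for sample {counts.sample_ids[bad]!r}")
    return counts.counts / lib[None, :] * 1e6


def filter_by_cpm(
    counts: CountMatrix,
    threshold: float,
    comparison: str = "ge",
) -> list[str]:
    """Genes whose CPM satisfies the comparison against ``threshold`` in
    every sample.

    ``comparison='ge'`` implements the "at least N CPM" rule used for the
    co-expression network; ``'gt'`` implements the "CPM > N" rule used for
    the gene universe. Original gene order is preserved.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    mat = cpm(counts)
    if comparison == "ge":
        mask = (mat >= threshold).all(axis=1)
    elif comparison == "gt":
        mask = (mat > threshold).all(axis=1)
    else:
        raise ValueError("comparison must be 'ge' or 'gt'")
    return [g for g, keep in zip(counts.gene_ids, mask) if keep]


def log_cpm(counts: CountMatrix) -> ExpressionMatrix:
    """log2((count + 0.5) / (library_size + 1) * 1e6); finite even at zero."""
    lib = counts.library_sizes.astype(float)
    values = np.log2((counts.counts + 0.5) / (lib[None, :] + 1.0) * 1e6)
    return ExpressionMatrix(
        gene_ids=list(counts.gene_ids),
        sample_ids=list(counts.sample_ids),
        values=values,
        provenance=["logcpm"],
    )


def _quantile_normalize_values(values: np.ndarray) -> np.ndarray:
    """Rank-mean substitution across columns, ties averaged.

    Every column's sorted values are replaced by the cross-column mean of
    sorted values; within a column, tied entries all receive the mean of the
    reference values their sorted positions span.
    """
    n_genes, n_samples = values.shape
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    reference = sorted_vals.mean(axis=1)
    out = np.empty_like(values, dtype=float)
    for j in range(n_samples):
        col_sorted = sorted_vals[:, j]
        assigned = reference.copy()
        # average reference values over runs of ties
        start = 0
        for i in range(1, n_genes + 1):
            if i == n_genes or col_sorted[i] != col_sorted[start]:
                if i - start > 1:
                    assigned[start:i] = reference[start:i].mean()
                start = i
        out[order[:, j], j] = assigned
    return out


def quantile_normalize_joint(
    expr_a: ExpressionMatrix, expr_b: ExpressionMatrix
) -> ExpressionMatrix:
    """Quantile-normalize the two experiments' samples together.

    Gene lists must be identical; the result carries per-sample dataset
    labels so the combined matrix can be split back apart downstream.
    """
    if expr_a.gene_ids != expr_b.gene_ids:
        only_a = set(expr_a.gene_ids) - set(expr_b.gene_ids)
        only_b = set(expr_b.gene_ids) - set(expr_a.gene_ids)
        raise ValidationError(
            f"gene lists differ: {len(only_a)} only in first "
            f"(e.g. {sorted(only_a)[:3]}), {len(only_b)} only in second "
            f"(e.g. {sorted(only_b)[:3]})"
        )
    combined = np.hstack([expr_a.values, expr_b.values])
    normalized = _quantile_normalize_values(combined)
    labels_a = expr_a.dataset_labels or ["A"] * expr_a.n_samples
    labels_b = expr_b.dataset_labels or ["B"] * expr_b.n_samples
    return ExpressionMatrix(
        gene_ids=list(expr_a.gene_ids),
        sample_ids=list(expr_a.sample_ids) + list(expr_b.sample_ids),
        values=normalized,
        provenance=sorted(set(expr_a.provenance) | set(expr_b.provenance)) + ["quantile_joint"],
        dataset_labels=labels_a + labels_b,
    )


def muscle_normalize(expr: ExpressionMatrix, muscle_genes: set[str]) -> ExpressionMatrix:
    """Center every sample on its mean expression over ``muscle_genes``.

    Post-condition: the per-sample mean over the muscle set is exactly 0.
    Idempotent, and leaves all between-gene differences within a sample
    unchanged.
    """
    if not muscle_genes:
        raise ValidationError("empty muscle gene set")
    index = expr.gene_index()
    missing = sorted(g for g in muscle_genes if g not in index)
    if missing:
        raise ValidationError(f"muscle genes absent from expression matrix: {missing[:5]}")
    rows = [index[g] for g in sorted(muscle_genes)]
    sample_means = expr.values[rows, :].mean(axis=0)
    return ExpressionMatrix(
        gene_ids=list(expr.gene_ids),
        sample_ids=list(expr.sample_ids),
        values=expr.values - sample_means[None, :],
        provenance=list(expr.provenance) + ["muscle_normalized"],
        dataset_labels=None if expr.dataset_labels is None else list(expr.dataset_labels),
    )
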