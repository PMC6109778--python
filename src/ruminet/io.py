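"""TSV readers/writers for counts, phenotypes, networks and manifests."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import KNOWN_PHENOTYPES, CountMatrix, PhenotypeTable, ValidationError


def read_counts(path: str | Path) -> CountMatrix:
    """Read a gene x sample counts TSV (first column gene ids, header row
    sample ids, integer cells)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0:
        raise ValidationError("no genes")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"duplicate gene id {dup!r} in {path}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValidationError(f"duplicate sample id {dup!r} in {path}")
    try:
        counts = df.to_numpy(dtype=np.int64)
    except ValueError:
        # locate the offending cell for a useful error address
        for j, col in enumerate(df.columns):
            for i, v in enumerate(df[col]):
                try:
                    int(v)
                except (TypeError, ValueError):
                    raise ValidationError(
                        f"non-integer count {v!r} at gene {df.index[i]!r}, "
                        f"sample {col!r}"
                    ) from None
        raise
    return CountMatrix(
        gene_ids=list(df.index), sample_ids=list(df.columns), counts=counts
    )


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_phenotypes(
    path: str | Path,
    dataset: str = "A",
    counts: CountMatrix | None = None,
) -> PhenotypeTable:
    """Read a per-sample phenotype TSV.

    Unknown columns are carried through as opaque extras with a warning.
    ``NA``/empty cells become NaN (explicit missing), never zero. When a
    companion CountMatrix is given, phenotype sample ids must cover it.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=["NA", "na", ""])
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path}: 'sample_id' column required")
    df = df.set_index("sample_id")
    extras = [c for c in df.columns if c not in KNOWN_PHENOTYPES and c not in ("dataset", "block")]
    if extras:
        warnings.warn(f"unknown phenotype columns carried as extras: {extras}", stacklevel=2)
    for col in df.columns:
        if col in KNOWN_PHENOTYPES:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    table = PhenotypeTable(data=df, dataset=dataset, extras=extras)
    if counts is not None:
        table = table.aligned(counts.sample_ids)
    return table


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id")


def write_edge_list(edges: list[tuple[str, str, float]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tr\n")
        for a, b, r in edges:
            fh.write(f"{a}\t{b}\t{r:.10g}\n")


def read_edge_list(path: str | Path) -> list[tuple[str, str, float]]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    return [(a, b, float(r)) for a, b, r in df.itertuples(index=False)]


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
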