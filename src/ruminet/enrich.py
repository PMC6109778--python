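"""Local gene-set over-representation by hypergeometric upper tail.

A deliberately plain replacement for web-service enrichment: each term is
tested with the upper-tail hypergeometric probability of its overlap with
the query inside an explicit gene universe, followed by Benjamini-Hochberg
adjustment across tested terms. No EASE-style score modification is
applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .cluster import hypergeometric_overlap
from .datatypes import ValidationError
from .de import bh_fdr


@dataclass
class GeneSetCollection:
    sets: dict[str, set[str]]
    source: str = ""
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [t for t, s in self.sets.items() if not s]
        if empty:
            raise ValidationError(f"empty gene sets: {empty[:5]}")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: term, description, then genes, tab-separated.

    Duplicate term names are an error; a gene repeated within a term is
    deduplicated with a warning.
    """
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: malformed GMT line (need term, "
                    f"description and >= 1 gene, got {len(fields)} fields)"
                )
            term, desc, genes = fields[0], fields[1], fields[2:]
            if term in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate term {term!r}")
            genes = [g for g in genes if g]
            if len(genes) != len(set(genes)):
                warnings.warn(
                    f"{path}:{lineno}: duplicate genes in term {term!r} deduplicated",
                    stacklevel=2,
                )
            sets[term] = set(genes)
            descriptions[term] = desc
    return GeneSetCollection(sets=sets, source=str(path), descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in collection.sets:
            desc = collection.descriptions.get(term, "")
            genes = "\t".join(sorted(collection.sets[term]))
            fh.write(f"{term}\t{desc}\t{genes}\n")


def enrich(
    query: set[str],
    sets: GeneSetCollection,
    universe: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of each term in the query, within the universe.

    Terms are intersected with the universe first; terms that vanish are
    dropped. Returns one row per tested term (term order independent —
    sorted by p then term name) with columns k, n_draw, K, N, p, adj_p and
    a ``significant`` flag at ``adj_p < alpha``.
    """
    if not query:
        raise ValidationError("empty query set")
    stray = query - universe
    if stray:
        raise ValidationError(
            f"query genes outside the universe: {sorted(stray)[:5]}"
        )
    n_draw = len(query)
    N = len(universe)
    rows = []
    for term, members in sets.sets.items():
        restricted = members & universe
        if not restricted:
            continue
        k = len(query & restricted)
        test = hypergeometric_overlap(k=k, n_draw=n_draw, K=len(restricted), N=N)
        rows.append((term, k, n_draw, len(restricted), N, test.hP))
    df = pd.DataFrame(rows, columns=["term", "k", "n_draw", "K", "N", "p"])
    if len(df):
        df["adj_p"] = bh_fdr(df["p"].to_numpy())
        df["significant"] = df["adj_p"] < alpha
        df = df.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
    return df
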