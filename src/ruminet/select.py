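"""Stepwise cross-experiment selection of genes consistently correlated
with a phenotype.

Rather than a hard p-value cutoff, the procedure combines soft ranking and
between-experiment reproducibility. Per experiment:

1. rank genes by |r| with the phenotype and keep the upper tercile
   (top 33% by default, ties at the boundary all included);
2. build a PCIT co-expression network on the kept genes and retain genes
   that are nodes (incident to at least one surviving edge with gene-gene
   |r| above the edge threshold).

The two experiments' node sets are then intersected, and a gene survives
only if its correlation has the same sign in both experiments and
|r| >= 0.15 in both. The result is sorted by mean |r| (descending).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .datatypes import ExpressionMatrix
from .pcit import network_from_expression

logger = logging.getLogger(__name__)


@dataclass
class ConsistentGeneSet:
    phenotype: str
    table: pd.DataFrame  # index gene; columns r_a, r_b
    stage_counts: dict[str, int] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)


def tercile_select(corr: pd.DataFrame, fraction: float = 1.0 / 3.0) -> list[str]:
    """Genes whose |r| reaches the upper ``fraction`` of the |r|
    distribution (empirical order statistic; boundary ties all included)."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    if len(corr) < 3:
        raise ValueError("need at least 3 genes")
    abs_r = corr["r"].abs()
    finite = abs_r.dropna()
    k = max(1, int(np.ceil(len(finite) * fraction)))
    cutoff = finite.sort_values(ascending=False).iloc[k - 1]
    selected = abs_r[abs_r >= cutoff].index
    return [g for g in corr.index if g in set(selected)]


def select_consistent(
    corr_a: pd.DataFrame,
    corr_b: pd.DataFrame,
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    config: PipelineConfig,
    phenotype: str = "",
) -> ConsistentGeneSet:
    """Cross-experiment consistent gene selection for one phenotype.

    ``corr_a``/``corr_b`` are per-gene correlation tables (column ``r``)
    over a shared gene namespace; ``expr_a``/``expr_b`` the per-experiment
    expression used for the PCIT sub-networks. An empty intersection is a
    valid outcome (logged), not an error.
    """
    shared = [g for g in corr_a.index if g in set(corr_b.index)]
    counts: dict[str, int] = {"shared_genes": len(shared)}

    nodes: dict[str, set[str]] = {}
    for tag, corr, expr in (("a", corr_a, expr_a), ("b", corr_b, expr_b)):
        selected = tercile_select(corr.loc[shared], config.tercile_fraction)
        counts[f"tercile_{tag}"] = len(selected)
        if len(selected) < 2:
            nodes[tag] = set()
            counts[f"network_nodes_{tag}"] = 0
            continue
        sub = expr.subset_genes(selected)
        net, _, _ = network_from_expression(sub, config.edge_r_threshold)
        nodes[tag] = set(net.nodes())
        counts[f"network_nodes_{tag}"] = len(nodes[tag])

    both = nodes["a"] & nodes["b"]
    counts["node_intersection"] = len(both)

    r_a = corr_a["r"]
    r_b = corr_b["r"]
    rows = []
    for g in sorted(both):
        ra, rb = float(r_a[g]), float(r_b[g])
        if np.isnan(ra) or np.isnan(rb):
            continue
        if np.sign(ra) != np.sign(rb):
            continue
        if abs(ra) < config.min_abs_r or abs(rb) < config.min_abs_r:
            continue
        rows.append((g, ra, rb))
    counts["consistent"] = len(rows)
    logger.info("select_consistent[%s] stage counts: %s", phenotype, counts)

    table = pd.DataFrame(rows, columns=["gene", "r_a", "r_b"]).set_index("gene")
    if len(table):
        order = (table["r_a"].abs() + table["r_b"].abs()).div(2).sort_values(ascending=False)
        table = table.loc[order.index]
    return ConsistentGeneSet(phenotype=phenotype, table=table, stage_counts=counts)
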