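"""Community detection on gene networks and gene-set overlap statistics."""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .datatypes import ValidationError

UNASSIGNED = "unassigned"


@dataclass
class ClusterAssignment:
    """Node -> community label plus the modularity of the partition."""

    labels: dict[str, str]
    modularity: float

    def members(self, label: str) -> set[str]:
        return {g for g, c in self.labels.items() if c == label}

    def communities(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for g, c in self.labels.items():
            out.setdefault(c, set()).add(g)
        return out


@dataclass
class OverlapTest:
    k: int
    n_draw: int
    K: int
    N: int
    hP: float


def detect_communities(net: nx.Graph, min_size: int = 1) -> ClusterAssignment:
    """Greedy modularity maximization on the unweighted edge topology.

    Deterministic given node identity: the graph is rebuilt with
    lexicographically sorted nodes and edges so heap tie-breaks do not
    depend on insertion history. Communities smaller than ``min_size`` are
    labelled ``unassigned``; the rest are ``c1, c2, ...`` in decreasing
    size order (ties broken by smallest member id).
    """
    if net.number_of_edges() == 0:
        raise ValidationError("non-empty network required")
    canonical = nx.Graph()
    canonical.add_nodes_from(sorted(net.nodes()))
    canonical.add_edges_from(sorted(tuple(sorted(e)) for e in net.edges()))
    communities = [
        set(c)
        for c in nx.algorithms.community.greedy_modularity_communities(canonical)
    ]
    modularity = nx.algorithms.community.modularity(canonical, communities)
    communities.sort(key=lambda c: (-len(c), min(c)))
    labels: dict[str, str] = {}
    idx = 0
    for comm in communities:
        if len(comm) < min_size:
            label = UNASSIGNED
        else:
            idx += 1
            label = f"c{idx}"
        for g in comm:
            labels[g] = label
    return ClusterAssignment(labels=labels, modularity=float(modularity))


def overlap_fraction(cluster_a: set[str], reference: set[str]) -> float:
    """|A intersect B| / |A| — the fraction of A contained in the reference."""
    if not cluster_a:
        raise ValidationError("empty query set")
    return len(set(cluster_a) & set(reference)) / len(set(cluster_a))


def hypergeometric_overlap(k: int, n_draw: int, K: int, N: int) -> OverlapTest:
    """Upper-tail hypergeometric probability P(X >= k) of drawing at least
    ``k`` of a ``K``-member category in ``n_draw`` draws from ``N`` genes.

    Summed in log space so extreme tails (< 1e-15) remain accurate.
    """
    if not (0 <= k <= min(n_draw, K)):
        raise ValidationError(f"infeasible overlap k={k} for n_draw={n_draw}, K={K}")
    if n_draw > N or K > N:
        raise ValidationError("draw or category size exceeds universe")
    if k == 0:
        return OverlapTest(k=k, n_draw=n_draw, K=K, N=N, hP=1.0)
    support = np.arange(k, min(n_draw, K) + 1)
    log_terms = hypergeom.logpmf(support, N, K, n_draw)
    h_p = float(np.exp(logsumexp(log_terms)))
    return OverlapTest(k=k, n_draw=n_draw, K=K, N=N, hP=min(h_p, 1.0))


def adjusted_rand_index(labels_a: dict[str, str], labels_b: dict[str, str]) -> float:
    """Chance-corrected agreement of two partitions over their common keys."""
    keys = sorted(set(labels_a) & set(labels_b))
    if len(keys) < 2:
        raise ValidationError("need at least 2 co-labelled items")
    a = [labels_a[k] for k in keys]
    b = [labels_b[k] for k in keys]
    cats_a = {c: i for i, c in enumerate(sorted(set(a)))}
    cats_b = {c: i for i, c in enumerate(sorted(set(b)))}
    table = np.zeros((len(cats_a), len(cats_b)), dtype=np.int64)
    for x, y in zip(a, b):
        table[cats_a[x], cats_b[y]] += 1

    def comb2(v: np.ndarray) -> float:
        return float((v * (v - 1) // 2).sum())

    sum_ij = comb2(table)
    sum_i = comb2(table.sum(axis=1))
    sum_j = comb2(table.sum(axis=0))
    n2 = len(keys) * (len(keys) - 1) / 2
    expected = sum_i * sum_j / n2
    max_index = (sum_i + sum_j) / 2
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)
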