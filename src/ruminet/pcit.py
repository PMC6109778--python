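"""Partial Correlation and Information Theory (PCIT) network construction.

PCIT decides, for every pair of genes, whether their direct correlation
survives comparison against all indirect routes through a third gene. For
an ordered trio (x, y, z) the three first-order partial correlations

    r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2) * (1 - r_yz^2))

are combined into a local tolerance

    eps_xyz = (|r_xy.z / r_xy| + |r_xz.y / r_xz| + |r_yz.x / r_yz|) / 3,

the average attenuation of direct correlations once the third gene is
controlled for. The edge (x, y) is rejected if *some* third gene z
dominates it on both sides:

    |r_xy| < eps_xyz * |r_xz|   and   |r_xy| < eps_xyz * |r_yz|.

Ratios are taken in absolute value so the tolerance is non-negative and the
rule is sign-symmetric; a ratio whose direct correlation is exactly zero is
skipped and the tolerance averaged over the remaining terms (degenerate-trio
rule). The surviving mask is then thresholded on |r| to yield the network.

The sweep is organized per third-gene z with full-matrix vectorization:
O(n^3) work and O(n^2) memory, which handles the 1000-gene synthetic runs
in seconds. A naive triple-loop reference implementation lives in the test
suite as the independent oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .datatypes import ExpressionMatrix, ValidationError


@dataclass
class CorrelationMatrix:
    gene_ids: list[str]
    r: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.gene_ids)
        if self.r.shape != (n, n):
            raise ValidationError("correlation matrix shape mismatch")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise ValidationError("correlation matrix not symmetric")
        if np.any(np.abs(self.r) > 1 + 1e-10):
            raise ValidationError("correlations outside [-1, 1]")


@dataclass
class PcitResult:
    keep_mask: np.ndarray
    n_trios_rejecting: int = 0
    r_threshold: float | None = None
    tolerance_trace: list[tuple[int, int, int, float]] | None = None


def pearson_matrix(expr: ExpressionMatrix) -> CorrelationMatrix:
    """Exact symmetric Pearson correlation matrix of gene profiles.

    Genes with zero variance across samples are excluded with a warning
    (their correlation is undefined).
    """
    if expr.n_samples < 3:
        raise ValidationError("at least 3 samples required for correlation")
    variances = expr.values.var(axis=1)
    keep = variances > 0
    if not np.all(keep):
        dropped = [g for g, k in zip(expr.gene_ids, keep) if not k]
        warnings.warn(
            f"excluding {len(dropped)} zero-variance genes, e.g. {dropped[:3]}",
            stacklevel=2,
        )
    genes = [g for g, k in zip(expr.gene_ids, keep) if k]
    r = np.corrcoef(expr.values[keep, :])
    r = np.atleast_2d(r)
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return CorrelationMatrix(gene_ids=genes, r=r, n_samples=expr.n_samples)


def partial_correlation(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation r_xy.z; NaN when a conditioning
    correlation is +-1 (undefined)."""
    denom_sq = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if denom_sq <= 0.0:
        return float("nan")
    return float((r_xy - r_xz * r_yz) / np.sqrt(denom_sq))


def pcit_keep_mask(corr: CorrelationMatrix) -> PcitResult:
    """Apply the trio-tolerance rejection rule to every edge.

    With fewer than 3 genes no trio exists and every edge is kept.
    """
    r = corr.r
    n = r.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 genes")
    keep = np.ones((n, n), dtype=bool)
    np.fill_diagonal(keep, False)
    if n < 3:
        return PcitResult(keep_mask=keep)

    abs_r = np.abs(r)
    off_diag = ~np.eye(n, dtype=bool)
    generic = bool(np.all(abs_r[off_diag] > 0.0) and np.all(abs_r[off_diag] < 1.0))
    if generic:
        reject = _reject_mask_generic(r, abs_r)
    else:
        reject = _reject_mask_degenerate(r, abs_r)
    keep = ~reject
    np.fill_diagonal(keep, False)
    keep &= keep.T  # symmetric by construction; enforce defensively
    return PcitResult(keep_mask=keep, n_trios_rejecting=int(reject.sum() // 2))


def _reject_mask_generic(r: np.ndarray, abs_r: np.ndarray) -> np.ndarray:
    """Vectorized per-z sweep for matrices with no exact 0 or +-1 off the
    diagonal (the generic case for correlations estimated from data).

    Buffers are preallocated and reused: the sweep is memory-bandwidth
    bound, so avoiding per-iteration allocation roughly halves the runtime
    on 1000-gene inputs.
    """
    n = r.shape[0]
    reject = np.zeros((n, n), dtype=bool)
    S = np.sqrt(np.clip(1.0 - r**2, 0.0, None))  # sqrt(1 - r^2), 0 on diagonal
    W1 = np.empty((n, n))
    W2 = np.empty((n, n))
    W3 = np.empty((n, n))
    M1 = np.empty((n, n), dtype=bool)
    M2 = np.empty((n, n), dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        for z in range(n):
            rz = r[:, z]
            sz = S[:, z]
            az = abs_r[:, z]
            # t1 = |r_xy.z / r_xy|
            np.outer(rz, rz, out=W1)
            np.subtract(r, W1, out=W1)
            np.outer(sz, sz, out=W2)
            np.divide(W1, W2, out=W1)
            np.abs(W1, out=W1)
            np.divide(W1, abs_r, out=W1)
            # t2 = |r_xz.y / r_xz|; t3 is its transpose
            np.multiply(r, rz[np.newaxis, :], out=W2)
            np.subtract(rz[:, np.newaxis], W2, out=W2)
            np.multiply(S, sz[np.newaxis, :], out=W3)
            np.divide(W2, W3, out=W2)
            np.abs(W2, out=W2)
            np.divide(W2, az[:, np.newaxis], out=W2)
            # eps = (t1 + t2 + t2.T) / 3
            np.add(W1, W2, out=W1)
            np.add(W1, W2.T, out=W1)
            W1 /= 3.0
            # dominated on both sides
            np.multiply(W1, az[:, np.newaxis], out=W2)
            np.less(abs_r, W2, out=M1)
            np.multiply(W1, az[np.newaxis, :], out=W2)
            np.less(abs_r, W2, out=M2)
            M1 &= M2
            M1[:, z] = False
            M1[z, :] = False
            reject |= M1
    np.fill_diagonal(reject, False)
    return reject


def _reject_mask_degenerate(r: np.ndarray, abs_r: np.ndarray) -> np.ndarray:
    """General sweep handling exact-zero direct correlations (ratio terms
    skipped, tolerance averaged over the rest) and |r| = 1 conditioning."""
    n = r.shape[0]
    reject = np.zeros((n, n), dtype=bool)
    eye = np.eye(n, dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        one_minus_r2 = np.clip(1.0 - r**2, 0.0, None)
        for z in range(n):
            rz = r[:, z]  # correlations of every gene with the third gene z
            omz = one_minus_r2[:, z]  # 1 - r_xz^2 per gene x
            # partial r_xy.z over all pairs (x, y)
            denom_xy = np.sqrt(np.outer(omz, omz))
            p_xy_z = (r - np.outer(rz, rz)) / denom_xy
            # partial r_xz.y (x with z, controlling the partner y)
            denom_xz = np.sqrt(one_minus_r2 * omz[None, :])
            p_xz_y = (rz[:, None] - r * rz[None, :]) / denom_xz
            # partial r_yz.x is the transpose by symmetry of the construction
            p_yz_x = p_xz_y.T

            t1 = np.abs(p_xy_z) / abs_r
            t2 = np.abs(p_xz_y) / np.abs(rz)[:, None]
            t3 = t2.T
            # degenerate-trio rule: skip ratio terms whose direct r is 0
            terms = np.stack([t1, t2, t3])
            valid = np.isfinite(terms)
            n_valid = valid.sum(axis=0)
            eps = np.where(
                n_valid > 0,
                np.where(valid, terms, 0.0).sum(axis=0) / np.maximum(n_valid, 1),
                np.inf,
            )
            # a trio with no finite term cannot dominate anything
            eps[n_valid == 0] = 0.0

            dominated = (abs_r < eps * np.abs(rz)[:, None]) & (
                abs_r < eps * np.abs(rz)[None, :]
            )
            dominated[:, z] = False
            dominated[z, :] = False
            dominated[eye] = False
            reject |= dominated
    return reject


def build_network(
    corr: CorrelationMatrix,
    pcit: PcitResult,
    r_threshold: float,
) -> nx.Graph:
    """Undirected gene network: edges kept by PCIT with |r| above threshold.

    Isolated genes are dropped — network membership means incidence to at
    least one retained edge.
    """
    r = corr.r
    if pcit.keep_mask.shape != r.shape:
        raise ValidationError("mask and correlation matrix are not aligned")
    mask = pcit.keep_mask & (np.abs(r) > r_threshold)
    g = nx.Graph()
    idx_i, idx_j = np.nonzero(np.triu(mask, k=1))
    for i, j in zip(idx_i, idx_j):
        g.add_edge(corr.gene_ids[i], corr.gene_ids[j], weight=float(r[i, j]))
    return g


def network_from_expression(
    expr: ExpressionMatrix, r_threshold: float
) -> tuple[nx.Graph, CorrelationMatrix, PcitResult]:
    """Convenience composition: Pearson -> PCIT -> thresholded network."""
    corr = pearson_matrix(expr)
    result = pcit_keep_mask(corr)
    result.r_threshold = r_threshold
    return build_network(corr, result, r_threshold), corr, result
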