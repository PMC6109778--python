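"""Recovery benchmarks against the synthetic generator's planted truth.

These routines re-run the analysis on freshly simulated data and score the
result against the planted ground truth: community recovery (adjusted Rand
index), consistent-selection recovery and background contamination,
extreme-retention-time prioritization recall, and the shuffled-phenotype
null selection rate. They are the package's own measure of whether the
pipeline finds what was planted under study-like conditions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .associate import cluster_mean_expression, correlate_genes_with_phenotype
from .cluster import adjusted_rand_index, detect_communities
from .config import PipelineConfig, SimConfig
from .de import de_fit, prioritize, rank_joint_negative, select_extremes
from .normalize import filter_by_cpm, log_cpm, muscle_normalize, quantile_normalize_joint
from .pcit import network_from_expression
from .select import select_consistent
from .simulate import simulate_pair

YIELD_LINKED = ("lipid_oxo", "muscle_junction")


def _shared_universe(counts_a, counts_b, config: PipelineConfig) -> list[str]:
    ua = set(filter_by_cpm(counts_a, config.universe_cpm_threshold, "gt"))
    ub = set(filter_by_cpm(counts_b, config.universe_cpm_threshold, "gt"))
    return [g for g in counts_a.gene_ids if g in ua and g in ub]


def _joint_expression(counts_a, counts_b, config: PipelineConfig):
    na = set(filter_by_cpm(counts_a, config.cpm_filter_threshold, "ge"))
    nb = set(filter_by_cpm(counts_b, config.cpm_filter_threshold, "ge"))
    joint_genes = [g for g in counts_a.gene_ids if g in na and g in nb]
    expr_a = log_cpm(counts_a.subset_genes(joint_genes))
    expr_b = log_cpm(counts_b.subset_genes(joint_genes))
    expr_a.dataset_labels = ["A"] * expr_a.n_samples
    expr_b.dataset_labels = ["B"] * expr_b.n_samples
    return quantile_normalize_joint(expr_a, expr_b)


def community_recovery(
    seed: int,
    sim_config: SimConfig | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    """Joint-network community detection scored against planted clusters.

    The ARI is computed over network genes (genes with at least one
    retained co-expression edge) against the planted labels.
    """
    config = config or PipelineConfig()
    sim_config = sim_config or SimConfig(seed=seed)
    counts_a, counts_b, _, _, truth = simulate_pair(sim_config, seed=seed)
    expr_joint = _joint_expression(counts_a, counts_b, config)
    net, _, _ = network_from_expression(expr_joint, config.edge_r_threshold)
    assignment = detect_communities(net, config.min_community_size)
    planted = {g: truth.cluster_membership[g] for g in assignment.labels}
    return {
        "ari": adjusted_rand_index(assignment.labels, planted),
        "n_nodes": net.number_of_nodes(),
        "n_communities": len(assignment.communities()),
    }


def consistent_selection_metrics(
    seed: int,
    phenotype: str = "ch4_yield",
    linked_clusters: tuple[str, ...] = YIELD_LINKED,
    sim_config: SimConfig | None = None,
    config: PipelineConfig | None = None,
    shuffle_phenotype: bool = False,
    shuffle_seed: int | None = None,
) -> dict:
    """Recovery of planted phenotype-linked genes by consistent selection.

    With ``shuffle_phenotype`` the phenotype is permuted within each
    experiment (destroying all links), giving the null selection rate.
    """
    config = config or PipelineConfig()
    sim_config = sim_config or SimConfig(seed=seed)
    counts_a, counts_b, phen_a, phen_b, truth = simulate_pair(sim_config, seed=seed)
    shared = _shared_universe(counts_a, counts_b, config)
    expr_a = log_cpm(counts_a.subset_genes(shared))
    expr_b = log_cpm(counts_b.subset_genes(shared))
    ya = phen_a.column(phenotype)
    yb = phen_b.column(phenotype)
    if shuffle_phenotype:
        rng = np.random.default_rng(seed + 1000 if shuffle_seed is None else shuffle_seed)
        ya = pd.Series(rng.permutation(ya.to_numpy()), index=ya.index)
        yb = pd.Series(rng.permutation(yb.to_numpy()), index=yb.index)
    corr_a = correlate_genes_with_phenotype(expr_a, ya)
    corr_b = correlate_genes_with_phenotype(expr_b, yb)
    result = select_consistent(corr_a, corr_b, expr_a, expr_b, config, phenotype=phenotype)
    selected = set(result.genes)
    planted = set().union(*(truth.members(c) for c in linked_clusters))
    background = truth.members("background")
    return {
        "n_selected": len(selected),
        "n_universe": len(shared),
        "recovery": len(selected & planted) / len(planted) if planted else float("nan"),
        "background_fraction": (
            len(selected & background) / len(selected) if selected else 0.0
        ),
        "selection_rate": len(selected) / len(shared),
    }


def prioritize_metrics(
    seed: int,
    sim_config: SimConfig | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    """Recall of the planted junction program by the extreme-MRT analysis.

    The structural-muscle signature is the planted muscle cluster, which
    the joint-network community detection recovers exactly under the
    default conditions (see :func:`community_recovery`); using it directly
    keeps the benchmark independent of the expensive global network step.
    """
    config = config or PipelineConfig()
    sim_config = sim_config or SimConfig(seed=seed)
    counts_a, counts_b, phen_a, phen_b, truth = simulate_pair(sim_config, seed=seed)
    universe = filter_by_cpm(counts_a, config.universe_cpm_threshold, "gt")
    expr_a = log_cpm(counts_a.subset_genes(universe))
    muscle = truth.members("muscle")

    # correlation rankings on the muscle-composition-normalized joint matrix
    expr_joint = _joint_expression(counts_a, counts_b, config)
    joint_m = muscle_normalize(expr_joint, muscle & set(expr_joint.gene_ids))
    a_ids = [s for s, d in zip(joint_m.sample_ids, joint_m.dataset_labels) if d == "A"]
    corr_mrt = correlate_genes_with_phenotype(
        joint_m.subset_samples(a_ids), phen_a.column("mrt")
    )
    yield_all = pd.concat([phen_a.column("ch4_yield"), phen_b.column("ch4_yield")])
    corr_yield = correlate_genes_with_phenotype(joint_m, yield_all)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        ranked = rank_joint_negative(corr_mrt, corr_yield, config.top_k)

    short, long_ = select_extremes(phen_a.column("mrt"), config.extreme_group_size)
    extreme = short + long_
    group = pd.Series(["short"] * len(short) + ["long"] * len(long_), index=extreme)
    signature = cluster_mean_expression(log_cpm(counts_a), muscle)
    de = de_fit(
        expr_a.subset_samples(extreme),
        group,
        block=phen_a.data["block"].astype(str).loc[extreme],
        covariate=signature.loc[extreme],
    )
    final = prioritize(de, ranked, config.de_fdr_threshold, corr_mrt, corr_yield)
    junction = truth.members("muscle_junction")
    return {
        "n_prioritized": len(final),
        "n_de_significant": int((de["q"] < config.de_fdr_threshold).sum()),
        "recall": len(set(final.index) & junction) / len(junction),
        "n_ranked": len(ranked),
    }


def monte_carlo(metric, seeds, **kwargs) -> pd.DataFrame:
    """Run one of the benchmark metrics over a list of seeds."""
    rows = [metric(seed, **kwargs) for seed in seeds]
    return pd.DataFrame(rows, index=list(seeds))
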