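"""Paired two-experiment synthetic rumen-wall RNA-seq generator.

The generator emulates the statistical structure the analysis assumes:

* six planted co-expression programs — structural muscle (with a distinct
  cell-junction sub-block), cell cycle, epithelial differentiation, general
  metabolism and lipid/oxo-acid metabolism — over a background of
  unstructured genes;
* full-thickness tissue mixing: each sample has a latent muscle proportion
  m in (0, 1); muscle-program genes scale with log2(m) and epithelial
  programs with log2(1 - m), so composition is the dominant shared signal
  of the muscle cluster, as it is in real rumen-wall biopsies;
* negative-binomial counts: gene g in sample i has mean
  ``libsize_i * 2^mu_gi / sum_g 2^mu_gi`` with
  ``mu_gi = baseline_g + loading_g * activity_{c(g),i} + mixing + block +
  noise`` and gene-wise dispersion phi (variance = mean + phi * mean^2);
* phenotypes built as linear functions of designated cluster activities at
  configured target Pearson correlations: CH4 yield rises with lipid/oxo
  activity and falls with the junction (retention-time) program; retention
  time is measured in experiment A only; CH4 production is yield * intake
  exactly; the three SCFAs are mutually correlated and tied to cell-cycle
  activity; experiment B gets distinct CH4 intercepts.

Experiment A has 62 samples in four blocks (16/16/14/16) with additive
per-block log-scale offsets; experiment B has 24 samples and no blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import BACKGROUND, CLUSTER_LABELS, SimConfig
from .datatypes import CountMatrix, PhenotypeTable
from .normalize import log_cpm

_EPITHELIAL = ("cell_cycle", "epithelial_diff", "general_metab", "lipid_oxo")
_MUSCULAR = ("muscle", "muscle_junction")


@dataclass
class SyntheticTruth:
    cluster_membership: dict[str, str]
    cluster_activity_a: pd.DataFrame  # samples x clusters
    cluster_activity_b: pd.DataFrame
    muscle_fraction_a: pd.Series
    muscle_fraction_b: pd.Series
    effect_map: dict[str, list[tuple[str, float]]]
    dispersion: pd.Series
    loadings: pd.Series

    def members(self, label: str) -> set[str]:
        return {g for g, c in self.cluster_membership.items() if c == label}


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def _latent_from_links(
    rng: np.random.Generator,
    activities: pd.DataFrame,
    links: list[tuple[str, float]],
    n: int,
) -> np.ndarray:
    """Standard-normal latent with target correlation r_j against each
    linked cluster activity (activities are independent by construction)."""
    total = sum(r * r for _, r in links)
    if total > 0.81:
        raise ValueError("combined phenotype targets exceed |r| = 0.9 budget")
    z = np.zeros(n)
    for cluster, r in links:
        z += r * activities[cluster].to_numpy()
    z += np.sqrt(max(1.0 - total, 0.0)) * rng.standard_normal(n)
    return z


def _gene_table(cfg: SimConfig, rng: np.random.Generator):
    """Assign genes to clusters and draw per-gene generative parameters."""
    gene_ids = [f"G{i + 1:06d}" for i in range(cfg.n_genes)]
    membership: dict[str, str] = {}
    cursor = 0
    for label in CLUSTER_LABELS:
        size = cfg.cluster_sizes.get(label, 0)
        for g in gene_ids[cursor : cursor + size]:
            membership[g] = label
        cursor += size
    for g in gene_ids[cursor:]:
        membership[g] = BACKGROUND

    loading_mean = {
        "muscle": cfg.loading_mean_muscle,
        "muscle_junction": cfg.loading_mean_junction,
    }
    compartment = {
        "muscle": cfg.compartment_loading_muscle,
        "muscle_junction": cfg.compartment_loading_junction,
    }
    baselines = np.empty(cfg.n_genes)
    loadings = np.empty(cfg.n_genes)
    gammas = np.empty(cfg.n_genes)
    for i, g in enumerate(gene_ids):
        label = membership[g]
        if label == BACKGROUND:
            baselines[i] = rng.normal(cfg.baseline_mean, cfg.baseline_sd)
            loadings[i] = 0.0
            gammas[i] = 0.0
        else:
            baselines[i] = rng.normal(cfg.cluster_baseline_mean, cfg.cluster_baseline_sd)
            loadings[i] = rng.normal(
                loading_mean.get(label, cfg.loading_mean), cfg.loading_sd
            )
            gammas[i] = compartment.get(label, cfg.compartment_loading_epithelial)
    dispersion = np.full(cfg.n_genes, cfg.nb_dispersion)
    return gene_ids, membership, baselines, loadings, gammas, dispersion


def _simulate_dataset(
    cfg: SimConfig,
    rng: np.random.Generator,
    dataset: str,
    gene_ids: list[str],
    membership: dict[str, str],
    baselines: np.ndarray,
    loadings: np.ndarray,
    gammas: np.ndarray,
    dispersion: np.ndarray,
):
    is_a = dataset == "A"
    n = cfg.n_samples_a if is_a else cfg.n_samples_b
    sample_ids = [f"{dataset}{i + 1:02d}" for i in range(n)]

    activities = pd.DataFrame(
        rng.standard_normal((n, len(CLUSTER_LABELS))),
        index=sample_ids,
        columns=list(CLUSTER_LABELS),
    )

    # --- phenotype latents -------------------------------------------------
    yield_z = _latent_from_links(rng, activities, cfg.effect_map.get("ch4_yield", []), n)
    mrt_z = _latent_from_links(rng, activities, cfg.effect_map.get("mrt", []), n)
    dmi_z = cfg.dmi_yield_r * yield_z + np.sqrt(
        1.0 - cfg.dmi_yield_r**2
    ) * rng.standard_normal(n)
    shared_scfa = rng.standard_normal(n)
    scfa_z = {}
    for name in ("acetate", "butyrate", "propionate"):
        links = cfg.effect_map.get(name, [])
        direct = sum(r * r for _, r in links)
        w = cfg.scfa_shared_weight
        if direct + w * w > 1.0:
            raise ValueError(f"SCFA targets plus shared weight exceed unit variance ({name})")
        z = np.zeros(n)
        for cluster, r in links:
            z += r * activities[cluster].to_numpy()
        z += w * shared_scfa
        z += np.sqrt(1.0 - direct - w * w) * rng.standard_normal(n)
        scfa_z[name] = z

    # --- tissue composition ------------------------------------------------
    # muscle proportion couples (weakly, configurable) to the retention-time
    # latent: shorter retention goes with a thicker muscle layer
    kappa = cfg.mrt_muscle_fraction_r
    logit_m = cfg.muscle_logit_sd * (
        kappa * mrt_z + np.sqrt(1.0 - kappa**2) * rng.standard_normal(n)
    )
    m = 1.0 / (1.0 + np.exp(-logit_m))
    z_mix_muscle = _standardize(np.log2(m))
    z_mix_epithelial = _standardize(np.log2(1.0 - m))

    # --- per-gene log2 means ----------------------------------------------
    mu = baselines[:, None] + cfg.noise_sd * rng.standard_normal((cfg.n_genes, n))
    labels = np.array([membership[g] for g in gene_ids])
    for label in CLUSTER_LABELS:
        rows = labels == label
        if not rows.any():
            continue
        act = activities[label].to_numpy()
        mix = z_mix_muscle if label in _MUSCULAR else z_mix_epithelial
        mu[rows, :] += loadings[rows, None] * act[None, :]
        mu[rows, :] += gammas[rows, None] * mix[None, :]

    block_labels = None
    if is_a:
        block_labels = np.concatenate(
            [
                np.full(size, b + 1)
                for b, size in enumerate(cfg.block_sizes_a)
            ]
        )
        block_offsets = rng.normal(0.0, cfg.block_sd, size=(cfg.n_genes, cfg.n_blocks_a))
        mu += block_offsets[:, block_labels - 1]
        if cfg.block1_epithelial_shift != 0.0:
            epi = np.isin(labels, ("epithelial_diff",))
            mu[np.ix_(epi, block_labels == 1)] -= cfg.block1_epithelial_shift

    # --- negative-binomial counts ------------------------------------------
    libsizes = np.exp(rng.normal(cfg.libsize_log_mean, cfg.libsize_log_sd, size=n))
    rel = np.exp2(mu)
    mean = libsizes[None, :] * rel / rel.sum(axis=0, keepdims=True)
    shape = 1.0 / dispersion[:, None]
    lam = rng.gamma(shape=np.broadcast_to(shape, mean.shape), scale=mean * dispersion[:, None])
    counts = rng.poisson(lam).astype(np.int64)

    cm = CountMatrix(gene_ids=list(gene_ids), sample_ids=sample_ids, counts=counts)

    # --- phenotype table in physical units ----------------------------------
    yield_mean = cfg.yield_mean_a if is_a else cfg.yield_mean_b
    dmi_mean = cfg.dmi_mean_a if is_a else cfg.dmi_mean_b
    scfa_means = cfg.scfa_means_a if is_a else cfg.scfa_means_b
    ch4_yield = yield_mean + cfg.yield_sd * yield_z
    dmi = np.maximum(dmi_mean + cfg.dmi_sd * dmi_z, 0.2)
    data = {
        "dataset": dataset,
        "block": block_labels if is_a else np.full(n, "na"),
        "ch4_yield": ch4_yield,
        "dmi": dmi,
        "ch4_production": ch4_yield * dmi,  # exact by construction
        "acetate": scfa_means[0] + cfg.scfa_sds[0] * scfa_z["acetate"],
        "butyrate": scfa_means[1] + cfg.scfa_sds[1] * scfa_z["butyrate"],
        "propionate": scfa_means[2] + cfg.scfa_sds[2] * scfa_z["propionate"],
    }
    if is_a:
        data["mrt"] = cfg.mrt_mean + cfg.mrt_sd * mrt_z
        data["muscle_depth"] = 10.0 * m + rng.normal(0.0, 0.4, size=n)
    phen = PhenotypeTable(
        data=pd.DataFrame(data, index=pd.Index(sample_ids, name="sample_id")),
        dataset=dataset,
    )
    return cm, phen, activities, pd.Series(m, index=sample_ids)


def simulate_pair(
    cfg: SimConfig | None = None, seed: int | None = None
) -> tuple[CountMatrix, CountMatrix, PhenotypeTable, PhenotypeTable, SyntheticTruth]:
    """Generate the paired experiments plus ground truth.

    ``seed`` overrides ``cfg.seed``; identical configuration and seed give
    identical outputs.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    gene_ids, membership, baselines, loadings, gammas, dispersion = _gene_table(cfg, rng)
    counts_a, phen_a, act_a, m_a = _simulate_dataset(
        cfg, rng, "A", gene_ids, membership, baselines, loadings, gammas, dispersion
    )
    counts_b, phen_b, act_b, m_b = _simulate_dataset(
        cfg, rng, "B", gene_ids, membership, baselines, loadings, gammas, dispersion
    )
    truth = SyntheticTruth(
        cluster_membership=membership,
        cluster_activity_a=act_a,
        cluster_activity_b=act_b,
        muscle_fraction_a=m_a,
        muscle_fraction_b=m_b,
        effect_map={k: [tuple(link) for link in v] for k, v in cfg.effect_map.items()},
        dispersion=pd.Series(dispersion, index=gene_ids),
        loadings=pd.Series(loadings, index=gene_ids),
    )
    return counts_a, counts_b, phen_a, phen_b, truth


def realized_effects(
    truth: SyntheticTruth,
    counts: CountMatrix,
    phenotypes: PhenotypeTable,
) -> pd.DataFrame:
    """Empirical cluster-phenotype correlations for one dataset.

    One row per (cluster, phenotype): Pearson r of the latent cluster
    activity with the phenotype (``r_activity``), the same for the cluster's
    mean log-CPM expression (``r_expression``), and the paired n. A
    zero-variance side yields NaN with ``undefined=True``, never a silent 0.
    """
    activities = (
        truth.cluster_activity_a
        if list(truth.cluster_activity_a.index) == counts.sample_ids
        else truth.cluster_activity_b
    )
    if list(activities.index) != counts.sample_ids:
        raise ValueError("sample ids do not match either simulated dataset")
    expr = log_cpm(counts)
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    pheno_cols = [
        c for c in phenotypes.data.columns if c not in ("dataset", "block")
    ]
    rows = []
    for cluster in CLUSTER_LABELS:
        members = sorted(truth.members(cluster))
        if not members:
            continue
        act = activities[cluster]
        mean_expr = expr.values[[gene_index[g] for g in members], :].mean(axis=0)
        for pheno in pheno_cols:
            y = phenotypes.data[pheno]
            paired = pd.DataFrame(
                {"act": act, "expr": mean_expr, "y": y}
            ).dropna()
            n = len(paired)
            undefined = n < 3 or paired["y"].nunique() <= 1
            if undefined:
                r_act = r_expr = float("nan")
            else:
                r_act = float(np.corrcoef(paired["act"], paired["y"])[0, 1])
                r_expr = float(np.corrcoef(paired["expr"], paired["y"])[0, 1])
            rows.append((cluster, pheno, r_act, r_expr, n, undefined))
    return pd.DataFrame(
        rows,
        columns=["cluster", "phenotype", "r_activity", "r_expression", "n", "undefined"],
    )
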