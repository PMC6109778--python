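"""End-to-end orchestration of the cross-experiment analysis.

Stages (in order): normalize, network, cluster, associate, select, de,
enrich. Each stage writes TSV results into the output directory and
records row counts in a machine-readable manifest; any failure aborts with
the stage name and marks the manifest partial.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .associate import (
    cluster_mean_expression,
    correlate_genes_with_phenotype,
    dataset_regressions,
    fisher_z_difference,
)
from .cluster import ClusterAssignment, detect_communities
from .config import PipelineConfig
from .datatypes import CountMatrix, PhenotypeTable, ValidationError
from .de import de_fit, prioritize, rank_joint_negative, select_extremes
from .enrich import GeneSetCollection, enrich
from .io import write_edge_list, write_manifest, write_table
from .normalize import filter_by_cpm, log_cpm, muscle_normalize, quantile_normalize_joint
from .pcit import network_from_expression
from .select import select_consistent

logger = logging.getLogger(__name__)

STAGES = ("normalize", "network", "cluster", "associate", "select", "de", "enrich")
SELECTION_PHENOTYPES = ("ch4_production", "ch4_yield", "acetate", "butyrate", "propionate")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _annotate_communities(
    assignment: ClusterAssignment,
    markers: GeneSetCollection | None,
    universe: set[str],
    alpha: float,
) -> dict[str, str]:
    """Name communities by their most over-represented marker term."""
    names: dict[str, str] = {}
    if markers is None:
        return names
    for label, members in assignment.communities().items():
        if label == "unassigned" or not members:
            continue
        table = enrich(members & universe, markers, universe, alpha=alpha)
        if len(table) and bool(table.iloc[0]["significant"]):
            names[label] = str(table.iloc[0]["term"])
    return names


def run_pipeline(
    config: PipelineConfig,
    counts_a: CountMatrix,
    counts_b: CountMatrix,
    phen_a: PhenotypeTable,
    phen_b: PhenotypeTable,
    out_dir: str | Path,
    markers: GeneSetCollection | None = None,
    gene_sets: GeneSetCollection | None = None,
) -> dict:
    """Run all stages; returns the manifest dictionary.

    ``markers`` (optional GMT) names detected communities — in particular
    the structural-muscle cluster used for the composition covariate; when
    absent, the muscle community is located by correlating community mean
    expression with the measured muscle depth.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.rng_seed,
        "stages": {},
        "completed": [],
        "partial": True,
    }

    # validate before any computation
    for counts, phen, tag in ((counts_a, phen_a, "A"), (counts_b, phen_b, "B")):
        phen.aligned(counts.sample_ids)
    if config.extreme_group_size > counts_a.n_samples / 2:
        raise ValidationError(
            f"extreme_group_size={config.extreme_group_size} exceeds half of "
            f"{counts_a.n_samples} samples"
        )
    shared_genes = [g for g in counts_a.gene_ids if g in set(counts_b.gene_ids)]
    if not shared_genes:
        raise ValidationError("no shared genes between the two datasets")
    logger.info("shared gene namespace: %d genes", len(shared_genes))
    manifest["shared_genes"] = len(shared_genes)

    state: dict = {}
    for stage in STAGES:
        try:
            _run_stage(
                stage, state, config, counts_a, counts_b, phen_a, phen_b,
                markers, gene_sets, out, manifest,
            )
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            write_manifest(manifest, out / "manifest.json")
            raise StageError(stage, exc) from exc
        manifest["completed"].append(stage)
    manifest["partial"] = False
    write_manifest(manifest, out / "manifest.json")
    return manifest


def _run_stage(
    stage, state, config, counts_a, counts_b, phen_a, phen_b,
    markers, gene_sets, out, manifest,
) -> None:
    info: dict = {}
    manifest["stages"][stage] = info

    if stage == "normalize":
        shared = [g for g in counts_a.gene_ids if g in set(counts_b.gene_ids)]
        ca, cb = counts_a.subset_genes(shared), counts_b.subset_genes(shared)
        universe_a = filter_by_cpm(ca, config.universe_cpm_threshold, "gt")
        universe_b = filter_by_cpm(cb, config.universe_cpm_threshold, "gt")
        net_genes_a = filter_by_cpm(ca, config.cpm_filter_threshold, "ge")
        net_genes_b = filter_by_cpm(cb, config.cpm_filter_threshold, "ge")
        joint_genes = [g for g in net_genes_a if g in set(net_genes_b)]
        expr_a, expr_b = log_cpm(ca), log_cpm(cb)
        expr_a.dataset_labels = [phen_a.dataset] * expr_a.n_samples
        expr_b.dataset_labels = [phen_b.dataset] * expr_b.n_samples
        expr_joint = quantile_normalize_joint(
            expr_a.subset_genes(joint_genes), expr_b.subset_genes(joint_genes)
        )
        state.update(
            counts_a=ca, counts_b=cb, universe_a=universe_a, universe_b=universe_b,
            shared_universe=[g for g in universe_a if g in set(universe_b)],
            net_genes_a=net_genes_a, joint_genes=joint_genes,
            expr_a=expr_a, expr_b=expr_b, expr_joint=expr_joint,
        )
        info.update(
            universe_a=len(universe_a), universe_b=len(universe_b),
            network_genes_a=len(net_genes_a), network_genes_joint=len(joint_genes),
        )

    elif stage == "network":
        net_a, _, _ = network_from_expression(
            state["expr_a"].subset_genes(state["net_genes_a"]), config.edge_r_threshold
        )
        net_joint, _, _ = network_from_expression(
            state["expr_joint"], config.edge_r_threshold
        )
        for name, net in (("network_a", net_a), ("network_joint", net_joint)):
            write_edge_list(
                [(a, b, d["weight"]) for a, b, d in net.edges(data=True)],
                out / f"{name}_edges.tsv",
            )
            info[name] = {"nodes": net.number_of_nodes(), "edges": net.number_of_edges()}
        state.update(net_a=net_a, net_joint=net_joint)

    elif stage == "cluster":
        assignment = detect_communities(state["net_joint"], config.min_community_size)
        universe = set(state["expr_joint"].gene_ids)
        names = _annotate_communities(assignment, markers, universe, config.enrichment_alpha)
        rows = [
            (g, c, names.get(c, "")) for g, c in sorted(assignment.labels.items())
        ]
        write_table(
            pd.DataFrame(rows, columns=["gene", "community", "annotation"]),
            out / "clusters_joint.tsv",
        )
        # the composition signature is the *structural* muscle community
        # only: the cell-junction program is the regulatory signal under
        # study and must not be normalized out with the tissue composition
        muscle_comms = [c for c, n in names.items() if n == "muscle"]
        if not muscle_comms and phen_a.has("muscle_depth"):
            # fall back: the community whose mean expression best tracks the
            # measured muscle depth is the structural-muscle cluster
            best, best_r = None, 0.0
            expr_j = state["expr_joint"]
            a_samples = [s for s, d in zip(expr_j.sample_ids, expr_j.dataset_labels)
                         if d == phen_a.dataset]
            for c, members in assignment.communities().items():
                if c == "unassigned":
                    continue
                means = cluster_mean_expression(expr_j.subset_samples(a_samples), members)
                paired = pd.concat(
                    [means, phen_a.column("muscle_depth")], axis=1, join="inner"
                ).dropna()
                if len(paired) < 3:
                    continue
                r = float(np.corrcoef(paired.iloc[:, 0], paired.iloc[:, 1])[0, 1])
                if r > best_r:
                    best, best_r = c, r
            if best is not None:
                muscle_comms = [best]
        muscle_core = set()
        for c in muscle_comms:
            muscle_core |= assignment.members(c)
        # the signature is restricted to genes present in every network
        muscle_sig = muscle_core & set(state["net_a"].nodes())
        state.update(assignment=assignment, community_names=names, muscle_sig=muscle_sig)
        info.update(
            communities=len(assignment.communities()),
            modularity=assignment.modularity,
            annotations=names,
            muscle_signature_genes=len(muscle_sig),
        )

    elif stage == "associate":
        expr_j = state["expr_joint"]
        labels = pd.Series(expr_j.dataset_labels, index=expr_j.sample_ids)
        phen = pd.concat([phen_a.data, phen_b.data])
        rows, regress_rows = [], []
        named = {
            c: n for c, n in state["community_names"].items()
        } or {c: c for c in state["assignment"].communities() if c != "unassigned"}
        for comm, name in sorted(named.items()):
            members = state["assignment"].members(comm)
            if not members:
                continue
            means = cluster_mean_expression(expr_j, members)
            for pheno in ("ch4_production", "ch4_yield", "dmi", "acetate",
                          "butyrate", "propionate", "mrt"):
                if pheno not in phen.columns:
                    continue
                per_ds = {}
                for ds in sorted(labels.unique()):
                    ids = labels.index[labels == ds]
                    paired = pd.concat(
                        [means.loc[ids], phen.loc[ids, pheno]], axis=1
                    ).dropna()
                    if len(paired) < 4:
                        continue
                    r = float(np.corrcoef(paired.iloc[:, 0], paired.iloc[:, 1])[0, 1])
                    per_ds[ds] = (r, len(paired))
                for ds, (r, n) in per_ds.items():
                    rows.append((name, comm, pheno, ds, r, n, np.nan, np.nan))
                if len(per_ds) == 2:
                    (ra, na), (rb, nb) = per_ds.values()
                    if abs(ra) < 1 and abs(rb) < 1:
                        fz = fisher_z_difference(ra, na, rb, nb)
                        rows[-1] = rows[-1][:6] + (fz.z_diff, fz.p)
                if pheno in ("ch4_production", "ch4_yield") and len(per_ds) == 2:
                    reg = dataset_regressions(means, phen[pheno], labels)
                    inter = reg["interaction"]
                    for ds, fit in reg["per_dataset"].items():
                        regress_rows.append(
                            (name, pheno, ds, fit["slope"], fit["intercept"],
                             fit["n"], inter["coef"], inter["p"])
                        )
        assoc = pd.DataFrame(
            rows,
            columns=["cluster", "community", "phenotype", "dataset", "r", "n",
                     "fisher_z_diff", "fisher_p"],
        )
        write_table(assoc, out / "cluster_phenotype_correlations.tsv")
        write_table(
            pd.DataFrame(
                regress_rows,
                columns=["cluster", "phenotype", "dataset", "slope", "intercept",
                         "n", "slope_diff", "slope_diff_p"],
            ),
            out / "cluster_phenotype_regressions.tsv",
        )
        state["associations"] = assoc
        info["rows"] = len(assoc)

    elif stage == "select":
        shared_u = state["shared_universe"]
        ea = state["expr_a"].subset_genes(shared_u)
        eb = state["expr_b"].subset_genes(shared_u)
        results = {}
        for pheno in SELECTION_PHENOTYPES:
            if not (phen_a.has(pheno) and phen_b.has(pheno)):
                continue
            corr_a = correlate_genes_with_phenotype(ea, phen_a.column(pheno))
            corr_b = correlate_genes_with_phenotype(eb, phen_b.column(pheno))
            result = select_consistent(corr_a, corr_b, ea, eb, config, phenotype=pheno)
            results[pheno] = result
            info[pheno] = result.stage_counts
        frames = [
            r.table.assign(phenotype=p).reset_index()
            for p, r in results.items()
            if len(r.table)
        ]
        combined = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["gene", "r_a", "r_b", "phenotype"])
        )
        write_table(combined[["gene", "phenotype", "r_a", "r_b"]],
                    out / "consistent_genes.tsv")
        state["consistent"] = results

    elif stage == "de":
        if not phen_a.has("mrt"):
            info["skipped"] = "no retention-time phenotype in dataset A"
            state["prioritized"] = pd.DataFrame()
            return
        universe_a = state["universe_a"]
        expr_a_u = state["expr_a"].subset_genes(universe_a)
        muscle_sig = state["muscle_sig"]
        if not muscle_sig:
            raise ValidationError("no structural-muscle signature genes identified")
        # muscle-composition-normalized transcriptome for the correlation
        # rankings (joint matrix: yield uses both datasets, MRT only A)
        joint_m = muscle_normalize(
            state["expr_joint"], muscle_sig & set(state["expr_joint"].gene_ids)
        )
        labels = pd.Series(joint_m.dataset_labels, index=joint_m.sample_ids)
        a_ids = list(labels.index[labels == phen_a.dataset])
        corr_mrt = correlate_genes_with_phenotype(
            joint_m.subset_samples(a_ids), phen_a.column("mrt")
        )
        yield_all = pd.concat([phen_a.column("ch4_yield"), phen_b.column("ch4_yield")])
        corr_yield = correlate_genes_with_phenotype(joint_m, yield_all)
        ranked = rank_joint_negative(corr_mrt, corr_yield, config.top_k)

        short, long_ = select_extremes(phen_a.column("mrt"), config.extreme_group_size)
        extreme = short + long_
        group = pd.Series(
            ["short"] * len(short) + ["long"] * len(long_), index=extreme
        )
        block = phen_a.data["block"].astype(str)
        sig_series = cluster_mean_expression(
            state["expr_a"], muscle_sig & set(state["expr_a"].gene_ids)
        )
        de1 = de_fit(
            expr_a_u.subset_samples(extreme), group,
            block=block.loc[extreme], covariate=sig_series.loc[extreme],
        )
        write_table(de1.reset_index(names="gene"), out / "de_muscle_signature.tsv")
        info["de_muscle_signature_significant"] = int((de1["q"] < config.de_fdr_threshold).sum())
        if phen_a.has("muscle_depth"):
            de2 = de_fit(
                expr_a_u.subset_samples(extreme), group,
                block=block.loc[extreme],
                covariate=phen_a.column("muscle_depth").loc[extreme],
            )
            write_table(de2.reset_index(names="gene"), out / "de_muscle_depth.tsv")
            info["de_muscle_depth_significant"] = int(
                (de2["q"] < config.de_fdr_threshold).sum()
            )
        final = prioritize(de1, ranked, config.de_fdr_threshold, corr_mrt, corr_yield)
        write_table(final.reset_index(names="gene"), out / "prioritized_mrt_genes.tsv")
        state.update(prioritized=final, ranked=ranked, corr_mrt=corr_mrt,
                     corr_yield=corr_yield, de1=de1)
        info.update(ranked=len(ranked), prioritized=len(final))

    elif stage == "enrich":
        if gene_sets is None:
            info["skipped"] = "no gene-set collection supplied"
            return
        universe = set(state["shared_universe"])
        tables = []
        queries = {"prioritized_mrt": set(state.get("prioritized", pd.DataFrame()).index)}
        for pheno, result in state.get("consistent", {}).items():
            queries[f"consistent_{pheno}"] = set(result.genes)
        for name, query in queries.items():
            query &= universe
            if not query:
                continue
            table = enrich(query, gene_sets, universe, alpha=config.enrichment_alpha)
            tables.append(table.assign(query=name))
        combined = (
            pd.concat(tables, ignore_index=True)
            if tables
            else pd.DataFrame(columns=["query", "term", "k", "p", "adj_p"])
        )
        write_table(combined, out / "enrichment.tsv")
        info["rows"] = len(combined)
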