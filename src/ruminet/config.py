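"""Pipeline and simulation configuration.

Defaults encode the analysis constants of the study design this package
reproduces: a >0.8 co-expression edge threshold, top-33% gene-phenotype
correlation tercile, a 0.15 floor on between-dataset correlation
consistency, FDR < 0.1 for differential expression, top-200 joint negative
ranking, and 10+10 extreme retention-time animals.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

CLUSTER_LABELS = (
    "muscle",
    "muscle_junction",
    "cell_cycle",
    "epithelial_diff",
    "general_metab",
    "lipid_oxo",
)
BACKGROUND = "background"


@dataclass
class PipelineConfig:
    # CPM filtering: the co-expression network uses ">= 3 CPM in all samples";
    # the gene universe for phenotype correlation uses "> 1 CPM in all samples".
    cpm_filter_threshold: float = 3.0
    cpm_filter_mode: str = "all_samples"
    universe_cpm_threshold: float = 1.0
    edge_r_threshold: float = 0.8
    tercile_fraction: float = 1.0 / 3.0
    min_abs_r: float = 0.15
    de_fdr_threshold: float = 0.1
    top_k: int = 200
    extreme_group_size: int = 10
    enrichment_alpha: float = 0.05
    min_community_size: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.edge_r_threshold <= 1.0):
            raise ValueError("edge_r_threshold must be in [0, 1]")
        if not (0.0 < self.tercile_fraction < 1.0):
            raise ValueError("tercile_fraction must be in (0, 1)")
        if not (0.0 <= self.min_abs_r <= 1.0):
            raise ValueError("min_abs_r must be in [0, 1]")
        if not (0.0 < self.de_fdr_threshold <= 1.0):
            raise ValueError("de_fdr_threshold must be in (0, 1]")
        if not (0.0 < self.enrichment_alpha <= 1.0):
            raise ValueError("enrichment_alpha must be in (0, 1]")
        if self.cpm_filter_threshold <= 0:
            raise ValueError("cpm_filter_threshold must be > 0")
        if self.cpm_filter_mode != "all_samples":
            raise ValueError("only cpm_filter_mode='all_samples' is supported")
        if self.top_k < 1 or self.extreme_group_size < 1:
            raise ValueError("top_k and extreme_group_size must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def _default_cluster_sizes() -> dict[str, int]:
    # Scaled-down emulation of the named functional clusters; sizes are a
    # fixed fraction of the 1000-gene default universe, with the remainder
    # unclustered background.
    return {
        "muscle": 70,
        "muscle_junction": 30,
        "cell_cycle": 40,
        "epithelial_diff": 50,
        "general_metab": 80,
        "lipid_oxo": 40,
    }


def _default_effect_map() -> dict[str, list[tuple[str, float]]]:
    # phenotype -> [(cluster, target Pearson r with the cluster activity)]
    # CH4 yield rises with lipid/oxo-acid metabolism activity and falls with
    # muscle cell-junction activity (the retention-time path); retention time
    # itself is negatively driven by the junction program; the three SCFAs
    # share a positive link to epithelial cell-cycle activity.
    return {
        "ch4_yield": [("lipid_oxo", 0.45), ("muscle_junction", -0.45)],
        "mrt": [("muscle_junction", -0.58)],
        "acetate": [("cell_cycle", 0.40)],
        "butyrate": [("cell_cycle", 0.40)],
        "propionate": [("cell_cycle", 0.40)],
    }


@dataclass
class SimConfig:
    """Generator settings for the paired two-experiment synthetic data.

    The defaults are the study conditions: 62 samples in four blocks
    (16/16/14/16) for experiment A and 24 samples for experiment B, with
    retention time measured in A only.
    """

    n_genes: int = 1000
    n_samples_a: int = 62
    n_samples_b: int = 24
    n_blocks_a: int = 4
    block_sizes_a: tuple[int, ...] = (16, 16, 14, 16)
    cluster_sizes: dict[str, int] = field(default_factory=_default_cluster_sizes)
    effect_map: dict[str, list[tuple[str, float]]] = field(default_factory=_default_effect_map)
    # log2-scale generative parameters
    loading_mean: float = 1.6
    loading_mean_junction: float = 1.8
    loading_mean_muscle: float = 0.5
    loading_sd: float = 0.15
    compartment_loading_muscle: float = 1.6
    compartment_loading_junction: float = 1.0
    compartment_loading_epithelial: float = 0.7
    noise_sd: float = 0.25
    block_sd: float = 0.15
    baseline_mean: float = 0.0
    baseline_sd: float = 1.2
    # clustered genes sit at moderate abundance (well above the CPM filters
    # for the default library sizes) so that no single co-expressed program
    # holds a large share of the library; coherent activity swings of a
    # high-mass cluster would otherwise move every gene's log-CPM through
    # the per-sample total-count normalization
    cluster_baseline_mean: float = -1.0
    cluster_baseline_sd: float = 0.5
    nb_dispersion: float = 0.1
    libsize_log_mean: float = 14.5  # ln scale; exp(14.5) ~ 2.0e6 reads
    libsize_log_sd: float = 0.15
    # muscle fraction (logit scale) and its optional coupling to retention
    # time; the default is 0 — wall muscle thickness and retention time are
    # uncorrelated in the experiments emulated here — but a nonzero value
    # plants a composition-group confound for covariate-adjustment tests
    muscle_logit_sd: float = 0.5
    mrt_muscle_fraction_r: float = 0.0
    # phenotype units
    yield_mean_a: float = 19.0
    yield_mean_b: float = 21.5
    yield_sd: float = 1.5
    dmi_mean_a: float = 1.5
    dmi_mean_b: float = 1.1
    dmi_sd: float = 0.2
    dmi_yield_r: float = -0.33
    mrt_mean: float = 30.0
    mrt_sd: float = 4.0
    scfa_means_a: tuple[float, float, float] = (75.0, 11.0, 22.0)
    scfa_means_b: tuple[float, float, float] = (60.0, 9.0, 18.0)
    scfa_sds: tuple[float, float, float] = (10.0, 2.5, 4.0)
    scfa_shared_weight: float = 0.7
    block1_epithelial_shift: float = 0.0  # optional depressed block-1 anomaly
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.cluster_sizes.values()) > self.n_genes:
            raise ValueError("cluster sizes exceed n_genes")
        unknown = set(self.cluster_sizes) - set(CLUSTER_LABELS)
        if unknown:
            raise ValueError(f"unknown cluster labels: {sorted(unknown)}")
        for pheno, links in self.effect_map.items():
            for cluster, r in links:
                if cluster not in CLUSTER_LABELS:
                    raise ValueError(f"effect_map references unknown cluster {cluster!r}")
                if abs(r) > 0.9:
                    raise ValueError(
                        f"infeasible target correlation {r} for {pheno}: |r| must be <= 0.9"
                    )
        for name in ("loading_sd", "noise_sd", "libsize_log_sd", "yield_sd", "dmi_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if len(self.block_sizes_a) != self.n_blocks_a:
            raise ValueError("block_sizes_a length must equal n_blocks_a")
        if sum(self.block_sizes_a) != self.n_samples_a:
            raise ValueError("block_sizes_a must sum to n_samples_a")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["block_sizes_a"] = list(self.block_sizes_a)
        return d

    @classmethod
    def scaled(cls, n_genes: int, **overrides) -> "SimConfig":
        """Default configuration with cluster sizes scaled proportionally
        to a different gene-universe size."""
        factor = n_genes / cls().n_genes
        sizes = {k: max(2, int(round(v * factor))) for k, v in _default_cluster_sizes().items()}
        return cls(n_genes=n_genes, cluster_sizes=sizes, **overrides)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a PipelineConfig from JSON or YAML (by extension)."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return PipelineConfig(**(data or {}))
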