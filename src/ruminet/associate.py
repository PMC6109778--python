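"""Gene/cluster-phenotype correlation and between-experiment comparison.

Correlations are plain Pearson with a two-sided t-test
(t = r * sqrt((n-2)/(1-r^2)), df = n-2). Phenotype missing values are
dropped pairwise, so n varies per record.

The between-experiment comparison uses the Fisher variance-stabilizing
transform z = atanh(r): the standardized difference of two independent
correlations is

    z_diff = |z_a - z_b| / sqrt(1/(n_a - 3) + 1/(n_b - 3)),

referred to the standard normal (two-sided).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import ExpressionMatrix, ValidationError


@dataclass
class CorrelationRecord:
    unit: str
    phenotype: str
    dataset: str
    r: float
    n: int
    p: float
    undefined: bool = False


@dataclass
class FisherZResult:
    z_a: float
    z_b: float
    n_a: int
    n_b: int
    z_diff: float
    p: float


def cluster_mean_expression(expr: ExpressionMatrix, genes: set[str]) -> pd.Series:
    """Per-sample arithmetic mean expression over a gene set."""
    if not genes:
        raise ValidationError("empty gene set")
    index = expr.gene_index()
    missing = sorted(g for g in genes if g not in index)
    if missing:
        raise ValidationError(f"genes absent from expression matrix: {missing[:5]}")
    rows = [index[g] for g in sorted(genes)]
    return pd.Series(expr.values[rows, :].mean(axis=0), index=expr.sample_ids)


def correlate_with_phenotype(
    values: pd.Series,
    phenotype: pd.Series,
    unit: str = "",
    phenotype_name: str = "",
    dataset: str = "",
) -> CorrelationRecord:
    """Pearson r and two-sided t-based p for paired complete observations."""
    paired = pd.concat([values, phenotype], axis=1, join="inner").dropna()
    n = len(paired)
    if n < 3:
        raise ValidationError(f"need >= 3 paired complete observations, got {n}")
    x = paired.iloc[:, 0].to_numpy(dtype=float)
    y = paired.iloc[:, 1].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationRecord(
            unit=unit, phenotype=phenotype_name, dataset=dataset,
            r=float("nan"), n=n, p=float("nan"), undefined=True,
        )
    r, p = stats.pearsonr(x, y)
    return CorrelationRecord(
        unit=unit, phenotype=phenotype_name, dataset=dataset,
        r=float(r), n=n, p=float(p),
    )


def correlate_genes_with_phenotype(
    expr: ExpressionMatrix, phenotype: pd.Series
) -> pd.DataFrame:
    """Vectorized per-gene Pearson correlation against one phenotype.

    Returns a DataFrame indexed by gene with columns r, n, p. Samples with
    missing phenotype are dropped (pairwise-complete convention).
    """
    pheno = phenotype.reindex(expr.sample_ids)
    keep = pheno.notna().to_numpy()
    n = int(keep.sum())
    if n < 3:
        raise ValidationError("need >= 3 samples with phenotype values")
    x = expr.values[:, keep]
    y = pheno.to_numpy(dtype=float)[keep]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isfinite(t), p, 0.0)
    p = np.where(np.isnan(r), np.nan, p)
    return pd.DataFrame({"r": r, "n": n, "p": p}, index=expr.gene_ids)


def fisher_z_difference(r_a: float, n_a: int, r_b: float, n_b: int) -> FisherZResult:
    """Fisher-Z test for the difference of two independent correlations."""
    for r, n, tag in ((r_a, n_a, "first"), (r_b, n_b, "second")):
        if abs(r) >= 1.0:
            raise ValidationError(f"|r| = 1 in {tag} sample: Fisher transform infinite")
        if n <= 3:
            raise ValidationError(f"n must exceed 3 in {tag} sample (got {n})")
    z_a = float(np.arctanh(r_a))
    z_b = float(np.arctanh(r_b))
    se = np.sqrt(1.0 / (n_a - 3) + 1.0 / (n_b - 3))
    z_diff = abs(z_a - z_b) / se
    p = min(1.0, 2.0 * float(stats.norm.sf(z_diff)))
    return FisherZResult(z_a=z_a, z_b=z_b, n_a=n_a, n_b=n_b, z_diff=float(z_diff), p=p)


def dataset_regressions(
    values: pd.Series, phenotype: pd.Series, dataset_labels: pd.Series
) -> dict:
    """Per-dataset OLS of phenotype on a predictor, plus a pooled
    slope-difference (interaction) t-test.

    Returns per-dataset slope/intercept and, when two datasets are present,
    the interaction coefficient of ``phenotype ~ value * dataset`` with its
    p-value. With a single dataset the interaction test is skipped and
    flagged.
    """
    df = pd.DataFrame(
        {"value": values, "phenotype": phenotype, "dataset": dataset_labels}
    ).dropna()
    out: dict = {"per_dataset": {}, "interaction": None, "interaction_skipped": False}
    datasets = sorted(df["dataset"].unique())
    for ds in datasets:
        sub = df[df["dataset"] == ds]
        if len(sub) < 3:
            raise ValidationError(f"need >= 3 samples per dataset (dataset {ds!r})")
        X = sm.add_constant(sub["value"].to_numpy())
        fit = sm.OLS(sub["phenotype"].to_numpy(), X).fit()
        out["per_dataset"][ds] = {
            "intercept": float(fit.params[0]),
            "slope": float(fit.params[1]),
            "slope_se": float(fit.bse[1]),
            "n": int(len(sub)),
        }
    if len(datasets) < 2:
        out["interaction_skipped"] = True
        return out
    indicator = (df["dataset"] == datasets[1]).astype(float).to_numpy()
    v = df["value"].to_numpy()
    X = np.column_stack([np.ones(len(df)), v, indicator, v * indicator])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("singular pooled design (value confounded with dataset)")
    fit = sm.OLS(df["phenotype"].to_numpy(), X).fit()
    out["interaction"] = {
        "coef": float(fit.params[3]),
        "p": float(fit.pvalues[3]),
        "intercept_shift": float(fit.params[2]),
        "intercept_shift_p": float(fit.pvalues[2]),
    }
    return out
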