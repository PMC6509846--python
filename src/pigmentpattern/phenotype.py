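"""Linking pattern phenotype to gene expression across a hybrid series.

Each hybrid individual carries a phenotype (pattern simplicity score,
colour tone, red fraction) and per-region log2 expression ratios.  Region
values are averaged per individual (missing regions — e.g. a fish without
red spots — are skipped, not zero-filled) and correlated with the chosen
phenotype axis.  Both Pearson's r and Spearman's rho are reported with
two-sided p-values; Spearman is the primary statistic, being rank-based
and robust on the bounded PSS scale.  Correlations can also be scoped to a
single region (e.g. expression in red spots vs overall colour tone).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CorrelationResult", "average_expression_per_individual",
           "correlate_expression_phenotype", "region_scoped_correlation",
           "correlate_genes", "phenotype_plane"]


@dataclass
class CorrelationResult:
    gene: str
    scope: str            # "all-regions" or "region:<label>"
    metric: str           # phenotype axis ("pss" or "tone")
    n: int
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    flag: str = ""        # "zero-variance" when coefficients are undefined


def average_expression_per_individual(individual: pd.DataFrame) -> pd.DataFrame:
    """Mean log2 ratio over available regions, per gene and individual.

    Parameters
    ----------
    individual :
        Long table with columns gene, region, individual, log2_ratio
        (the ``individual`` member of
        :func:`pigmentpattern.qpcr.expression_table`).

    Returns
    -------
    pandas.DataFrame
        Columns gene, individual, mean_log2_ratio, n_regions.
    """
    if individual.empty:
        return pd.DataFrame(columns=["gene", "individual", "mean_log2_ratio",
                                     "n_regions"])
    out = (individual.dropna(subset=["log2_ratio"])
           .groupby(["gene", "individual"], sort=False)["log2_ratio"]
           .agg(["mean", "count"]).reset_index())
    return out.rename(columns={"mean": "mean_log2_ratio",
                               "count": "n_regions"})


def correlate_expression_phenotype(values, phenotype, gene: str = "",
                                   scope: str = "all-regions",
                                   metric: str = "pss") -> CorrelationResult:
    """Pearson and Spearman association of paired expression and phenotype.

    Pairs with a missing value on either side are dropped; at least 3
    complete pairs are required.  Zero variance in either vector leaves
    the coefficients undefined (NaN) with the flag "zero-variance".
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if len(x) != len(y):
        raise ValueError("expression and phenotype vectors differ in length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError(f"need >= 3 complete pairs, have {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(gene=gene, scope=scope, metric=metric,
                                 n=len(x), pearson_r=float("nan"),
                                 pearson_p=float("nan"),
                                 spearman_rho=float("nan"),
                                 spearman_p=float("nan"),
                                 flag="zero-variance")
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return CorrelationResult(gene=gene, scope=scope, metric=metric, n=len(x),
                             pearson_r=float(pr.statistic),
                             pearson_p=float(pr.pvalue),
                             spearman_rho=float(sr.statistic),
                             spearman_p=float(sr.pvalue))


def region_scoped_correlation(individual: pd.DataFrame, region: str,
                              phenotype: pd.DataFrame, gene: str,
                              metric: str = "tone") -> CorrelationResult:
    """Correlation restricted to one region's expression values.

    Parameters
    ----------
    individual :
        Per-individual, per-region log2 ratios (long table).
    region :
        Region label to restrict to; fewer than 3 individuals carrying it
        is a refusal (ValueError naming the count).
    phenotype :
        Table with columns individual and the chosen `metric`.
    """
    sub = individual[(individual["gene"] == gene)
                     & (individual["region"] == region)]
    merged = sub.merge(phenotype[["individual", metric]], on="individual")
    merged = merged.dropna(subset=["log2_ratio", metric])
    if len(merged) < 3:
        raise ValueError(f"region {region!r}: only {len(merged)} individuals "
                         "with data (need >= 3)")
    return correlate_expression_phenotype(merged["log2_ratio"], merged[metric],
                                          gene=gene, scope=f"region:{region}",
                                          metric=metric)


def correlate_genes(individual: pd.DataFrame, phenotype: pd.DataFrame,
                    metric: str = "pss") -> pd.DataFrame:
    """Region-averaged expression vs phenotype, for every gene.

    Returns one row per gene with both correlation statistics; genes with
    fewer than 3 paired individuals are skipped.
    """
    avg = average_expression_per_individual(individual)
    rows = []
    for gene, sub in avg.groupby("gene", sort=False):
        merged = sub.merge(phenotype[["individual", metric]], on="individual")
        try:
            res = correlate_expression_phenotype(
                merged["mean_log2_ratio"], merged[metric], gene=gene,
                metric=metric)
        except ValueError:
            continue
        rows.append(vars(res))
    return pd.DataFrame(rows)


def phenotype_plane(phenotypes: pd.DataFrame, out_figure=None) -> pd.DataFrame:
    """PSS-vs-tone phenotype plane, optionally drawn to a figure file.

    Parameters
    ----------
    phenotypes :
        Columns individual, pss, tone and optionally group (e.g.
        "spotted" / "hybrid" / "labyrinth"); missing group defaults to
        "hybrid".

    Returns
    -------
    pandas.DataFrame
        (individual, pss, tone, group) sorted by group then individual.
    """
    if phenotypes.empty:
        raise ValueError("phenotype table is empty")
    df = phenotypes.copy()
    if "group" not in df.columns:
        df["group"] = "hybrid"
    df = df[["individual", "pss", "tone", "group"]] \
        .sort_values(["group", "individual"], ignore_index=True)

    if out_figure is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        palette = {"spotted": "#888888", "hybrid": "#e75480",
                   "labyrinth": "#4169aa"}
        fig, axis = plt.subplots(figsize=(5, 4))
        for grp, sub in df.groupby("group", sort=True):
            axis.scatter(sub["tone"], sub["pss"], s=35,
                         color=palette.get(grp, "#444444"), label=grp)
        axis.set_xlabel("overall colour tone (white fraction)")
        axis.set_ylabel("pattern simplicity score")
        axis.set_xlim(0, 1)
        axis.set_ylim(0, 1.05)
        axis.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        fig.savefig(out_figure, dpi=120)
        plt.close(fig)
    return df
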