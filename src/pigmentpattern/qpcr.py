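"""Efficiency-corrected relative qPCR quantification.

Workflow: estimate per-gene amplification factors E from dilution-series
standard curves (E = 10^(-1/slope)), screen candidate reference genes for
stability, then convert Cq tables into expression ratios with the Pfaffl
model,

    ratio(group) = E_target^dCq_target / geomean_j( E_j^dCq_j ),

where dCq = Cq(calibrator) - Cq(group) and the geometric mean runs over
the reference genes j.  Ratios are reported per individual (against the
calibrator group's mean Cq), log2-transformed, and compared between groups
with an unpaired two-sided Student's t-test (pooled variance), starred at
p < 0.05 / 0.01 / 0.001.  With every efficiency equal to 2 the ratio
reduces exactly to the classic 2^-ddCq.

Efficiencies are handled as amplification factors E; the conventional
"percent efficiency" is (E - 1)·100, so 100% means perfect doubling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EfficiencyEstimate", "efficiency_from_standard_curve",
    "percent_to_factor", "factor_to_percent", "efficiency_factors",
    "screen_reference_genes", "pfaffl_ratio", "expression_table",
    "ExpressionTables", "significance_stars", "TROUT_PANEL_EFFICIENCY_PCT",
]

#: Percent amplification efficiencies of the brown/marble trout qPCR primer
#: panel (targets plus the two reference genes rps20 and pgk), usable as a
#: fixture input for efficiency-corrected analyses.
TROUT_PANEL_EFFICIENCY_PCT = {
    "rps20": 99.8, "pgk": 98.1, "dct": 110.3, "mitf": 93.5, "tyr": 96.4,
    "tyrp1": 99.3, "pmel": 93.5, "mc1r": 96.5, "ednrb": 109.7, "sox10": 99.7,
    "aox1": 116.2, "cdkn1a": 106.4, "wnt10a": 117.5, "wnt9b": 100.2,
    "gja1": 87.4, "gja4": 102.5, "gja5": 91.2, "gja9": 112.4, "gjb1": 101.5,
    "gjb3": 96.7, "gjb4": 99.7, "gjd2": 117.5, "tjp1": 109.8, "tspan3": 99.6,
    "slc7a2": 89.0, "slco1c1": 92.3, "kcnc2": 94.8, "clcn2": 92.9,
    "pcdhac2": 106.4,
}


def percent_to_factor(percent: float) -> float:
    """Amplification factor E from percent efficiency: E = 1 + pct/100."""
    if not 0.0 < percent <= 150.0:
        raise ValueError(f"percent efficiency {percent} outside (0, 150]")
    return 1.0 + percent / 100.0


def factor_to_percent(factor: float) -> float:
    return (factor - 1.0) * 100.0


@dataclass
class EfficiencyEstimate:
    """Standard-curve fit for one gene."""

    gene: str
    slope: float          # cycles per log10 dilution, < 0
    efficiency: float     # amplification factor E = 10^(-1/slope)
    percent: float        # (E - 1) * 100
    r_squared: float


def efficiency_from_standard_curve(points, gene: str = "") -> EfficiencyEstimate:
    """Fit a dilution series and derive the amplification factor.

    Parameters
    ----------
    points :
        Sequence of ``(log10_dilution, cq)`` pairs or a DataFrame with
        columns ``log10_dilution`` and ``cq``; at least 3 distinct
        dilution levels are required.
    """
    if isinstance(points, pd.DataFrame):
        x = points["log10_dilution"].to_numpy(float)
        y = points["cq"].to_numpy(float)
    else:
        arr = np.asarray(points, dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    if len(np.unique(x)) < 3:
        raise ValueError("standard curve needs >= 3 distinct dilution points")
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValueError(
            f"standard curve failed: non-negative slope {fit.slope:.3f}")
    E = 10.0 ** (-1.0 / fit.slope)
    return EfficiencyEstimate(gene=gene, slope=float(fit.slope),
                              efficiency=float(E),
                              percent=float(factor_to_percent(E)),
                              r_squared=float(fit.rvalue**2))


def efficiency_factors(source) -> dict:
    """Normalize an efficiency source to a {gene: factor E} mapping.

    Accepts a DataFrame with columns ``gene`` and ``percent_efficiency``
    (panel-table style), or a mapping of gene to either percent (> 10) or
    factor (<= 2.5) — the scales do not overlap, so the unit is inferred.
    """
    if isinstance(source, pd.DataFrame):
        return {str(r.gene): percent_to_factor(float(r.percent_efficiency))
                for r in source.itertuples(index=False)}
    out = {}
    for gene, val in source.items():
        v = float(val)
        out[gene] = percent_to_factor(v) if v > 2.5 else v
    return out


def _sample_means(cq: pd.DataFrame) -> pd.DataFrame:
    """Collapse technical replicates: mean Cq per individual x region x gene."""
    return (cq.groupby(["individual", "region", "gene"], sort=False)["cq"]
            .mean().reset_index())


def screen_reference_genes(cq: pd.DataFrame, candidates) -> pd.DataFrame:
    """Rank candidate reference genes by expression stability.

    Stability is the standard deviation of replicate-averaged Cq across
    all samples (individual x region); stable genes sit at the same level
    everywhere, so a lower SD ranks higher.  Candidates missing from some
    sample group are excluded with a warning.  The top two are flagged
    ``chosen`` (two references are needed for geometric-mean
    normalization); a single usable candidate is returned with a warning.

    Returns
    -------
    pandas.DataFrame
        Columns gene, stability_sd, n_samples, rank, chosen — sorted by
        ascending SD.
    """
    means = _sample_means(cq)
    groups = set(zip(means["individual"], means["region"]))
    rows = []
    for gene in candidates:
        sub = means[means["gene"] == gene]
        have = set(zip(sub["individual"], sub["region"]))
        if have != groups:
            warnings.warn(f"reference candidate {gene!r} missing in "
                          f"{len(groups - have)} sample(s); excluded",
                          stacklevel=2)
            continue
        rows.append({"gene": gene, "stability_sd": float(sub["cq"].std(ddof=1)),
                     "n_samples": len(sub)})
    if not rows:
        raise ValueError("no reference candidate measured in every sample")
    out = pd.DataFrame(rows).sort_values("stability_sd", kind="stable",
                                         ignore_index=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out["chosen"] = out["rank"] <= 2
    if len(out) < 2:
        warnings.warn("only one usable reference candidate; two are required "
                      "for geometric-mean normalization", stacklevel=2)
    return out


def pfaffl_ratio(target_cq: Mapping[str, float],
                 reference_cq: Mapping[str, Mapping[str, float]],
                 efficiencies: Mapping[str, float],
                 calibrator: str) -> dict:
    """Efficiency-corrected expression ratio of each group vs the calibrator.

    Parameters
    ----------
    target_cq :
        Mean Cq of the target gene per group.
    reference_cq :
        Per reference gene, mean Cq per group.
    efficiencies :
        Amplification factor E per gene; the target's E is looked up under
        the key ``"target"`` if present, else every reference key must
        exist and the remaining key is the target's.
    calibrator :
        Group all ratios are expressed against (its own ratio is 1).

    Returns
    -------
    dict
        group -> ratio; NaN (with a warning) where a reference
        measurement is missing for the group.
    """
    if calibrator not in target_cq:
        raise ValueError(f"calibrator group {calibrator!r} missing from target Cq")
    e_target = efficiencies.get("target")
    if e_target is None:
        leftover = [g for g in efficiencies if g not in reference_cq]
        if len(leftover) != 1:
            raise ValueError("cannot identify the target efficiency; supply "
                             "it under the key 'target'")
        e_target = efficiencies[leftover[0]]

    out = {}
    for group, cq in target_cq.items():
        num = e_target ** (target_cq[calibrator] - cq)
        logs = []
        ok = True
        for ref, per_group in reference_cq.items():
            if group not in per_group or calibrator not in per_group:
                warnings.warn(f"group {group!r}: missing reference {ref!r} "
                              "measurement; ratio flagged NaN", stacklevel=2)
                ok = False
                break
            logs.append(np.log(efficiencies[ref])
                        * (per_group[calibrator] - per_group[group]))
        out[group] = float(num / np.exp(np.mean(logs))) if ok else float("nan")
    return out


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


class ExpressionTables(NamedTuple):
    """``summary`` per gene x region; ``individual`` per-fish log2 ratios."""

    summary: pd.DataFrame
    individual: pd.DataFrame


def expression_table(cq: pd.DataFrame, efficiencies,
                     references=("rps20", "pgk1"),
                     calibrator: str = "BTB") -> ExpressionTables:
    """Reference-normalized log2 expression ratios per gene x region.

    Technical replicates are first collapsed to per-individual mean Cq.
    Each individual's Pfaffl ratio is computed against the calibrator
    group's mean Cq (so a t-test against the calibrator group is
    possible); the calibrator group's mean log2 ratio is 0 by
    construction.  Groups are compared to the calibrator with an unpaired
    two-sided Student's t-test (pooled variance); groups with fewer than
    two individuals, or zero variance, carry a NaN p-value.

    Parameters
    ----------
    cq :
        Long table with columns individual, region, gene, replicate, cq.
    efficiencies :
        Anything :func:`efficiency_factors` accepts.
    references :
        Reference gene names (>= 2 expected); must appear in `cq`.
    calibrator :
        Region label all ratios are expressed against.

    Returns
    -------
    ExpressionTables
        ``summary``: gene, region, n, log2_ratio_mean, sd, t, p, stars.
        ``individual``: gene, region, individual, log2_ratio.
    """
    eff = efficiency_factors(efficiencies)
    references = list(references)
    for g in references:
        if g not in set(cq["gene"]):
            raise ValueError(f"reference gene {g!r} absent from Cq table")
        if g not in eff:
            raise ValueError(f"no efficiency for reference gene {g!r}")

    means = _sample_means(cq)
    if calibrator not in set(means["region"]):
        raise ValueError(f"calibrator region {calibrator!r} absent from Cq table")
    wide = means.pivot_table(index=["region", "individual"], columns="gene",
                             values="cq")
    cal_mean = wide.loc[calibrator].mean()  # per-gene calibrator group mean Cq

    targets = [g for g in means["gene"].unique() if g not in references]
    log2e = {g: np.log2(e) for g, e in eff.items()}

    indiv_rows = []
    for gene in targets:
        if gene not in eff:
            raise ValueError(f"no efficiency for gene {gene!r}")
        d_target = cal_mean[gene] - wide[gene]
        ref_term = sum(log2e[r] * (cal_mean[r] - wide[r]) for r in references) \
            / len(references)
        log2_ratio = log2e[gene] * d_target - ref_term
        for (region, individual), val in log2_ratio.items():
            if np.isfinite(val):
                indiv_rows.append({"gene": gene, "region": region,
                                   "individual": individual,
                                   "log2_ratio": float(val)})
    individual = pd.DataFrame(indiv_rows)

    summary_rows = []
    for gene in targets:
        per_gene = individual[individual["gene"] == gene]
        cal_vals = per_gene.loc[per_gene["region"] == calibrator,
                                "log2_ratio"].to_numpy()
        for region, sub in per_gene.groupby("region", sort=False):
            vals = sub["log2_ratio"].to_numpy()
            t = p = float("nan")
            if (region != calibrator and len(vals) >= 2 and len(cal_vals) >= 2
                    and vals.std() + cal_vals.std() > 1e-10):
                t, p = stats.ttest_ind(vals, cal_vals, equal_var=True)
            summary_rows.append({
                "gene": gene, "region": region, "n": len(vals),
                "log2_ratio_mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) >= 2 else float("nan"),
                "t": float(t), "p": float(p),
                "stars": significance_stars(p),
            })
    return ExpressionTables(summary=pd.DataFrame(summary_rows),
                            individual=individual)
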