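"""Synthetic qPCR Cq tables with known expression ground truth.

The generative model for one well (gene g, region r, individual i,
technical replicate t) is

    Cq = baseline_g + offset_{g,r} + slope_g * PSS_i + fish_i + eps,

with ``fish_i ~ N(0, individual_sd²)`` shared across all genes and
replicates of an individual (biological replicate structure) and
``eps ~ N(0, noise_sd²)`` independent per well.  Reference genes have zero
offsets in every region.  The true efficiency-corrected expression ratio of
(g, r) versus a calibrator region follows from the offsets alone:

    log2 ratio = (offset_{g,cal} - offset_{g,r}) * log2(E_g).

Two sampling layouts are supported: a *region-cohort* layout where each
region has its own individuals (two parental species, several skin regions
each), and a *hybrid* layout where every individual is measured in every
region and may carry a phenotype (PSS) that couples to expression through
``slope_g`` (delta-Cq per unit PSS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["QpcrDesign", "simulate_qpcr", "simulate_standard_curve",
           "coupling_slope_for_r2", "trout_design", "screen_design",
           "hybrid_design"]


@dataclass
class QpcrDesign:
    """Layout and ground truth of a simulated qPCR experiment.

    offsets map gene -> region -> true delta-Cq relative to the gene's
    baseline; efficiencies map gene -> amplification factor E in (1, 2.2];
    coupling_slope maps gene -> delta-Cq per unit PSS (hybrid layout only).
    """

    genes: list
    regions: list
    offsets: dict
    efficiencies: dict
    reference_genes: list
    n_individuals: int = 10
    n_replicates: int = 3
    noise_sd: float = 0.2
    individual_sd: float = 0.3
    baselines: dict = field(default_factory=dict)
    coupling_slope: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if len(self.reference_genes) < 2:
            raise ValueError("need at least 2 reference genes")
        if self.noise_sd < 0 or self.individual_sd < 0:
            raise ValueError("noise/individual SDs must be >= 0")
        if self.n_replicates < 1 or self.n_individuals < 1:
            raise ValueError("replicates and individuals must be >= 1")
        for g in self.genes:
            if g not in self.efficiencies:
                raise ValueError(f"gene {g}: missing efficiency")
            E = self.efficiencies[g]
            if not (1.0 < E <= 2.2):
                raise ValueError(f"gene {g}: efficiency {E} outside (1, 2.2]")
            for r in self.regions:
                if r not in self.offsets.get(g, {}):
                    raise ValueError(f"gene {g}: missing offset for region {r}")
        for g in self.reference_genes:
            if g not in self.genes:
                raise ValueError(f"reference gene {g} not in gene list")
            if any(self.offsets[g][r] != 0.0 for r in self.regions):
                raise ValueError(f"reference gene {g} must have zero offsets")

    def truth_table(self, calibrator: str) -> pd.DataFrame:
        """True log2 expression ratios of every gene x region vs `calibrator`."""
        if calibrator not in self.regions:
            raise ValueError(f"calibrator region {calibrator!r} not in design")
        rows = []
        for g in self.genes:
            e = np.log2(self.efficiencies[g])
            for r in self.regions:
                rows.append({"gene": g, "region": r,
                             "true_log2_ratio":
                                 (self.offsets[g][calibrator]
                                  - self.offsets[g][r]) * e})
        return pd.DataFrame(rows)


def simulate_qpcr(design: QpcrDesign, seed: int | None = None,
                  phenotypes: pd.DataFrame | None = None,
                  calibrator: str | None = None):
    """Draw a Cq table from the design; returns ``(cq_table, truth_table)``.

    Parameters
    ----------
    design :
        The experiment layout and ground truth.
    seed :
        Overrides ``design.seed`` when given.
    phenotypes :
        Hybrid layout: DataFrame with columns ``individual`` and ``pss``;
        each individual is measured in every region and the coupling
        slopes act on its PSS.  When omitted, each region gets its own
        ``design.n_individuals`` individuals.
    calibrator :
        Region for the truth table (default: first region of the design).

    Returns
    -------
    cq : pandas.DataFrame
        Columns sample_id, individual, region, gene, replicate, cq.
    truth : pandas.DataFrame
        Columns gene, region, true_log2_ratio (vs the calibrator).
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    calibrator = calibrator or design.regions[0]

    if phenotypes is not None:
        missing = {"individual", "pss"} - set(phenotypes.columns)
        if missing:
            raise ValueError(f"phenotypes table missing columns {sorted(missing)}")
        indivs = [(str(row.individual), r, float(row.pss))
                  for row in phenotypes.itertuples(index=False)
                  for r in design.regions]
        fish_ids = list(dict.fromkeys(i for i, _, _ in indivs))
    else:
        indivs = [(f"{r}_{i + 1:02d}", r, 0.0)
                  for r in design.regions for i in range(design.n_individuals)]
        fish_ids = [i for i, _, _ in indivs if True]
        fish_ids = list(dict.fromkeys(fish_ids))
    fish_effect = dict(zip(fish_ids,
                           design.individual_sd * rng.standard_normal(len(fish_ids))))

    rows = []
    for indiv, region, pss in indivs:
        for g in design.genes:
            mu = (design.baselines.get(g, 22.0) + design.offsets[g][region]
                  + design.coupling_slope.get(g, 0.0) * pss
                  + fish_effect[indiv])
            eps = design.noise_sd * rng.standard_normal(design.n_replicates)
            for t in range(design.n_replicates):
                rows.append((f"{indiv}:{region}", indiv, region, g, t + 1,
                             mu + eps[t]))
    cq = pd.DataFrame(rows, columns=["sample_id", "individual", "region",
                                     "gene", "replicate", "cq"])
    return cq, design.truth_table(calibrator)


def simulate_standard_curve(efficiency: float, gene: str = "gene",
                            log10_dilutions=(-4, -3, -2, -1, 0),
                            n_replicates: int = 1, noise_sd: float = 0.0,
                            baseline: float = 30.0,
                            seed: int = 0) -> pd.DataFrame:
    """Dilution-series Cq table for a gene with true amplification factor E.

    Cq rises by ``-1/log10(E)`` per tenfold dilution, so fitting a line and
    applying E = 10^(-1/slope) recovers `efficiency` exactly at zero noise.
    """
    if not efficiency > 1.0:
        raise ValueError("efficiency factor must exceed 1")
    rng = np.random.default_rng(seed)
    slope = -1.0 / np.log10(efficiency)
    rows = [{"gene": gene, "log10_dilution": float(d),
             "cq": baseline + slope * float(d) + noise_sd * rng.standard_normal()}
            for d in log10_dilutions for _ in range(n_replicates)]
    return pd.DataFrame(rows)


def coupling_slope_for_r2(r2: float, pss_sd: float, efficiency: float,
                          ref_efficiencies, noise_sd: float,
                          n_replicates: int, n_regions: int) -> float:
    """Cq-per-PSS slope giving a target population R² for the correlation
    between per-individual region-averaged log2 expression and PSS.

    The per-individual technical noise of a region-averaged, reference-
    normalized log2 ratio is ``(noise_sd²/(T·R)) · (e_t² + mean_j(e_j²)/J)``
    with ``e = log2 E``; the coupling signal has variance
    ``slope² · e_t² · pss_sd²``.  Solving signal/(signal+noise) = r2 gives
    the slope.  Biological (fish) effects cancel through the references
    and are ignored here.
    """
    if not 0.0 < r2 < 1.0:
        raise ValueError("r2 must lie strictly between 0 and 1")
    e_t = np.log2(efficiency)
    e_refs = np.log2(np.asarray(list(ref_efficiencies), dtype=float))
    var_noise = (noise_sd**2 / (n_replicates * n_regions)) \
        * (e_t**2 + (e_refs**2).mean() / len(e_refs))
    return float(np.sqrt(r2 / (1.0 - r2) * var_noise) / (e_t * pss_sd))


# ---------------------------------------------------------------------------
# ready-made designs

_TROUT_REGIONS = ["BTB", "BTL", "BTR", "MTD", "MTL"]


def trout_design(noise_sd: float = 0.2, n_individuals: int = 10,
                 seed: int = 0) -> QpcrDesign:
    """Two-species five-region layout: 10 biological replicates per region,
    triplicate reactions, two stable reference genes and three targets with
    region-dependent expression."""
    genes = ["rps20", "pgk1", "dct", "gja5", "clcn2"]
    offsets = {
        "rps20": dict.fromkeys(_TROUT_REGIONS, 0.0),
        "pgk1": dict.fromkeys(_TROUT_REGIONS, 0.0),
        # dct higher in brown trout skin (lower Cq there)
        "dct": {"BTB": 0.0, "BTL": 0.3, "BTR": 0.2, "MTD": 2.0, "MTL": 2.3},
        # gja5 higher in brown trout spots
        "gja5": {"BTB": 0.0, "BTR": 0.2, "BTL": 1.8, "MTD": 1.6, "MTL": 1.9},
        # clcn2 higher in marble trout skin
        "clcn2": {"BTB": 0.0, "BTL": 0.1, "BTR": 0.1, "MTD": -1.5, "MTL": -1.4},
    }
    eff = {"rps20": 1.998, "pgk1": 1.981, "dct": 2.103, "gja5": 1.912,
           "clcn2": 1.929}
    return QpcrDesign(genes=genes, regions=list(_TROUT_REGIONS),
                      offsets=offsets, efficiencies=eff,
                      reference_genes=["rps20", "pgk1"],
                      n_individuals=n_individuals, noise_sd=noise_sd, seed=seed)


def screen_design(seed: int = 0, noise_sd: float = 0.2) -> QpcrDesign:
    """Reference-gene screening panel: 10 candidates, exactly two of which
    (rps20, pgk1) are stable across regions."""
    candidates = ["rps20", "hprt1", "polr2a", "ppia1", "pgk1",
                  "sdha", "b2m", "ef1a", "actb", "rn18s"]
    rng = np.random.default_rng(123)  # fixed unstable-offset pattern
    offsets = {}
    for g in candidates:
        if g in ("rps20", "pgk1"):
            offsets[g] = dict.fromkeys(_TROUT_REGIONS, 0.0)
        else:
            amp = rng.uniform(0.8, 1.8)
            vals = amp * rng.choice([-1.0, 1.0], size=len(_TROUT_REGIONS)) \
                * rng.uniform(0.6, 1.0, size=len(_TROUT_REGIONS))
            offsets[g] = dict(zip(_TROUT_REGIONS, vals - vals[0]))
    eff = dict.fromkeys(candidates, 2.0)
    return QpcrDesign(genes=candidates, regions=list(_TROUT_REGIONS),
                      offsets=offsets, efficiencies=eff,
                      reference_genes=["rps20", "pgk1"],
                      n_individuals=3, noise_sd=noise_sd, seed=seed)


def hybrid_design(target_genes, coupled_gene: str | None, slope: float = 0.0,
                  regions=("dark", "light", "red"), noise_sd: float = 0.2,
                  seed: int = 0) -> QpcrDesign:
    """Hybrid-skin layout: targets plus the two reference genes, measured in
    every region of every individual; one gene optionally coupled to PSS."""
    genes = ["rps20", "pgk1", *target_genes]
    regions = list(regions)
    offsets = {g: dict.fromkeys(regions, 0.0) for g in genes}
    eff = dict.fromkeys(genes, 2.0)
    eff["rps20"], eff["pgk1"] = 1.998, 1.981
    coupling = {}
    if coupled_gene is not None:
        if coupled_gene not in target_genes:
            raise ValueError(f"coupled gene {coupled_gene!r} not among targets")
        coupling[coupled_gene] = slope
    return QpcrDesign(genes=genes, regions=regions, offsets=offsets,
                      efficiencies=eff, reference_genes=["rps20", "pgk1"],
                      noise_sd=noise_sd, coupling_slope=coupling, seed=seed)
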