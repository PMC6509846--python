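"""End-to-end pipeline: simulate or load data, score, express, correlate.

Every run writes a self-contained output directory: scores, expression and
correlation CSVs, the phenotype-plane figure, a plain-text log, an echo of
the fully-resolved configuration, and a manifest listing each output file
with its SHA-256 hash.  Outputs are a pure function of (inputs, config,
seed): the log carries no timestamps, so identical runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import metrics, phenotype, qpcr
from .config import PipelineConfig
from .synth import (coupling_slope_for_r2, generate_hybrid_series,
                    hybrid_design, preset, binarize_field, render_shapes,
                    ShapeSpec, simulate_gray_scott, simulate_qpcr,
                    simulate_standard_curve, trout_design)

__all__ = ["run_pipeline", "make_fixtures", "simulate_experiment",
           "save_image", "write_manifest", "score_directory"]

CANDIDATE_GENES = ["dct", "cdkn1a", "gja5", "tjp1", "wnt10a",
                   "gjd2", "slc7a2", "kcnc2", "clcn2", "pcdhac2"]


def save_image(image: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask (0/255 grayscale) or RGB array as 8-bit PNG."""
    arr = np.asarray(image)
    if arr.dtype == bool:
        arr = (arr.astype(np.uint8)) * 255
    Image.fromarray(arr).save(path)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(out_dir: str | Path, name: str = "manifest.json") -> Path:
    """Hash every file under `out_dir` (except the manifest) into a manifest."""
    out_dir = Path(out_dir)
    files = sorted(p for p in out_dir.rglob("*")
                   if p.is_file() and p.name != name)
    manifest = {str(p.relative_to(out_dir)): _sha256(p) for p in files}
    path = out_dir / name
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return path


def score_directory(images_dir: str | Path,
                    config: PipelineConfig | None = None,
                    per_contour: bool = False):
    """Score every PNG/TIFF image in a directory.

    Returns ``(scores, per_contour_table)``; the second is None unless
    requested.
    """
    images_dir = Path(images_dir)
    if not images_dir.is_dir():
        raise FileNotFoundError(f"image directory not found: {images_dir}")
    paths = sorted(p for p in images_dir.iterdir()
                   if p.suffix.lower() in (".png", ".tif", ".tiff"))
    if not paths:
        raise FileNotFoundError(f"no PNG/TIFF images in {images_dir}")
    rows, contour_rows = [], []
    for p in paths:
        s = metrics.score_image(p, config)
        rows.append({"image_id": p.stem, "n_contours": s.n_contours,
                     "pss": s.pss, "tone": s.tone,
                     "red_fraction": s.red_fraction})
        if per_contour:
            t = s.per_contour.copy()
            t.insert(0, "contour_id", np.arange(len(t)))
            t.insert(0, "image_id", p.stem)
            contour_rows.append(t)
    scores = pd.DataFrame(rows)
    per = pd.concat(contour_rows, ignore_index=True) if contour_rows else None
    return scores, per


def simulate_experiment(cfg: PipelineConfig, out: Path | None = None,
                        log: list | None = None) -> dict:
    """Generate and score a full synthetic experiment in memory.

    One master seed (``cfg.seed``) is split deterministically into a
    pattern seed and a qPCR seed.  A hybrid pattern series is generated
    and scored; one gene (``cfg.coupled_gene``) is coupled to the realized
    PSS with a slope chosen for population R² ``cfg.coupled_r2``, the rest
    are null.  Returns scores, the Cq table, the expression truth table
    and the efficiency table; images are written only when `out` is given.
    """
    log = log if log is not None else []
    rng = np.random.default_rng(cfg.seed)
    seed_patterns, seed_qpcr = (int(s) for s in
                                rng.integers(0, 2**31 - 1, size=2))

    series = generate_hybrid_series(n=cfg.n_hybrids, seed=seed_patterns,
                                    red_spots=True)
    if out is not None:
        (out / "images").mkdir(exist_ok=True)
    rows = []
    for h in series.individuals:
        if out is not None:
            save_image(h.image, out / "images" / f"{h.individual}.png")
        s = metrics.score_image(h.image, cfg)
        rows.append({"individual": h.individual, "mix": h.mix,
                     "n_contours": s.n_contours, "pss": s.pss,
                     "tone": s.tone, "red_fraction": s.red_fraction})
    scores = pd.DataFrame(rows)
    log.append(f"simulate: {cfg.n_hybrids} hybrids, seed {seed_patterns}")

    genes = CANDIDATE_GENES[:cfg.n_genes]
    coupled = cfg.coupled_gene if cfg.coupled_gene in genes else None
    slope = 0.0
    if coupled:
        design_probe = hybrid_design(genes, None)
        slope = coupling_slope_for_r2(
            cfg.coupled_r2, float(scores["pss"].std(ddof=1)),
            design_probe.efficiencies[coupled],
            [design_probe.efficiencies[r] for r in ("rps20", "pgk1")],
            design_probe.noise_sd, design_probe.n_replicates,
            n_regions=3)
    design = hybrid_design(genes, coupled, slope=slope)
    phen = scores.rename(columns={"pss": "pss"})[["individual", "pss"]]
    cq, truth = simulate_qpcr(design, seed=seed_qpcr, phenotypes=phen,
                              calibrator="dark")
    log.append(f"simulate: qPCR {len(genes)} targets, coupled={coupled}, "
               f"slope={slope:.4f} dCq/PSS, seed {seed_qpcr}")
    eff = pd.DataFrame({"gene": list(design.efficiencies),
                        "percent_efficiency":
                            [qpcr.factor_to_percent(e)
                             for e in design.efficiencies.values()]})
    return {"scores": scores, "cq": cq, "truth": truth, "efficiencies": eff,
            "calibrator": "dark"}


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 simulate: bool = False, images_dir=None, cq_path=None,
                 efficiencies_path=None) -> Path:
    """Run score -> express -> correlate and write all artifacts.

    With ``simulate=True`` a full synthetic dataset (hybrid pattern series
    plus coupled qPCR) is generated from ``config.seed``; otherwise
    `images_dir`, `cq_path` and `efficiencies_path` must name existing
    inputs (a missing one raises FileNotFoundError naming the artifact).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"pipeline: seed={config.seed} simulate={simulate}"]

    if simulate:
        art = simulate_experiment(config, out, log)
        scores, cq, eff = art["scores"], art["cq"], art["efficiencies"]
        calibrator = art["calibrator"]
        art["truth"].to_csv(out / "truth_expression.csv", index=False)
    else:
        for label, p in (("images directory", images_dir),
                         ("cq table", cq_path),
                         ("efficiency table", efficiencies_path)):
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"missing input: {label} ({p})")
        scores, _ = score_directory(images_dir, config)
        scores = scores.rename(columns={"image_id": "individual"})
        cq = pd.read_csv(cq_path)
        eff = pd.read_csv(efficiencies_path)
        calibrator = config.calibrator_region
    log.append(f"score: {len(scores)} images, "
               f"{int(scores['n_contours'].sum())} contours")

    refs = [g for g in config.reference_genes if g in set(cq["gene"])]
    tables = qpcr.expression_table(cq, eff, references=refs,
                                   calibrator=calibrator)
    log.append(f"express: {tables.summary['gene'].nunique()} genes, "
               f"calibrator {calibrator}")

    corr = phenotype.correlate_genes(tables.individual, scores,
                                     metric=config.correlation_metric)
    red_rows = []
    if "red" in set(tables.individual["region"]):
        for gene in tables.individual["gene"].unique():
            try:
                res = phenotype.region_scoped_correlation(
                    tables.individual, "red", scores, gene, metric="tone")
                red_rows.append(vars(res))
            except ValueError as exc:
                log.append(f"correlate: skipped {gene} in red region ({exc})")
    correlations = pd.concat([corr, pd.DataFrame(red_rows)],
                             ignore_index=True)
    log.append(f"correlate: {len(correlations)} gene x scope rows")

    plane = phenotype.phenotype_plane(scores,
                                      out_figure=out / "phenotype_plane.png")
    scores.to_csv(out / "scores.csv", index=False)
    cq.to_csv(out / "cq.csv", index=False)
    tables.summary.to_csv(out / "expression.csv", index=False)
    tables.individual.to_csv(out / "expression_individual.csv", index=False)
    correlations.to_csv(out / "correlations.csv", index=False)
    plane.to_csv(out / "phenotype_plane.csv", index=False)
    config.to_yaml(out / "config.yaml")
    (out / "log.txt").write_text("\n".join(log) + "\n")
    write_manifest(out)
    return out


def make_fixtures(out_dir: str | Path, seed: int = 0) -> Path:
    """Write the canonical deterministic fixture tree.

    shapes/   rendered analytic scenes plus their closed-form truth table
    presets/  thresholded spots and labyrinth reaction-diffusion fields
    qpcr/     simulated Cq and truth tables, the primer-panel efficiency
              table, and a noiseless standard-curve series
    hybrids/  a short hybrid series with its mix/score table
    """
    out = Path(out_dir)
    for sub in ("shapes", "presets", "qpcr", "hybrids"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    # --- shapes with closed-form truth
    scenes = {
        "disc": [ShapeSpec("disc", (50, 50), radius=10)],
        "square": [ShapeSpec("rectangle", (50, 50), width=10, height=10)],
        "disc_square": [  # equal areas -> PSS = (1 + pi/4) / 2
            ShapeSpec("disc", (30, 50), radius=10),
            ShapeSpec("rectangle", (70, 50), width=np.sqrt(100 * np.pi),
                      height=np.sqrt(100 * np.pi))],
        "red_scene": [ShapeSpec("disc", (30, 30), radius=12),
                      ShapeSpec("disc", (70, 70), radius=8, colour="red")],
    }
    rows = []
    for name, shapes in scenes.items():
        res = render_shapes(shapes, canvas=(100, 100), resolution=8)
        save_image(res.image, out / "shapes" / f"{name}.png")
        rows.append({"image_id": name, "pss_truth": res.truth.pss,
                     "tone_truth": res.truth.tone,
                     "red_truth": res.truth.red_fraction})
    pd.DataFrame(rows).to_csv(out / "shapes" / "truth.csv", index=False)

    # --- reaction-diffusion presets (thresholded)
    for name in ("spots", "labyrinth"):
        field = simulate_gray_scott(preset(name, seed=seed))
        save_image(binarize_field(field), out / "presets" / f"{name}.png")

    # --- qPCR
    design = trout_design(seed=seed)
    cq, truth = simulate_qpcr(design, seed=seed)
    cq.to_csv(out / "qpcr" / "cq.csv", index=False)
    truth.to_csv(out / "qpcr" / "truth.csv", index=False)
    pd.DataFrame({"gene": list(qpcr.TROUT_PANEL_EFFICIENCY_PCT),
                  "percent_efficiency":
                      list(qpcr.TROUT_PANEL_EFFICIENCY_PCT.values())}) \
        .to_csv(out / "qpcr" / "efficiencies.csv", index=False)
    simulate_standard_curve(1.95, gene="dct", seed=seed) \
        .to_csv(out / "qpcr" / "standard_curve.csv", index=False)

    # --- hybrid series (scored, since its PSS has no closed form)
    series = generate_hybrid_series(n=5, seed=seed)
    rows = []
    for h in series.individuals:
        save_image(h.image, out / "hybrids" / f"{h.individual}.png")
        s = metrics.score_image(h.image)
        rows.append({"individual": h.individual, "mix": h.mix,
                     "pss": s.pss, "tone": s.tone,
                     "red_fraction": s.red_fraction})
    pd.DataFrame(rows).to_csv(out / "hybrids" / "scores.csv", index=False)

    write_manifest(out)
    return out
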