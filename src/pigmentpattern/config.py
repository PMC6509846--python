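"""Pipeline configuration: one flat record with a default for every field."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Every tunable of the scoring / expression / correlation pipeline.

    Image scoring
    -------------
    binarization : "otsu" or "fixed"; pigment (dark) is foreground.
    fixed_threshold : luminance threshold (0-255) when binarization="fixed".
    min_area : smallest contour pixel count retained (speckle filter).
    connectivity : 4 or 8; foreground pixel connectivity.
    smoothing_window : contour-polygon moving-average window (vertices).
    red_* : hue window (degrees around 0°), minimum saturation and value
        of the "reddish" pixel classifier.

    Expression
    ----------
    reference_genes : stable genes used for Pfaffl normalization.
    calibrator_region : region all ratios are expressed against.

    Correlation / simulation
    ------------------------
    correlation_metric : "pss" or "tone"; phenotype axis for correlations.
    n_hybrids, n_genes, coupled_gene, coupled_r2 : synthetic-run layout.
    """

    seed: int = 0
    # image scoring
    binarization: str = "otsu"
    fixed_threshold: float = 128.0
    min_area: int = 5
    connectivity: int = 8
    smoothing_window: int = 5
    red_hue_halfwidth_deg: float = 20.0
    red_min_saturation: float = 0.3
    red_min_value: float = 0.2
    # expression
    reference_genes: tuple = ("rps20", "pgk1")
    calibrator_region: str = "BTB"
    # correlation
    correlation_metric: str = "pss"
    # synthetic pipeline layout
    n_hybrids: int = 13
    n_genes: int = 10
    coupled_gene: str = "gja5"
    coupled_r2: float = 0.8

    def __post_init__(self):
        if self.binarization not in ("otsu", "fixed"):
            raise ValueError(f"binarization must be otsu|fixed, got {self.binarization!r}")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.correlation_metric not in ("pss", "tone"):
            raise ValueError("correlation_metric must be pss|tone")
        self.reference_genes = tuple(self.reference_genes)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["reference_genes"] = list(self.reference_genes)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))
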