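"""Synthetic hybrid series: patterns morphing from spots to labyrinth.

Each individual carries a mixing coordinate ``mix`` in [0, 1].  At mix 0
the pattern is a jittered lattice of disjoint discs (brown-trout-like
spots); as mix grows the discs elongate and bridges between lattice
neighbours switch on in a fixed, nested order, so an individual's pattern
at a higher mix contains every merge present at a lower mix.  At mix 1 the
lattice is fully connected — a labyrinth.  The nesting makes the pattern
simplicity score monotone in mix by construction, emulating a hybrid
series spanning the two parental phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["HybridIndividual", "HybridSeries", "generate_hybrid_series"]

_DARK_RGB = (30, 30, 30)
_RED_RGB = (205, 40, 40)


@dataclass
class HybridIndividual:
    individual: str
    mix: float
    image: np.ndarray  # bool mask, or uint8 RGB when red spots are present


@dataclass
class HybridSeries:
    individuals: list
    metadata: pd.DataFrame = field(repr=False)


def _capsule_mask(X, Y, p0, p1, radius):
    """Pixels within `radius` of the segment p0-p1 (round-capped bar)."""
    d = np.subtract(p1, p0)
    seg2 = float(d @ d)
    if seg2 == 0:
        return (X - p0[0]) ** 2 + (Y - p0[1]) ** 2 <= radius**2
    t = np.clip(((X - p0[0]) * d[0] + (Y - p0[1]) * d[1]) / seg2, 0.0, 1.0)
    return (X - (p0[0] + t * d[0])) ** 2 + (Y - (p0[1] + t * d[1])) ** 2 <= radius**2


def generate_hybrid_series(n: int = 13, mix=None, seed: int = 0,
                           canvas_px: int = 256, grid: int = 5,
                           red_spots: bool = False) -> HybridSeries:
    """Generate `n` pattern images ordered from spotted to labyrinthine.

    Parameters
    ----------
    n :
        Number of individuals, >= 2.
    mix :
        Per-individual mixing coordinates in [0, 1]; defaults to an even
        spacing from 0 (pure spots) to 1 (labyrinth).
    seed :
        Controls lattice jitter, disc orientations and the bridge
        activation order; the layout is shared across the series so mixes
        differ only in how merged the same pattern is.
    canvas_px, grid :
        Image side in pixels and lattice size (grid × grid discs).
    red_spots :
        Add a fixed set of red discs between the dark pattern elements and
        return RGB images (for red-fraction and red-region analyses).
    """
    if n < 2:
        raise ValueError("need n >= 2 individuals")
    if mix is None:
        mix = np.linspace(0.0, 1.0, n)
    mix = np.asarray(mix, dtype=float)
    if len(mix) != n or (mix < 0).any() or (mix > 1).any():
        raise ValueError("mix must hold n values in [0, 1]")

    rng = np.random.default_rng(seed)
    spacing = canvas_px / grid
    r0 = 0.27 * spacing
    jitter = rng.uniform(-0.08 * spacing, 0.08 * spacing, size=(grid, grid, 2))
    centers = np.empty((grid, grid, 2))
    for i in range(grid):
        for j in range(grid):
            centers[i, j] = ((j + 0.5) * spacing + jitter[i, j, 0],
                             (i + 0.5) * spacing + jitter[i, j, 1])
    theta = rng.uniform(0, np.pi, size=(grid, grid))

    # nested bridge order: edge e is active iff its rank/n_edges < mix
    edges = [((i, j), (i, j + 1)) for i in range(grid) for j in range(grid - 1)]
    edges += [((i, j), (i + 1, j)) for i in range(grid - 1) for j in range(grid)]
    order = rng.permutation(len(edges))
    thresholds = {tuple(e): (np.argsort(order)[idx] + 0.5) / len(edges)
                  for idx, e in enumerate(edges)}

    ax = np.arange(canvas_px) + 0.5
    X, Y = np.meshgrid(ax, ax)

    red_mask = np.zeros((canvas_px, canvas_px), dtype=bool)
    if red_spots:
        rr = 0.16 * spacing
        corners = [(1, 1), (1, grid - 1), (grid - 1, 1), (grid - 1, grid - 1)]
        for (i, j) in corners:
            cx, cy = j * spacing, i * spacing
            red_mask |= (X - cx) ** 2 + (Y - cy) ** 2 <= rr**2

    individuals = []
    for idx, m in enumerate(mix):
        fg = np.zeros((canvas_px, canvas_px), dtype=bool)
        half = 0.9 * m * r0  # elongation: disc -> capsule along its own axis
        for i in range(grid):
            for j in range(grid):
                c = centers[i, j]
                d = np.array([np.cos(theta[i, j]), np.sin(theta[i, j])]) * half
                fg |= _capsule_mask(X, Y, c - d, c + d, r0)
        bar = 0.55 * r0
        for e in edges:
            if thresholds[tuple(e)] < m:
                (i0, j0), (i1, j1) = e
                fg |= _capsule_mask(X, Y, centers[i0, j0], centers[i1, j1], bar)

        if red_spots:
            rgb = np.full((canvas_px, canvas_px, 3), 255, dtype=np.uint8)
            rgb[fg] = _DARK_RGB
            rgb[red_mask & ~fg] = _RED_RGB
            image = rgb
        else:
            image = fg
        individuals.append(HybridIndividual(f"H{idx + 1:02d}", float(m), image))

    meta = pd.DataFrame({"individual": [h.individual for h in individuals],
                         "mix": [h.mix for h in individuals]})
    return HybridSeries(individuals=individuals, metadata=meta)
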