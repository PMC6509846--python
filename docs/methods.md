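# Methods

This note documents the models, estimators, defaults and known
limitations of `pigmentpattern`, stage by stage.

## Pattern metrics

### Model

A pigment pattern is reduced to three numbers. The **pattern simplicity
score** is the area-weighted mean isoperimetric quotient of the contours
of the pigmented regions, PSS = Σ wᵢQᵢ with Qᵢ = 4πSᵢ/Lᵢ² and
wᵢ = Sᵢ/ΣSᵢ. Discrete round spots give PSS near 1; elongation, branching
and fusion push it toward 0, so lower values mean more complex patterns.
**Colour tone** is the non-pigmented (background) pixel fraction of the
binarized image, and the **red fraction** is the fraction of pixels inside
a hue/saturation/value window around red.

### Binarization and polarity

Pigment is dark: foreground = pixels below the threshold (Otsu by default,
or a fixed 0–255 value). A constant image has no Otsu threshold and is
treated as all background with a warning. Bilevel files holding exactly
{0, 255} are interpreted as masks written by this package (255 =
foreground), matching the on-disk convention for binary pattern images.

### Contour measurement

Connected components (8-connectivity for foreground; background is
implicitly 4-connected, the standard complementary pairing) are extracted
with `skimage.measure.label`; components below `min_area` (default 5 px²,
a speckle filter) are dropped, and border-touching components are
retained with their clipped boundary counted — labyrinthine patterns
cross the frame by nature.

Per component, boundaries are traced as subpixel marching-squares
polygons (`skimage.measure.find_contours` at level 0.5) and smoothed with
a short cyclic moving average (`smoothing_window`, default 5 vertices)
before measuring. The smoothing is the load-bearing numerical choice: raw
pixel-lattice boundaries overestimate the perimeter of smooth shapes by
about 5%, which biases every Q down by ~10% and would make even a perfect
digital circle score ≈0.90. With the smoothed-polygon estimator a disc
rasterized at 256² measures Q ≈ 0.993, a square ≈ 0.788 (theory π/4 ≈
0.785), and a 45°-rotated rectangle agrees with its axis-aligned twin to
< 0.01. Areas use the shoelace formula on the same polygons so S and L
are mutually consistent; hole areas are subtracted from S and hole
boundary lengths added to L, which makes multiply-connected (annular,
labyrinthine) regions read as complex. Residual Q marginally above 1 from
rasterization is clamped to 1 and counted (`n_clamped`).

Degenerate inputs: an image with no retained contour reports PSS as NaN
with an explicit warning, never 0 — 0 would mean "maximally complex".

### Red classifier

A pixel is reddish when its hue is within ±20° of 0° (wrapping),
saturation ≥ 0.3 and value ≥ 0.2. There is no canonical definition of
"reddish"; the window is configurable and recorded in the config echo.
Grayscale input yields red fraction 0 with a warning.

## Synthetic pattern generators

### Parametric shapes

Discs, rectangles and ellipses have closed-form S and L (the ellipse
perimeter via the complete elliptic integral), so scenes of disjoint
shapes carry an exact PSS/tone/red-fraction truth computed without any
rasterization — the oracle against which the raster pipeline is tested.
Rasterization samples pixel centers at a configurable resolution
(≥ 8 px/unit). The dumbbell (two discs joined by a bar) exists to test
that merging lowers PSS; its truth is measured numerically at 64 px/unit
rather than in closed form.

### Reaction–diffusion presets

The Gray–Scott system (substrate u, activator v; feed F, kill k,
diffusion Du > Dv, periodic boundaries, forward-Euler with dt = 1) is used
purely as a pattern generator: parameter regimes produce either discrete
spots or connected labyrinths, emulating the two parental phenotypes.
The shipped presets were calibrated once so the two regimes separate
cleanly on PSS and then frozen:

| preset    | F     | k     | Du   | Dv   | grid | steps  | PSS (threshold @ midpoint) |
|-----------|-------|-------|------|------|------|--------|-----------------------------|
| spots     | 0.035 | 0.065 | 0.16 | 0.08 | 128² | 10 000 | ≈ 0.97 |
| labyrinth | 0.055 | 0.062 | 0.16 | 0.08 | 128² | 10 000 | ≈ 0.02 |

Initialisation is the standard symmetry-breaking recipe — uniform state,
a perturbed centre square, plus seeded Gaussian noise (amplitude 0.02) —
making runs bit-reproducible per seed. Fields are binarized at the
midpoint of min/max, a parameter-free rule that is stable at steady
state. Any non-finite value aborts with the step index and a parameter
echo.

### Hybrid series

Hybrids are generated geometrically rather than by interpolating the
reaction–diffusion presets: a jittered 5×5 disc lattice in which each
disc elongates with the mixing coordinate `mix` and bridges between
lattice neighbours activate in a fixed random order. Bridge activation is
*nested* — the pattern at a higher mix contains every merge present at a
lower one — so PSS is monotone in mix by construction, and the series is
cheap enough to regenerate hundreds of times in simulation studies. At
mix 0 the pattern is 25 disjoint spots (PSS > 0.95); at mix 1 the lattice
is fully connected (PSS < 0.1). Optional red discs are placed between
lattice cells, shared across the series.

What this emulates — and does not: the generator reproduces the
*topological* range from spotted to labyrinthine and a known ordering of
complexity; it does not attempt realistic trout skin texture, scales,
lighting, fish outlines or photographic preprocessing. Passing tests
therefore validate the measurement pipeline and statistics, not
segmentation of field photographs (inputs are assumed pre-cropped pattern
regions).

## qPCR simulation

One well follows Cq = baseline_g + offset_{g,r} + slope_g·PSSᵢ + fishᵢ + ε,
with fishᵢ ~ N(0, 0.3²) shared across all genes and replicates of an
individual (the biological-replicate structure of a 10-fish-per-region,
triplicate design) and ε ~ N(0, 0.2²) per well. Reference genes have zero
offsets everywhere. The true efficiency-corrected log2 ratio of (g, r)
versus a calibrator region is (offset_{g,cal} − offset_{g,r})·log2 E_g.
Defaults mirror the emulated experiment: regions BTB/BTL/BTR (brown trout
black spot / light / red spot) and MTD/MTL (marble trout dark / light),
10 individuals per region, triplicates, noise SD 0.2 cycles. A master
seed is split deterministically into per-stage seeds.

For hybrid layouts, a coupling slope (ΔCq per unit PSS) ties one gene's
expression to the realized phenotype. The slope for a target population
R² is solved analytically from the technical-noise variance of a
region-averaged, reference-normalized log2 ratio,
(σ²/(T·R))·(e_t² + mean_j e_j²/J) with e = log2 E; fish effects cancel
through the references and are ignored in that budget.

## Expression analysis

Technical replicates are collapsed by arithmetic mean of Cq first.
Efficiencies come either from dilution-series standard curves
(least-squares slope, E = 10^(−1/slope); non-negative slopes are rejected
as failed curves) or directly as percent values (E = 1 + pct/100);
supplied values take precedence. Candidate reference genes are ranked by
the SD of their replicate-averaged Cq across all samples — stable genes
sit at the same level in every sample — and the top two are flagged.

Multi-reference normalization applies the geometric mean to the
per-reference efficiency-corrected factors E_jᴰᶜq — equivalently the
arithmetic mean of ΔCq_j·log E_j. Each individual's ratio is computed
against the calibrator *group mean* Cq (so the calibrator group's mean
log2 ratio is 0 by construction and a two-sample test against it is
possible); the alternative, paired-sample convention is not used because
the group layout has distinct individuals per region. Group comparisons
use the classical unpaired pooled-variance Student's t-test, two-sided,
with no multiple-testing correction across genes; the gene count is in
the output so users can apply their own. Groups with < 2 individuals, or
zero variance (noiseless data), report their ratio with an undefined
(NaN) p-value rather than failing. NTC and melt-curve QC are outside
numerical scope; QC flag columns pass through untouched.

## Phenotype–expression correlation

Per-individual expression is the arithmetic mean of available region
log2 ratios; missing regions (a hybrid without red spots) are skipped and
counted, never zero-filled. Both Pearson r and Spearman ρ are reported
with two-sided p-values; Spearman is primary — the PSS scale is bounded
and the association need not be linear. Correlations can be scoped to a
single region (e.g. red-spot expression vs colour tone); fewer than 3
individuals with data is a refusal, and zero variance flags the
coefficients undefined. The complexity axis is PSS itself (low =
complex); no inversion is applied.

## Pipeline determinism

`run --simulate` derives all randomness from one seed, writes no
timestamps, and hashes every output into `manifest.json`; identical
config + seed gives byte-identical trees. Exit codes: 0 success,
2 validation failure, 3 missing input.

## Simulation sizes

The validation studies use 10 seeds per reaction–diffusion preset, 100
simulated experiments for expression-recovery, reference-screen and
end-to-end detection rates, and 1000 for t-test size — sizes at which the
binomial uncertainty of the measured rates is comfortably inside the
asserted bands.

## Known limitations

* The perimeter estimator is tuned for patterns whose features span at
  least ~10 px; structures a few pixels wide are dominated by
  rasterization error (mitigated, not removed, by smoothing).
* The hole/border conventions (holes subtract area and add perimeter;
  border components retained) are one defensible choice among several;
  both are configurable points in the code and flagged in the per-contour
  table, and comparisons between datasets should hold them fixed.
* The qPCR noise model is Gaussian in Cq with a single shared fish
  effect; real assays show heavier tails, plate effects and
  efficiency drift that the simulator does not emulate.
* The end-to-end detection-rate study reports per-gene rates across
  runs; with nine null genes tested at α = 0.05 per run, some run-level
  false positive is expected in roughly a third of runs — an inherent
  property of uncorrected multiple testing, not an implementation defect.
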