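# Methods

This note documents the models, conventions and numerical choices behind
`hscquant`, and what the synthetic-data validation does and does not show.

## Imaging model and geometry

A slice is represented as per-channel 2D intensity planes (`ChannelImage`)
with a physical pixel size. Pixel indices are 0-based; physical coordinates
refer to **pixel centers**, `x_um = (col + 0.5) · pixel_size_um`. Areas are
pixel counts times `pixel_size_um²` exactly, so every area-derived quantity
(tissue mm², patch µm², percentages) is a closed-form function of the masks.

**Tiling.** Acquisitions tile the slice with 512 × 512 px frames overlapping
by 10 % (defaults; both configurable). Splitting uses a stride of
`tile − round(tile · overlap)` with the last tile clamped to the image edge;
assembly averages overlapping contributions. Averaging is unweighted and
order-independent; where all contributions agree the assembled value is taken
directly rather than as sum/count, which makes the split → assemble round
trip bit-exact even where three or more clamped tiles overlap (3a/3 is not
exact in IEEE arithmetic).

**Z-stacks** (3 µm steps) are collapsed by maximum-intensity projection:
the acquisition performs no averaging, and MIP preserves droplets that are
bright in a single optical section. The projection operator is configurable
in principle but MIP is the only one shipped.

**Tissue mask.** The slice outline is not delimited by the acquisition, so
the mask is computed: Otsu threshold on the Gaussian-smoothed (σ = 1 px
default) RF + CF sum, hole filling, and removal of components below
100 µm². An all-zero input yields an empty, flagged mask. Percentages are
referenced to this mask (primary) and to the whole frame (also reported),
because "total surface area" is ambiguous between the two; the choice
changes the numbers and is therefore surfaced rather than hidden.

## Patch individualization

RF signal is binarized (Otsu over tissue pixels by default; a fixed
threshold can be forced), restricted to tissue, hole-filled, cleaned of
components smaller than `min_area_um2` (default 10 µm², suppressing noise
speckle), and labeled under **8-connectivity** — diagonal contact merges
regions. Connectivity changes counts, so it is fixed and documented. A
"patch" is deliberately scale-ambiguous: one droplet, one droplet-laden
cell, or a cluster of cells; no per-cell instance separation is attempted.

Metrics: `rf_area_pct = 100 · ΣA_patch / A_tissue`; density =
count / tissue mm²; size histogram over µm² bins whose last bin is
open-ended (counts always sum to the patch count); proximity = distance
from each patch centroid to the nearest collagen pixel via a Euclidean
distance transform, with "near" meaning ≤ 20 µm by default (an invented,
configurable statistic — the colocalization itself is only qualitative in
histology). The heat map counts each centroid once in the 100 × 100 µm cell
containing it, floor convention (a centroid exactly on an interior boundary
belongs to the higher-index cell); partial edge cells are kept, so the grid
sum equals the patch count.

## Spectral separation

Reference spectra (retinoid, tissue background) are measured from ROIs as
per-bin means normalized to unit maximum; they are never hard-coded — on
real data they must come from a measured acquisition (e.g. primary HSC
droplets), on synthetic data from the generator. Unmixing is per-pixel
non-negative least squares against the two references. With two columns the
NNLS minimizer is available in closed form (interior normal-equations
solution when non-negative, otherwise the best non-negative single-column
projection), which is exact, deterministic and vectorizes over pixels;
`scipy.optimize.nnls` serves as the independent oracle in the tests.
References closer than 1e−6 in 1 − |cos θ| are rejected as collinear.
Coefficients inherit instrument-intensity units because references have
unit maximum. Two components only; n-component and blind unmixing are out
of scope.

## Scoring rules

The four scales are implemented exactly as printed decision tables:

- mouse hypertrophy: 0 none; 3 if > 10 cells/field; otherwise 1 vs 2 by a
  mean-cell-area surrogate (default 200 µm²) for the qualitative
  "small" / "bigger" wording — a documented stand-in, not the pathologists'
  rule. A count of exactly 10 is unassigned by the printed wording and falls
  to the size branch (never 3).
- human hypertrophy: 0 / 1 / 2–5 / > 5 hypertrophied areas per biopsy.
- steatosis: fat-area % rounded to the nearest integer (half away from
  zero), then 0 / 1–33 / 34–66 / 67–100.
- inflammation: 0 / < 2 / [2, 4] (closed, "between 2 and 4") / > 4 foci per
  lobule.

Fibrosis staging (0, 1a, 1b, 1c, 2, 3, 4 or METAVIR F0–F4) is expert
histopathology and passes through as a recorded label only.

## HPLC quantification

Calibration lines are ordinary least squares with a free intercept
(through-origin by flag; the original protocol does not state which, nor
the number of levels — both are configuration). Extraction yield =
recovered internal standard (2.5 µg retinyl acetate, inverted through its
curve) / spike; yields above 1 are tolerated with a warning and capped at
1.5. Sample amounts invert through the retinol and retinyl palmitate
curves (esters are quantified collectively against palmitate), are divided
by the yield, and normalized by tissue mass (default 45 mg, the middle of
the 40–50 mg protocol range) to µg/g. Negative inverted amounts clip to 0
with a warning. Peak detection from raw traces is out of scope: the input
contract starts at integrated areas.

## Statistics

Spearman r is the Pearson correlation of midranks; p is exact by full
permutation enumeration for n ≤ 9, else the t approximation on n − 2 df.
Mann–Whitney U is the smaller of the two U statistics (ties count ½); p is
exact by enumeration of all group assignments for pooled n ≤ 12 (valid
with ties), else the tie-corrected normal approximation **without**
continuity correction — chosen so that the two-group Kruskal–Wallis p
equals the Mann–Whitney p through the χ²₁ = z² identity. Kruskal–Wallis
uses the tie-corrected H with a χ² p on k − 1 df; an all-identical pooled
sample is degenerate and returns H = 0 with a flag. Which convention
(exact vs asymptotic) produced each p is recorded in the result. Group
summaries are median and Q1/Q3 by linear interpolation (stated in the
output, since IQR depends on the convention). Stars follow
\*p < 0.05, \*\*p < 0.01, \*\*\*p < 0.005, \*\*\*\*p < 0.0005; no
multiple-testing correction is applied.

## Synthetic-data generator

The generator is the test bed, not a model of any particular slide.

- **Fields**: axis-aligned random ellipses (analytically known pixel areas)
  placed by rejection sampling with a guaranteed ≥ 2 px gap, so patches are
  pairwise disjoint under 8-connectivity by construction; a bounded number
  of attempts, then an explicit placement error. A stated fraction of
  patches is placed within `focus_radius_um` (default 150 µm) of random
  centrilobular foci. Collagen fibers are direction-persistent random-walk
  polylines of stated thickness, a stated fraction seeded on a 2 px
  dilation of patch borders. The tissue region is the field minus an
  optional border margin, so all truth fractions are exact pixel ratios.
  Noise is additive Gaussian clipped at 0 — the simplest model that
  exercises thresholding. Default conditions: 1 × 1 mm field, 0.5 µm/px,
  20 patches of 5–25 µm radius, 80 % clustered, 30 fibers (70 % near
  patches), background 10, RF 200, CF 150, noise σ 2 on an 8-bit-like
  scale.
- **Spectral stacks**: exact linear mixtures of two reference spectra on a
  shared axis (e.g. 490–790 nm in 5 nm windows) plus clipped noise; truth
  stores the coefficient maps.
- **Peak tables**: areas are `curve(amount · yield) · (1 + ε)`, the IS peak
  from `2.5 µg · yield`; the inverse pipeline recovers amounts exactly when
  ε = 0 and the estimated yield equals the simulated one.
- **Score cohorts**: a Gaussian copula with Pearson ρ = 2 sin(π ρₛ/6) gives
  the latent pair the requested Spearman correlation in expectation; the
  latents are cut into fibrosis stage 0–4 using the 27-biopsy human
  cohort's stage proportions (4/5/9/5/4) and hypertrophy 0–3 by uniform
  quartiles. Discretization attenuates the sample Spearman slightly
  relative to the latent target (≈ 0.46 vs 0.50 at n = 200); both the
  discrete scores and the latents are returned so either can be checked.

What passing on synthetic data does **not** show: robustness to real
tissue texture, uneven illumination, autofluorescence structure,
anisotropic droplet shapes, or 3D partial-volume effects — the generator's
two-level noise model is far cleaner than real slides, and thresholds that
are exact here are approximate there. The generator also handles z only as
identical-plane stacks; there is no volumetric simulation.

## Problem sizes in the test suite

The suite validates segmentation against a brute-force flood-fill oracle on
100 random 64 × 64 µm fields plus one full 1 × 1 mm field, unmixing on a
64 × 64 × 60-bin stack, the HPLC round trip on 500 noisy replicates at 5 %
relative noise, and cohort correlation recovery over 200 seeds at n = 200 —
sizes chosen to exercise every code path at desk scale while keeping the
default run fast.

## Known limitations

- No registration-based stitching or flat-field correction; tile offsets
  are assumed exact.
- Otsu thresholds are per-slice global; intensity drift within a slice is
  not modelled.
- Patch proximity uses centroids, which can sit outside highly concave
  patches (not generated here, but possible in real data).
- Exact Mann–Whitney enumeration is combinatorial; pooled n > 12 falls back
  to the asymptotic p automatically.
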