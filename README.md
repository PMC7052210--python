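# hscquant

Quantification of **hypertrophied hepatic stellate cells (HSCs)** in fibrotic
liver from multiphoton microscopy, with the supporting chemistry and
statistics.

Quiescent HSCs store vitamin A (retinyl esters) in lipid droplets; on
activation they turn into collagen-producing myofibroblasts and normally shed
their retinoid stock. In diet-induced metabolic fibrosis, however, clusters of
retinoid-overloaded, hypertrophied HSCs appear next to collagen deposits.
Their two intrinsic signals can be imaged label-free: **RF** (retinoid
fluorescence of the droplets) and **CF/SHG** (second-harmonic generation of
fibrillar collagen). This package implements the complete measurement chain a
study of that phenotype needs:

- **`mosaic`** — tiled-acquisition assembly (512 × 512 px frames, 10 %
  overlap), maximum-intensity z-projection, and the tissue mask whose area is
  the denominator of every percentage.
- **`quantify`** — individualization of RF signal into connected "patches"
  (8-connectivity, Otsu or fixed threshold, hole filling, minimum-area
  cleaning), collagen mask segmentation, and the per-slice metrics:
  `rf_area_pct = 100 · ΣA_patch / A_tissue`, patch density (patches · mm⁻²),
  patch-size histogram, patch-to-collagen proximity, and the 100 × 100 µm
  heat map of patch counts.
- **`spectral`** — ROI emission-spectrum extraction and two-component
  unmixing: each pixel spectrum is fitted as
  `y(λ) = c_ret · s_ret(λ) + c_bg · s_bg(λ)`, `c ≥ 0`, by exact per-pixel
  non-negative least squares, separating retinoid signal from tissue
  autofluorescence.
- **`scoring`** — the four ordinal histology scales (mouse and human HSC
  hypertrophy, steatosis, lobular inflammation), each 0–3, as pure decision
  functions; fibrosis stage is recorded metadata, never computed.
- **`hplc`** — calibration-line fitting (area = a·µg + b), extraction-yield
  estimation from a 2.5 µg retinyl acetate internal standard, and
  yield-corrected retinol / retinyl-ester content in µg per g liver.
- **`stats_report`** — Spearman, Mann–Whitney and Kruskal–Wallis with
  tie-corrected statistics, exact small-sample p-values, median/IQR
  summaries and a markdown report writer.
- **`synthgen`** — synthetic slides, spectral stacks, peak tables and score
  cohorts with exact ground truth, used throughout the test suite.

## Worked example

```python
from hscquant import (LobuleFieldSpec, generate_lobule_field, segment_rf,
                      segment_cf, slice_metrics, density_heatmap)
from hscquant.synthgen import tissue_mask_from_spec

spec = LobuleFieldSpec(seed=7)            # 1 x 1 mm field, 0.5 µm/px, 20 patches
rf, cf, truth = generate_lobule_field(spec)
tissue = tissue_mask_from_spec(spec)

patches = segment_rf(rf, tissue)
m = slice_metrics(patches, segment_cf(cf, tissue), tissue)
print(f"patches: {patches.count}")
print(f"RF area: {m.rf_area_pct:.2f} % of tissue")
print(f"patch density: {m.rf_patch_density_per_mm2:.1f} per mm^2")
print(f"near collagen: {m.proximity['fraction_patches_near_collagen']:.2f}")
heat = density_heatmap(patches)           # 100 µm grid
print("heat-map sum:", heat.total)
```

prints

```
patches: 20
RF area: 1.22 % of tissue
patch density: 20.0 per mm^2
near collagen: 0.75
heat-map sum: 20
```

All 20 synthetic patches are recovered; the RF area fraction (1.22 %) matches
the generator's ground truth (1.2165 %) to within the pixel raster, the
density is count/area by definition, 75 % of patches lie within 20 µm of a
collagen fiber (the generator seeds 70 % of fibers on patch borders), and the
heat map conserves the patch count.

A CLI mirrors the common steps: `hscquant quantify --rf rf.tif --cf cf.tif
--pixel-size 0.5`, plus `stitch`, `project`, `mask`, `score` and
`hscquant hplc quantify`.

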