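# bactorg

Quantitative image analysis of subcellular organization in rod-shaped
bacteria, built for fluorescence microscopy of cyanobacteria in which
carboxysomes (Rubisco-filled microcompartments, visible as
diffraction-limited foci) are positioned along the nucleoid by a
ParA-family ATPase (McdA) and its partner (McdB).  The package measures,
per cell:

* **focus statistics** — Laplacian-of-Gaussian (LoG) spot detection with
  unsharp-mask preprocessing; focus intensity as the raw pixel sum in a
  circle of radius 2*r* around each detection; counts, nearest-neighbor
  spacing and distance from the cell's medial axis;
* **mobility** — a gated linear-assignment tracker (linking gate 7.5 px,
  gap closing 4.5 px over ≤ 2 frames) and the *confinement radius*: the
  mean distance of a track's first ten localizations from their centroid;
* **nucleoid compaction** — cytoplasmic background from a Gaussian fit to
  the cell-boundary rim histogram, 66 nm blur, Yen's threshold, and the
  compaction score `s_comp = 1 − A_nuc / A_cell`;
* **protein patterning** — the oscillation score (fraction of per-cell
  min-max-normalized pixels with `I_n < 0.5`; high for polarized or
  pole-to-pole oscillating proteins, lower for diffuse ones) and
  kymographs extracted along the cell midline with an 11 px band;
* **localization density maps** — each localization mapped into a
  normalized cell frame (`r_rel`: radial distance from the midline over
  cell width; `l_rel`: arc-length position over cell length; `φ`: angle in
  the polar caps), binned with per-cell bin areas, pooled across cells,
  fourfold-symmetrized, and reported as a probability density in µm⁻²
  that integrates to the number of cells;
* **colocalization** — per-cell and per-field Pearson correlation.

Everything is validated against a **synthetic scene generator**
(`bactorg.synthgen`) that renders rod-shaped cells (spherocylinders,
~1 µm × 2–4 µm at 60 nm/pixel), diffraction-limited foci on confined
random walks, nucleoids of controlled area fraction, polar-gradient /
diffuse / punctate protein patterns, stage drift and channel pairs with
prescribed correlation — with full ground truth recorded before noise.

## Worked example

```python
from bactorg import pipeline

res = pipeline.run_experiment(dict(
    scene=dict(n_cells=6, n_frames=10, mcda_mode="polar_gradient",
               nucleoid_area_fraction=0.5, confinement_radius_um=0.1, rho=0.8),
    condition="demo", seed=7))
print(res["metrics"][["cell_id", "length_um", "focus_count", "s_comp",
                      "oscillation_score", "pearson_r"]].round(3))
```

prints

```
 cell_id  length_um  focus_count  s_comp  oscillation_score  pearson_r
       1      3.696            3   0.493              0.877      0.759
       2      3.593            3   0.499              0.872      0.735
       3      3.108            3   0.498              0.875      0.731
       4      3.809            3   0.504              0.875      0.756
       5      2.982            3   0.172              0.878      0.762
       6      2.633            3   0.485              0.885      0.752
```

Each row is one segmented cell.  The scene injected a nucleoid area
fraction of 0.5, so `s_comp ≈ 0.5` (cell 5's rim fit failed on this noise
draw — exactly the kind of record the ROUT outlier step removes before
replicate summaries).  The polar-gradient protein pattern scores high
(~0.88) on the oscillation metric, and the injected channel correlation
ρ = 0.8 is recovered per cell to within sampling error.  The median
confinement radius over all tracks is 0.0625 µm and the density map
integrates to exactly 6 (the number of cells).

The same stages are available from a shell:

```sh
bactorg simulate --n-cells 6 --n-frames 10 --mode polar_gradient --seed 7 --out scene
bactorg segment scene/scene.tif --out seg
bactorg foci scene/scene.tif --labels seg/labels.tif --out detections.csv
bactorg track detections.csv --out tracking
bactorg nucleoid scene/scene.tif --labels seg/labels.tif --out nucleoid.csv
bactorg map scene/scene.tif detections.csv --labels seg/labels.tif --out dmap
bactorg run --config config.yaml --out results
```

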