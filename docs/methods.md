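# Methods

This note documents the models, numerical choices and limitations behind
each stage of the package. Pixel coordinates are 0-based with integer
coordinates at pixel centers; point coordinates are `(x, y)`; images are
indexed `[row, col]`. The default physical scale is 60 nm per pixel edge
(configurable everywhere).

## Synthetic scenes (`synthgen`)

The generator exists so that every downstream stage can be tested against
exact ground truth. Truth is always computed before noise; every function
is bit-reproducible under its seed.

**Cells** are spherocylinders (a rectangle with hemispherical caps): a
pixel belongs to a cell when its center lies within half the width of the
central axis segment. Defaults: width 1 µm, lengths drawn from
2.5–4 µm, arbitrary orientation — the geometry of rod-shaped
cyanobacteria at 60 nm/px. `length == width` degenerates to a disk.

**Foci** are isotropic 2-D Gaussians with peak-amplitude convention and a
point-spread sigma of 120 nm (2 px), chosen so that the default detector
scale (blob diameter 3 px) is matched to the synthetic spots. The
integrated signal per focus is `amplitude · 2π σ²`.

**Confined motion** is a hard-wall random walk: isotropic Gaussian steps,
with proposals that would leave the confinement disk redrawn until they
land inside. We chose this wall over specular reflection because it has a
clean limiting law to test against — for steps much larger than the
radius the positions approach the uniform distribution on the disk (mean
distance from center `2R/3`) — whereas the stationary law of a reflected
large-step walk has no simple closed form. The walk starts at a uniform
random point of the disk: observation begins at an arbitrary phase of the
motion, so single-frame snapshots already show the confinement-dependent
spread.

**Nucleoids** are rendered as a bright region (default 150 a.u. over a
50 a.u. cytoplasm) occupying a target fraction of the cell area,
compressed along the chosen principal axis, then blurred and noised. The
true pixel set is chosen by pixel-count targeting (achieved fraction
within one quantization step of the request) and *prefers pixels at least
one pixel inside the membrane*, spilling outward only when the requested
fraction cannot fit. This emulates the radial centering of real
nucleoids: in a projection image the membrane-adjacent pixels sample
cytoplasm, which is precisely the assumption the rim-background method
(below) relies on.

**Protein patterns** come in three regimes: `polar_gradient`
(exponential decay from one pole with decay length 0.2 of the cell
length; the bright pole flips at phase 0.5, so a phase ramp yields
pole-to-pole oscillation), `diffuse` (flat), and `puncta` (a few bright,
well-separated spots at seed-deterministic interior positions).

**Noise** is additive background (default 100 a.u.) plus Gaussian read
noise (default σ 5) with optional Poisson shot noise. The defaults put
synthetic SNR high enough that detection failures indicate bugs rather
than noise; tests that probe noise robustness raise σ explicitly (SNR 10
means peak signal over read σ of 10).

**Scenes** place non-touching cells on a tile grid and render phase
contrast (dark rods on a bright background), the focus channel, the
protein channel, a DAPI-like nucleoid channel, and optionally a channel
pair with prescribed Pearson correlation (bivariate normal in-mask
pixels). Stage drift is an integer random walk applied identically to all
channels; the frame interval is a free parameter and is not asserted
anywhere.

## Stack I/O and registration (`stackio`)

Stacks are multi-page TIFFs (time-major, channel within time) with a JSON
sidecar for channel names, pixel size and frame interval; a missing
sidecar or a page-count mismatch is an explicit error, never a guessed
layout. Registration aligns the chosen reference channel (phase contrast
in normal use) of each frame to frame 0 by integer-pixel
cross-correlation of mean-subtracted images, computed in the frequency
domain with zero padding to avoid wrap-around peaks; the same shift is
applied to all channels of that time point. Integer-only shifts are
deliberate: subpixel registration would resample intensities and perturb
focus-intensity sums and kymograph bands. Vacated pixels are filled with
the frame's modal (rounded) intensity. Flat reference frames get shift
(0, 0) and a flag; shifts beyond 25% of the frame size indicate a failed
acquisition and raise.

## Segmentation and morphology (`cellseg`)

Segmentation proper is a pluggable backend — any callable from image to
label map, so a pretrained neural segmenter can slot in; the built-in
backend (invert + Otsu, 4-connected labeling) handles synthetic phase
contrast. The module owns what surrounds the backend: a 66 nm Gaussian
pre-blur, per-cell hole filling, removal of border-touching cells, label
compaction, and an override-label-map hook for manual corrections.

Morphology is skeleton-based. The mask's skeleton is pruned to its
longest geodesic path (ties broken in sorted pixel order, which keeps the
result translation-invariant), and each end is extended along the local
tangent to the boundary (half-up rounding in the stopping rule, again for
translation invariance). Length is the midline's arc length. Width is
twice the mean perpendicular half-chord over the cylindrical part of the
midline (vertices farther from both poles than the cap radius); each
half-chord is located where the bilinearly interpolated mask crosses 0.5
along the normal, and the two sides are averaged, which centers the
estimate even when the discrete skeleton wiggles off-axis. This
subpixel-chord definition avoids the orientation-dependent bias of
distance-transform widths (up to ~7% for rotated rods). Near-round cells
fall back to a principal-axis midline; cells under 9 px are excluded.
Recovered length and width match generator parameters within 5%.

## Focus detection (`focidet`)

Per cell: unsharp-mask sharpening (radius 2 px, amount 1.0), Gaussian
blur (σ 1 px), then a single-scale scale-normalized LoG at
`σ = blob_diameter / (2√2)` (blob diameter 3 px by default, matching the
tracking detector's settings; threshold 80). Out-of-mask pixels are
replaced by the in-mask median before filtering so neighboring cells
cannot bleed in. Detections are 8-neighborhood maxima of the response
above the quality threshold, integer-pixel by default (an optional
quadratic refinement exists), sorted by quality with (y, x) tie-breaks
for determinism. Focus intensity sums *raw* pixel values whose centers
lie within distance 2*r* of the detection (r = the LoG spot radius,
`σ√2`), clipped to the image. Per-cell statistics: nearest-neighbor
center spacing, perpendicular distance to the midline polyline, and
whole-cell in-mask intensity divided by cell length.

## Tracking and confinement (`trackconf`)

Frame-to-frame linking is a rectangular linear assignment with squared
displacement cost, gated at 7.5 px; unmatched detections open new
segments. Gap closing then merges segment ends and starts separated by
2 frames up to the maximum gap (2) and at most 4.5 px, again by minimal
total cost. Tracks shorter than two localizations are dropped. The
confinement radius crops a track to its first ten localizations and
reports the mean Euclidean distance from their centroid, in pixels and in
µm. It is translation/rotation invariant, scales linearly with the
coordinates, and its floor for immobile particles is set by localization
error (the mean distance of ten iid Gaussian localizations from their
centroid), mirroring the use of chemically fixed cells as the immobile
reference. Note the statistic saturates from below for confinement radii
large relative to the per-frame step: ten steps of σ 0.1 µm explore only
part of a 0.3 µm disk, so it is a mobility proxy, not an unbiased radius
estimate.

## Nucleoid compaction (`nucmorph`)

The cytoplasmic background is estimated from the inner rim of the cell
boundary (mask minus its erosion by 2 px): the rim intensities are
histogrammed into 64 bins and fit with a Gaussian by least squares,
initialized at the dominant histogram mode with a MAD-based width, so a
bright-nucleoid tail leaking into the rim cannot drag the center. Rims
under 20 px or failed fits fall back to the rim median, flagged. The
background is subtracted (negatives clipped to zero, preventing threshold
bias from negative lobes), the image blurred at 66 nm, and Yen's
threshold computed on the in-mask intensity histogram (per cell, not per
field, since each cell is scored independently); pixels at or above
threshold are the nucleoid. `s_comp = 1 − A_nuc / A_cell`.

**Known limitation.** The blur step turns the nucleoid edge into a ~3 px
intensity ramp whose histogram valley is flat, and Yen's criterion then
settles against the dominant mode's flank rather than at mid-ramp. The
segmented boundary therefore sits about one pixel off the true edge, in
the direction that shrinks the majority class. For 4 × 1 µm cells this
biases `s_comp` toward 0.5 by up to ~0.1–0.2 at extreme area fractions
(0.2 or 0.8), and the effect is scale-invariant because the shift is
proportional to the 66 nm blur physically. The bias vanishes when the
blur step is disabled (area fractions are then recovered exactly), and
orderings across conditions are always preserved — so comparative
compaction results are trustworthy while absolute area fractions at the
extremes are not.

## Oscillation score and kymographs (`oscillo`)

Per cell, intensities are min-max normalized,
`I_n = (I − I_min)/(I_max − I_min)`, histogrammed (20 bins over [0, 1]),
and scored as the fraction of pixels with `I_n < 0.5` — strictly: ties at
exactly 0.5 count as not-below. A constant cell is degenerate and scores
0 with a flag. The score is invariant under positive affine intensity
transforms. Note that on real segmentations the per-cell minimum often
comes from dim mask-edge pixels, which deflates diffuse-cell scores below
the idealized 0.5; polarized cells still score distinctly higher, which
is the quantity of interest. Scores are computed per frame, with time
averaging left to the caller.

Kymographs sample a band perpendicular to the midline (default 11 px =
660 nm wide) by bilinear interpolation at 1 px steps along the normal,
average across the band, and min-max normalize each time column (constant
columns map to zero), which removes photobleaching from the
visualization. Midlines shorter than 3 px are rejected.

## Normalized-cell density maps (`cellmap`)

Each localization is projected onto the midline. If the closest midline
point is interior, the coordinate is cylindrical: `l` from arc length,
`r` from perpendicular distance, with a left/right side sign from the
cross product. If it is an endpoint, the coordinate is polar: `r` from
the distance to the pole, `φ` the angle between the point-to-pole vector
and the outward tangent. `r` is divided by the per-cell width and `l` by
the length (the per-cell reading of "average cell width" is a recorded
decision). The default grid is 3 radial rings × 8 longitudinal segments
per side in the cylindrical region and 3 rings × 4 angular sectors per
side per cap; edges are half-open with boundary values going to the
lower-index bin, and the outermost ring is open-ended so boundary pixels
are always captured.

Because bins have unequal physical size, per-cell bin areas are computed
by classifying every mask pixel — subdivided 3 × 3 so bins narrower than
a pixel (the innermost ring straddles the midline) receive their fair
share — and summing subpixel areas; per cell the areas tile the cell
area exactly. Counts and areas are summed across cells, optionally pooled
fourfold over (left/right) × (head/tail) symmetry classes (the class id
is emitted with each bin for audit), and converted to probability
density: `(Σcounts / Σareas) / total_counts × n_cells`, in µm⁻². By
construction `Σ density · area = n_cells` for every map, symmetrized or
not. Representative cells for display are made by aligning masks by
centroid and principal-axis orientation, summing, and thresholding at
50% of the stack maximum.

## Colocalization (`coloc`)

Sample Pearson correlation over in-mask pixel pairs (per cell) or all
pixels (per field). Zero-variance channels yield flagged records that
summaries must exclude. No Costes randomization or Manders coefficients —
Pearson is the reported quantity. An optional chlorophyll viability gate
keeps cells whose mean chlorophyll intensity exceeds 2× the field
background (the numeric gate is this package's choice).

## Orchestration, outliers, summaries (`pipeline`)

`run_experiment` executes register → segment → detect → track → nucleoid
→ oscillation → colocalization → density map on a scene described by a
config dict, returns tidy tables, and writes CSVs plus a manifest (seed,
config hash, per-stage counts) when given an output directory; reruns
with the same config are byte-identical.

Outlier removal follows the ROUT procedure on the constant model: robust
center = median; robust scale = the 68.27th percentile of absolute
residuals corrected by n/(n−1); each value's two-tailed t probability
(df = n−1) is tested by FDR step-up at Q = 1% (the method's conventional
default; the original Q is not recoverable). Fewer than five values:
nothing removed, flagged. Flags are invariant under affine transforms of
the data. Replicate summaries pool technical replicates and report per
biological replicate the median, quartiles (linear-interpolation
convention), mean, SD and retained n per metric. Hypothesis testing is
intentionally out of scope: the tables are the input to any stats tool.

## What the synthetic tests do and do not show

Passing tests demonstrate that each algorithm implements its definition
correctly (oracle equivalence), that the chain recovers known ground
truth under controlled imaging conditions, and that the four physiology
regimes (expanded/oscillating, compacted/diffuse, expanded/clustered,
hyper-compacted) separate with the expected orderings of oscillation
score, compaction score, confinement radius, focus clustering and radial
concentration. They do not validate performance on real micrographs:
synthetic cells have ideal spherocylinder shapes, uniform cytoplasm, a
Gaussian PSF, no chromatic offsets, no photobleaching beyond an optional
decay factor, no cell division or overlap, and noise that is stationary
across the field. Segmentation backends trained on real phase contrast,
and parameter choices for unsharp masking, must be set per dataset.

## Problem sizes

The test suite and the acceptance script run scenes of 4–10 cells with
1–10 frames, 100-cell populations for detection fidelity and score
separation, 1,000 random tracks for the confinement oracle, and 10⁴-pixel
masks for correlation recovery; these sizes give stable statistics for
every assertion while keeping a full run to a few minutes on one CPU.
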