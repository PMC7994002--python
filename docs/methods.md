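# Methods

This note records the models and procedures implemented in `atlasforge`, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic phantoms do and do not show about real
data.

## Data model

A volume is a 3D scalar array with per-axis physical spacing in µm and axis
order (plane, row, column); axis 0 is the sagittal stacking axis, axis 1 runs
dorsoventrally, axis 2 rostrocaudally. Annotations are integer volumes
co-shaped with their intensity volume; 0 is background. All distances and
densities are physical (spacing-aware); all morphological radii and Gaussian
sigmas are in voxels unless noted. Indices are 0-based, ranges half-open.

## Anatomical edge maps

Edges are the zero crossings of a Laplacian-of-Gaussian response: the
intensity volume is blurred with an isotropic-in-index-space Gaussian
(default sigma 5 voxels for full-resolution atlases whose structures span
hundreds of voxels; sigma ≈ half the inter-boundary spacing is the rule used
for smaller data, giving sigma 2 for the 128³ phantom), a 3×3×3 Laplacian is
applied, and a voxel is flagged where the local minimum and maximum of the
response over a spherical radius-1 neighborhood disagree in sign. Edges are
restricted to the tissue foreground (Otsu threshold, optionally unioned with
the labels mask and hole-filled) and the outer surface of the foreground is
added so the brain outline always participates.

Sign changes of a near-zero response are noise, not anatomy; an optional
contrast gate (`zero_crossing_contrast`) additionally requires the local
min–max swing to exceed a threshold (a number, or Otsu of the swing). The
default is off: every sign change is flagged.

Label surfaces use the face-connected (cross) element — a nonzero voxel is
surface iff any of its six face neighbors (or the image border) differs —
while zero-crossing neighborhoods use the spherical radius-1 element; the
two connectivities serve different constructions and are fixed independently.

## Atlas completion

**Extension start.** Scanning inward from the labeled-side edge, the start is
the most lateral plane of the first run of at least 3 consecutively labeled
planes (isolated labeled planes are skipped); profiles may override the start
as a fraction of the plane count.

**Lateral extension.** For each unlabeled plane moving outward: the
thresholded histology (default threshold 10, components under 200 px
discarded) defines the structures; the previous plane's labels are resized
order-0 from their bounding box to each structure's bounding box (largest
connected object only), restricted to the structure, and unlabeled structure
voxels are in-painted from their nearest label. The labels are then refit:
each label is eroded by a disk whose radius is the per-atlas base radius
scaled by the label's median distance to the structure perimeter over the
plane's maximum distance (so central labels erode first and may vanish —
the tapering model), and the eroded labels seed a compact watershed
(compactness 0.005) on the plane of the 3D distance-to-edge landscape. The
refit plane becomes the template for the next plane.

**Rotation, mirroring, shears, stripping.** Rotations are identical 2D
rotations of every slice along the stated axis (order 0 for labels, exact at
right angles); mirroring replaces planes at index `j ≥ m = round(fraction·N)`
with plane `2m−1−j` (clamped), for intensity and labels alike; mirrored label
IDs keep their sign unless hemisphere-aware negation is requested. The
piecewise affine shears a cuboid ROI plane-by-plane along one axis with a
linear 0→max ramp, optionally ramping line-by-line from an attachment face so
the block stays connected on two faces; vacated voxels become background and
content shifted past the ROI is clipped. Non-CNS stripping crops both
volumes to the labels' bounding box padded by 5 voxels and zeroes intensity
outside the labels mask dilated by a radius-2 ball.

## Edge-aware 3D reannotation

Per label, the watershed seed is the erosion by a spherical element (default
radius 8; half the typical structure half-width is the scale rule — radius 4
for the phantom) united with the 3D skeleton of the lightly eroded label
(half the main radius), which rescues sheets and processes that global
erosion would destroy. Labels of ≤ 2 voxels skip skeletonization; a label
whose seed would be empty falls back to its lightly eroded mask or its
innermost voxel, so every ID survives into the seeds.

The landscape is the negated spacing-aware Euclidean distance transform of
the edge map: voxels far from anatomical edges flood first and basins meet at
the edges. Growth is a compact watershed (compactness 0.005) restricted to
the labels' foreground (optionally opened by radius 0–2 to keep labels from
leaking across small ventricular gaps; seed voxels are always kept inside
the mask). Mask islands unreachable from any seed are assigned their nearest
label afterwards, so the output is exactly a partition of the mask.
Tie-breaking on flat plateaus follows the flooding queue's deterministic
(value, insertion order) discipline, so identical inputs give identical
outputs. The composed pipeline finishes with a light adaptive opening
(radius 1 in the phantom profile: after a 3D watershed only low-amplitude
artifacts remain, so a small filter suffices).

Spherical erosions/dilations/openings are computed exactly as distance-
transform thresholds (erosion by radius r keeps voxels with distance-to-
background > r), which is both faster than sliding large structuring
elements and exact for the Euclidean ball.

## Label smoothing

Labels are processed largest to smallest in place: each label is extracted
in its bounding box padded by the filter radius + 1, filtered, and written
back (vacated voxels cleared, gained voxels overwriting); afterwards any
foreground voxel left unlabeled is assigned its nearest surviving label.
Later (smaller) labels therefore overwrite earlier gap fills; the order is
fixed and documented because it is observable.

*Adaptive opening*: spherical opening of radius `size`; for labels of
≤ 5000 voxels the radius is halved (floor, minimum 1); if the opened label
vanishes the opening is replaced by a closing. No label is ever lost; the
filter actually applied and before/after voxel counts are recorded per label.

*Gaussian baseline*: the label indicator is blurred (`iterations` passes,
default 2) and re-binarized at a low support floor (0.0025) rather than 0.5.
At the sub-voxel sigmas used for this baseline the discrete kernel is nearly
a delta, so a 0.5 threshold would make the filter the exact identity; the
support floor instead keeps every voxel the blur reaches with non-negligible
mass, so sequentially processed labels fill their pinholes and absorb sparse
fragments embedded in them. This reproduces the baseline's documented
failure mode — sparse fragmented labels are lost even at sigma 0.25, loss
grows with sigma, and quality first rises then falls as displacement
grows — while smooth convex labels are untouched at small sigma. The floor
sits between the 3-neighbor convex-surface support (~2.0e-3) and the
4-neighbor pocket support (~2.7e-3) of the sigma-0.25 kernel.

*Contour interpolation*: intervening planes between two edited planes take
the zero superlevel set of the linearly interpolated 2D signed distance
fields (inside-positive), leaving the end planes untouched.

## Quality metrics

**Compactness** `SA³/Vol²`. Volume is voxel count × voxel volume. Surface
area comes from a marching-cubes mesh of the indicator smoothed by a
sub-voxel Gaussian (sigma 0.6 voxels, one-voxel-plus padding, level 0.5,
anisotropic spacing honored): a raw binary mesh overestimates the area of a
digital ball by ~29% (staircase bias), while the smoothed mesh puts a
radius-30 ball within ~7% of the spherical bound 36π and a 60³ cube within
~5% of the closed form 216. Masks too small to reach the iso-level after
smoothing fall back to the raw mesh. Smoothing acts in voxel space and the
mesh in physical space, so the statistic is exactly invariant to uniform
spacing rescaling.

**Smoothing quality.** Per label: compaction `(C_orig − C_smooth)/C_orig`,
displacement `|smooth ∖ orig|/|smooth|`, quality = compaction −
displacement; atlas-wide quality is the volume-weighted mean over surviving
labels, with lost labels counted separately (their quality is undefined).

**Dice** `2|A∩B|/(|A|+|B|)`; two empty masks score 1.0 by convention (the
registration-quality use never reaches that case).

**Edge distances.** The spacing-aware distance transform of the edge map
sampled at every label-surface voxel; per-label sums and the total, in µm.

**Intensity CV** `σ/µ` per label with the population σ (divide by n); labels
with zero mean are flagged NaN and excluded from aggregates with a warning.
Both the volume-weighted mean and the volume-weighted median are reported.

## Nuclei detection

Per chunk: intensities are clipped at the 5th/98.5th percentiles and
rescaled to [0, 1]; values below the 50th percentile are clipped away and
the remainder restretched (driving kept signal toward saturation and
flattening sub-median background — the clip direction that behaves correctly
whether nuclei are dense or sparse in the chunk); unsharp masking (sigma 8,
amount 0.3) sharpens blob boundaries; a radius-1 octahedral erosion
separates touching blobs. Scale-space LoG detection then sweeps 10 sigmas
over `r/√3 · [0.5, 1.5]` for expected nucleus radius r, with response
threshold 0.1 and overlap suppression 0.55; radius estimates are `σ√3`.
Blobs centered in the first/last plane of a chunk are dropped (they belong
to the neighboring, overlapping chunk). Anisotropic stacks can be resampled
to near-isotropy along the coarse axis first, with coordinates mapped back.

Whole volumes are processed in overlapping chunks (overlap ≈ the nucleus
diameter) laid out on an even grid with no degenerate sliver chunk at the
far edge (thin chunks make percentile normalization misbehave). Results are
pooled in a canonical sort order — chunk scheduling cannot affect the
output — and duplicates are merged axis by axis over the actual
consecutive-chunk overlap slabs, padded by the pruning tolerance (default
half the overlap per axis): any pair within tolerance on every axis becomes
one blob at the coordinate/radius mean.

Evaluation scales coordinates to µm and computes a Hungarian
minimum-total-distance assignment; pairs within the match tolerance are true
positives. With an inner margin set, a first pass matches inner-region
objects only and a second pass pairs remaining inner objects against the
border shell, so matches that straddle the ROI border are not miscounted;
counting is restricted to inner objects. Recall is `TP/(TP+FN)`, precision
`TP/(TP+FP)`; empty truth and detections score 1.0. A grid-search utility
sweeps detection hyperparameters over fixed fixtures.

## Density and clustering

Blob centers are scaled, rounded to the nearest voxel and accumulated into a
heat map (out-of-bounds blobs dropped and counted). Per label: nuclei count,
volume in mm³ (voxel count × voxel volume × 1e-9), density per mm³, and the
CV of per-voxel counts. A blob on a label boundary belongs to the label at
its rounded voxel — one rule shared by counting and clustering.

DBSCAN runs per label (a cluster cannot span labels) on coordinates in µm
with `min_samples = 2·ndim = 6` and eps defaulting to 20 µm; the sorted
k-th-nearest-neighbor curve (k = 2·ndim − 1 = 5) is provided for elbow
inspection, and the eps sweep range defaults to 10–40 µm. Unclustered
nuclei are noise; because a misplaced label boundary strands nuclei in
pockets too small to cluster, total noise over labels is a label-misalignment
indicator.

## Synthetic phantoms

**Atlas phantom** (default 128³, 12 labels): nested ellipsoid shells split
dorsoventrally, each label with its own mean intensity (60–230, background
5, Gaussian noise SD 2 — averaged histology templates are high-SNR, and at
noise SD 5 the inter-region LoG response would fall below the noise response
and no edge detector could operate), laid out symmetrically about the
mid-sagittal plane so mirroring and extension have exact ground truth. The
degraded labels dilate or erode each region's 2D mask per plane by a random
radius up to the jitter amplitude (default 4 voxels, chosen so the
degraded-vs-true per-label Dice sits near 0.76–0.8, a typical disagreement
level between plane-wise annotations and their anatomy-refined
counterparts), then re-partition the true foreground by nearest-label
in-fill —
jagged boundaries in orthogonal views, exactly as plane-wise annotation
produces. Options clear a fraction of lateral planes, drop one hemisphere,
and add a sparse fragmented label of ~30 single voxels embedded in the core
deeper than the maximum per-plane boundary recession (jitter + 1), so its
absorption behavior under the smoothing filters is deterministic. The
fragmented label exists to exercise the closing fallback; it has no coherent
boundary, so refinement metrics are evaluated on the fixture without it.

**Nuclei phantom** (default 128³, 200 nuclei): quasi-spherical blobs with
Gaussian profile σ = r/√3 at rejection-sampled centers (minimum separation
8 voxels, 6-voxel edge margin), radius 3 ± 0.3 voxels. Noise is
shot-noise-limited fluorescence: Poisson noise on the signal with peak SNR 5
plus 1% additive camera read noise on a dark background, as in cleared-tissue
lightsheet imaging; an additive white-Gaussian model is available as an
option. All generators are pure functions of (parameters, seed).

**What passing tests do and do not show.** The phantoms have piecewise-
constant region intensities, geometrically simple boundaries, dark nuclei
backgrounds and no registration error, staining gradients, vasculature or
tissue damage. Passing shows the algorithms are implemented correctly and
behave as designed under their stated assumptions; it does not certify
accuracy on real histology, where edge maps are noisier, label/anatomy
disagreement is structured, and detection contends with autofluorescence and
touching nuclei. Parameter scale rules (edge sigma ~ half the boundary
separation; seed erosion ~ half the structure half-width) transfer; specific
numbers may not.

## Problem sizes and degenerate inputs

The shipped test and acceptance runs use 64³–128³ volumes with 8–12 labels
and 80–200 nuclei — small enough to iterate quickly, large enough that
shells are several erosion radii thick and detection statistics are stable.
Degenerate inputs are handled explicitly: constant images threshold to empty
masks with a warning; empty label sets refuse to in-paint or strip; an empty
edge map refuses distance statistics; constant ROIs preprocess to zeros;
labels of ≤ 2 voxels skip skeletonization; a label whose blurred indicator
never reaches the re-binarization floor keeps its original mask rather than
vanishing numerically.

## Known limitations

Filter sizes are uniform within a label (no spatially varying structuring
elements); edge strength is not weighted by local intensity contrast; the
watershed compactness value is tied to this landscape formulation and may
need recalibration against other implementations (the planar-edge test
anchors the behavior); automatic midline detection is out of scope — the
per-atlas profiles carry manually determined rotations and mirror fractions;
registration to sample brains is an external step, and the density stages
consume already-registered label volumes.
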