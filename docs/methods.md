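# Methods

This note documents the models and procedures implemented in `msq`, the
defaults that matter, the synthetic data the tests rely on, and the design
choices made where the design was genuinely open.

## Coordinate and physical conventions

All pixel coordinates are 0-based with origin at the top-left, x rightward
(columns) and y downward (rows). Every rectangle is half-open (right and
bottom edges exclusive) so that abutting tile cores partition the slide —
this is what makes cross-tile deduplication exact rather than approximate.
Physical scale is carried per slide as microns per pixel (`mpp`), default
0.5 µm/px (a 1000-px tile then spans ~500 µm); every micron-valued
threshold is converted through `mpp` at use time, never baked in as pixels.

## Colour deconvolution

Brightfield chromogens mix linearly in optical density (Beer–Lambert), so
`od = −log10(max(I, 1)/I0)` with `I0 = 255` and base 10 throughout — the
convention is pinned so tests can assert exact values (intensity 25.5 ↔
OD 1.0). The stain matrix has unit-norm columns (chromogen, nuclear,
residual). Estimation is Macenko-style: tissue pixels (OD vector norm above
`od_floor = 0.15`) are projected onto their two leading principal
directions, and the stain vectors are taken at the 1%/99% percentiles of
the in-plane angle; the residual column is the normalized cross product.
Columns are labelled by cosine match against reference hues (AEC ≈ red,
haematoxylin ≈ blue-purple; standard published OD vectors). One matrix is
estimated per staining round, because every round has its own
chromogen/counterstain balance, and the nine floats are persisted into the
run configuration for bit-identical reruns.

Unmixing is an exact per-pixel 3×3 solve; negative concentrations are
clipped to zero and *not* renormalized — clipping is visible in QC rather
than smeared across channels. Deconvolution is per-pixel, hence trivially
tile-order independent.

## Tissue masking and tiling

A pixel of the thumbnail is tissue when its HSV saturation exceeds
`s_min = 0.05` and value falls below `v_max = 0.95` (glass is bright and
unsaturated), followed by morphological closing, hole filling and removal
of objects under 64 mask pixels. Manually drawn regions *replace* the
automatic mask entirely — override, not union, so a reviewer's correction
is authoritative. Tiles are `tile_size = 1000` px cores anchored at the
tissue bounding box, padded by `overlap_frac/2 × tile_size = 50` px per
side; two neighbours therefore share a 100-px (10%) strip, giving
registration and segmentation symmetric context at edges while cores stay
disjoint. Tiles under `min_tissue_frac = 0.05` tissue are dropped; their
area is excluded from the analysed-area denominator used for densities,
and both areas are recorded.

## Registration

Rounds are registered to the first round only through their deconvolved
nuclear channels — tissue morphology and chromogen signal differ between
rounds, the counterstain does not. Coarse alignment is a whole-thumbnail
phase correlation whose confidence (NCC of the shifted overlap) gates a
low-confidence fallback to zero shift. Per tile, an affine stage
(regular-step gradient descent, 3-level pyramid) is followed by a B-spline
elastic stage (grid spacing 100 px, 2-level pyramid, L-BFGS-B, ≤100
iterations), both optimizing normalized cross-correlation evaluated on a
deterministic 5% pixel sample (nuclear tiles are texture-rich; dense
evaluation only costs time). Mutual information is available by config for
cross-modality cases. The composed transform is materialized as a dense
backward displacement field and applied unchanged to the RGB channels with
linear interpolation and white fill.

A fallback ladder — elastic → affine-only → identity, keeping whichever
scores best — guarantees the reported post-metric never falls below the
identity baseline on empty or low-texture tiles. On synthetic tiles with a
known rot-2°/shift-(6,3)/5-px-elastic warp, the recovered field agrees
with the analytic forward map to ≲0.1 px mean residual.

There is no published parameter set for the elastic stage on this kind of
data; the values above are this package's pinned, config-exposed choice.

## Composite segmentation

Each round's nuclear channel is segmented independently. The built-in
backend is deliberately classical and fully deterministic: Gaussian
smoothing (σ = 1.5), a two-stage Otsu threshold (if the first split claims
most of the raster it has merely separated glass from the diffuse tissue
wash, and is re-run within the tissue to isolate nuclei),
Laplacian-of-Gaussian blob seeds, and marker-controlled watershed; objects
outside [12, 2500] px² are discarded. Deep-learning backends (stardist,
cellpose) are selectable by name and raise a clear error when absent.

Reconciliation is a greedy centroid consensus: candidates are visited in
(round, label) order; each claims the nearest unconsumed centroid within
`match_radius_um = 3` µm (6 px at default scale — 30% of a typical 10-µm
immune cell, absorbing residual registration error) from every other
round. A composite is emitted iff support/n_rounds ≥ `consensus_frac =
0.6`, compared in exact rational arithmetic so 3/5 passes (the rule is
inclusive). Geometry is taken from the earliest detecting round (the
registration reference frame); union or intersection alternatives were
rejected because registration noise inflates or erodes them. The greedy
matcher agrees with an exhaustive union-find oracle on realistic densities
(cells separated by more than twice the radius), which the tests assert.

RBC filtering is this package's own stand-in (no published criterion): a
cell is flagged when its median nuclear OD falls below the cohort's Otsu
split AND its median residual OD lies above the residual Otsu split, with
residual medians under 0.02 OD treated as deconvolution noise rather than
evidence. It is validated only on synthetic fixtures. Cohorts under 10
cells skip the filter (Otsu on a handful of points is meaningless).

Cytoplasm is simulated by dilating each nucleus by `cytoplasm_px = 3`
pixels; rings of neighbouring cells may overlap (expansion is per cell).

## Quantification and deduplication

Per cell × round × compartment: chromogen OD min, max, percentiles
{10, 25, 50, 75, 90} (linear interpolation; the exact set is
configurable), mean, std, and the median nuclear OD (the RBC filter's
input, alongside the residual median over the nucleus). Morphology —
area, perimeter, ellipse axes from second moments, eccentricity — is
measured once from the composite nucleus, which is by construction shared
across rounds. Intensities are recorded in OD; the transform from 8-bit
intensity is monotone, so rank-based downstream results are unchanged.
Empty compartments yield NaN-marked statistics (imputed with 0 OD for
clustering only, flagged); a record survives only if its centroid lies in
its tile's half-open core, and ids derived from (tile row, tile col,
local index) make id collisions a loud failure rather than silent double
counting.

## Classification

Each marker is clustered independently on that stain's intensity
statistics plus shared morphology: z-score → PCA keeping components to
90% cumulative explained variance → mini-batch k-means with k = 20
(a value fine enough to isolate positive populations and coarse enough to
review; no published default exists). Reviewer decisions then binarize
whole clusters, with two escape hatches: hierarchical re-clustering of a
mixed cluster into subtier paths ("3" → "3.0", "3.1", …; 0-based like the
k-means labels) and per-cell overrides that take precedence either way.
Precision–recall sweeps rank clusters by descending mean whole-cell
chromogen OD; the random baseline of such a sweep is the prevalence line.

The batched-GMM alternative samples ≤50 000 cells, embeds the PCA scores
in 2-D with UMAP (n_neighbors 15, min_dist 0.1, fixed seed), splits the
sample into ⌈n/833⌉ ≤ 60 batches, fits one GMM per batch seeded from
shared k-means++ centroids, pools the component means, z-scores them per
feature and merges them by k-means into the final centroids. Cells outside
the sample inherit the label of their nearest sampled neighbour in PCA
space (the assignment rule for unsampled cells is this package's choice).

## Spatial statistics

Compartment assignment is point-in-polygon with the boundary counted
inside; overlapping annotations resolve by file order — the pathologist's
ordering is the only available priority signal. Distances are between
centroids in µm (the features table stores centroids; "proximity" here is
not membrane contact). For populations A and B, one nearest-neighbour
distance per A cell (self excluded when A = B) is computed exactly (the
KD-tree is only a speed-up), and the distribution is summarized by the
mode of a Gaussian KDE evaluated on a 512-point grid over
[0, max + 3·bandwidth], ties breaking toward the smaller distance.
Bandwidth defaults to Scott's rule (n^(−1/5)·σ̂) and is configurable; an
all-identical sample returns that value without a KDE. Each summary row
carries n_A and n_B so users can weight per-sample modes as they see fit.

## Validation statistics

Manual click points are matched to segmented cells point-in-polygon with
consumption, in point-file order (nearest-centroid tie-break when one
point sits in several cells); unmatched points are FNs (drawn as 3-px
circles in QC overlays), unconsumed cells FPs. Dice is 2TP/(2TP+FP+FN).

The Spearman test computes ρ from average ranks (equal to
1 − 6ΣD²/(n(n²−1)) without ties). For n ≤ 9 without ties the two-sided
p-value is exact: the tail probability P(|ρ_perm| ≥ |ρ_observed|) over all
n! equally likely rank permutations, enumerated outright. This two-sided
tail definition (not a mid-p variant) reproduces the standard printed
values for perfect monotone association at n = 5 (p = 2/120 ≈ 0.0167).
Larger n or ties fall back to the t approximation, flagged as non-exact.

## Synthetic data

`msq.synthetic` renders what the pipeline consumes, with complete
provenance: elliptical nuclei (radius 4–6.5 px, OD 0.55–1.0) through
Beer–Lambert mixing with a known stain matrix over a faint nuclear-hue
tissue wash (OD 0.13 — enough saturation to trip the HSV mask, below the
deconvolution OD floor); AEC-hue cytoplasm rings on marker-positive cells;
anucleate RBC-like discs painted in an eosin-like hue whose overlap with
the counterstain reproduces the classic weak-false-nucleus artefact;
single-round artefact blobs; per-round random affine + smooth sinusoidal
elastic warps; per-round cell dropout; Gaussian pixel noise (σ = 1.5 grey
levels). Warps are generated as analytic backward maps and each cell's
post-warp position is solved by fixed-point iteration, so registration
error is measurable in pixels against truth rather than by image
similarity. Default study conditions for the consensus suite: 5 rounds,
500 cells, 20 single-round artefacts, 10% dropout, warp amplitude ≤ 5 px.

What the generator does **not** emulate — real chromatin texture, uneven
illumination, folds, out-of-focus regions, scanner stitching seams,
touching cell clusters at tissue densities — bounds what passing tests
show: they demonstrate the algorithms are implemented correctly and
recover planted truth under controlled degradation, not that segmentation
accuracy on clinical slides matches any particular figure.

## Numerical choices and degenerate inputs

Zero-area reads, empty point populations, singular stain matrices, k >
n clustering and unknown tier paths raise; empty masks, all-background
thumbnails, sub-10-cell RBC cohorts and unknown config keys warn and
continue. Percentiles interpolate linearly; Otsu thresholds fall back to
the median when a cohort is constant; KDE ties break toward zero; the
k-means paths are seeded explicitly and the registration metric sample is
drawn with a fixed seed, so a written-then-reread config replays a run
bit-identically.

## Problem sizes in the test suite

The suite runs the full pipeline on a 3-round, 150-cell panel and the
consensus study on a 5-round, 500-cell panel (2000² px), registration
recovery on a single 1100² tile pair, and classification recovery on a
400-cell single-round slide — sizes chosen so the planted-truth
comparisons are statistically meaningful while the whole suite stays
comfortably runnable on one CPU.

## Known limitations

Membrane-marker segmentation, doublet resolution, texture features,
cross-scanner intensity calibration, TMA de-arraying and vendor slide
formats are out of scope. The RBC criterion and the elastic-registration
parameter set are documented package choices, not published values. The
GMM path's seeding and UMAP parameters are pinned but were not tuned
against any external reference.
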