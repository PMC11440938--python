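# Methods

## Scope and model

The package analyzes 2D multi-channel fluorescence fields (maximum
projections are assumed done upstream; 3D input is rejected).  Each field
carries a nucleus channel, a cytoplasm channel (a membrane stain can be used
by inverting the channel), an organelle channel and an optional measurement
channel, with a single pixel size in µm/px.  Coordinates are 0-based,
x = column, y = row, origin top-left; distances are reported in µm with
pixel-unit columns kept alongside in the CSV exports.

## Segmentation

Nuclei: median filter (disk footprint) → rolling-ball background subtraction
→ automatic global threshold (Otsu by default; Li/Yen/triangle/mean/isodata
selectable) → optional binary erosions → 8-connected instance labeling.
Instances touching the field border, outside the size range (µm²) or outside
the circularity range are rejected.  Circularity is the ImageJ-style
4πA/P² on the instance perimeter, clamped at 1 to absorb discretization.

Cells: (optional inversion) → median → rolling ball → *fixed* global
threshold → marker-controlled watershed.  The watershed relief is the
Gaussian-smoothed (default σ = 10 px) sum of the nucleus and cytoplasm
channels; seeds are its prominence-filtered maxima (default prominence 10
gray levels), and the 1-px watershed boundary lines are multiplied into the
area mask.  Separated instances are labeled with 4-connectivity (so the 1-px
lines actually disconnect them), filtered by size/circularity, and finally a
cell survives only if it contains exactly one surviving nucleus (majority
pixel overlap).  Seeding from composite-image maxima rather than from
nucleus instances is deliberate: two nuclei close enough that their smoothed
peaks merge leave their cell unseparated, and the binucleate cell is then
rejected by the nucleus-count rule instead of being artificially split in
two.  Cells touching the border are kept by default (`reject_border_cells`
flips this); only border nuclei are always rejected.

The thresholded cell-area mask *before* watershed and filtering defines the
background region (its complement) for field-level background estimation;
an all-covering mask flags the background as absent rather than zero.

A filter radius of 0 disables the corresponding step.  The packaged defaults
(median radius 2, no rolling ball, fixed threshold 60) suit clean
high-contrast data such as the simulated cells and are expected to be tuned
per dataset through the settings file; rolling-ball radii on real data are
typically of the order of the cell diameter in pixels.

## Detection

The organelle channel is filtered with a scale-normalized LoG,
r = −σ²·(∇²G_σ * I), so bright blobs on a dark background give positive
maxima whose amplitude is comparable across σ.  For a disk of radius R and
contrast c the center response is c·R²/σ²·exp(−R²/(2σ²)) — useful for
choosing a prominence.  Maxima are prominence-filtered via the h-maxima
transform: regional maxima of the morphological reconstruction of (r − h)
under r.  This realizes ImageJ-style noise tolerance exactly: a maximum
survives if it stands ≥ h above the highest saddle connecting it to a higher
maximum, and maxima closer than h in height to a shared saddle merge into
one plateau, which is reduced to its centroid.  Plateaus touching the image
border are discarded (undefined filter support).  Detections are kept only
inside surviving cells and, by default, outside every nucleus.  Whether
prominence applies before or after the σ² rescaling is an implementation
choice; here it applies to the rescaled response, documented rather than
inferred.

## Measurements

Per cell, the distance map is the exact Euclidean distance transform
(`scipy.ndimage.distance_transform_edt`) of the nucleus complement,
restricted to the cytoplasm (cell minus nucleus): nucleus pixels have
distance 0 and the first cytoplasmic ring distance 1 px, a convention chosen
because the sub-pixel location of the "nucleus edge" is otherwise undefined.
Any reference mask (e.g. a Golgi segmentation) can replace the nucleus under
the same contract.  The Feret diameter is the maximum pairwise distance
between boundary *pixel centers* (computed on convex-hull vertices; equal to
the brute-force maximum, which the tests assert exactly).  Per-pixel
intensity profiles bin distances into half-open bins [k·w, (k+1)·w), default
w = 1 µm, wide enough for readable curves at typical magnifications while
resolving a 10-µm perinuclear band.

## Analysis

Aggregation applies field-level background subtraction (mean channel
intensity outside the unfiltered cell mask), clamped at 0 because gray
values cannot be negative, removes cells with Feret diameter above 600 µm
(a sanity bound against segmentation fusions) and averages distances per
cell, so statistics operate on cells, not detections.  The perinuclear index
splits the cytoplasm at a fixed 10 µm from the nucleus edge; the default is
the ratio of *mean* intensities inner/outer, with the integrated-density
ratio available as an option (the two differ by the region-area ratio, and
the integrated variant is the cell-size-sensitive one the robustness study
exercises).  Kernel density curves use a Gaussian kernel with Silverman's
bandwidth by default (an absolute bandwidth in µm can be given); the curve
is evaluated on a grid padded 9 bandwidths beyond the data so its exact
integral over the grid span (computed through the normal CDF) is 1 to
numerical precision.  A zero-variance sample degrades gracefully to a narrow
peak at the common value instead of failing.

The two-sample comparison is the unpaired two-sided Wilcoxon rank-sum test:
exact by full enumeration of group assignments with midranks when
C(n, n_A) ≤ 50 000 (ties handled correctly), exact via the tie-free
distribution for larger untied samples, and the normal approximation with
tie and continuity corrections otherwise; the method used is reported.

## Detection validation

Manual and automatic point sets are matched greedily on the pairwise
Euclidean distance matrix in increasing distance order (ties broken by point
index), one-to-one, accepting only distances strictly below the threshold
(default 4 px, the smallest expected object spacing).  Matched pairs are TP,
unmatched manual points FN; unmatched automatic points within the threshold
of a matched manual point are reported separately as ambiguous
over-detections (excluded from FP by default, a flag counts them as FP),
and the rest are FP.  F1 = TP/(TP + 0.5·(FN+FP)).  Greedy nearest-first
matching is not a maximum-cardinality matching in adversarial geometry (two
manual points sharing two equidistant autos), but for detection-like
instances — objects spaced at least twice the threshold apart, detections
jittered by less than half of it — the match graph is a union of stars and
greedy provably equals the optimal assignment; the test suite checks this
against `scipy.optimize.linear_sum_assignment` on random such instances.

## Synthetic cells and the robustness study

The generator renders one cell per 8-bit 500 × 300 px 3-channel field:
an axis-aligned ellipse ("oval"/"elongated") or rectangle ("cubical") cell,
a disk nucleus at the cell centroid, and organelles as filled disks of
constant intensity placed with a seeded RNG, uniformly in angle, on an
annulus at a controlled distance from the nucleus edge (default 40 ± 5 px)
with a minimum separation (default 8 px, twice the validation threshold).
Baseline values not fixed elsewhere were chosen once as a plausible adherent
cultured cell at 1 µm/px: half-axes 140 × 90 px, nucleus radius 30 px,
20 organelles of radius 3 px, intensities nucleus/cytoplasm/organelle
200/100/200 over background 20.  An optional linear background ramp and an
optional Gaussian blur of the organelle channel emulate staining gradients
and the PSF.  Placement infeasibility (annulus outside the cell) raises an
error rather than silently under-filling.  Images are deterministic per
seed, bit for bit.

What the generator does *not* emulate: photon/readout noise, textured
cytoplasm, organelle intensity variation, overlapping or sheet-like
organelles, out-of-focus light.  Passing tests therefore demonstrate the
correctness of the measurement pipeline and its geometric claims, not
segmentation or detection robustness on real micrographs, whose parameters
must be tuned per dataset.

The robustness study perturbs one parameter at a time — the derived
`cell_scale` parameter scales the cell half-axes and the organelle annulus
jointly (a pure cell-size change in which the layout scales with the cell),
plus background level and organelle radius — and measures each field with
the full pipeline by four methods: integrated-density perinuclear ratio, its
area-normalized (mean-intensity) variant, mean detection distance, and mean
Feret-normalized distance.  Each result R becomes an error factor
|R/R₀ − 1| against the same sweep's baseline field; the baseline is exactly
0 by construction.  The study's detection settings are LoG σ = 2 with
prominence 30, chosen from the disk-response formula above so that every
swept organelle radius (2–5 px) stays detectable on noiseless renders; its
intensity measurements are deliberately not background-subtracted, since
background sensitivity is one of the quantities under study.

## Problem sizes and numerical choices

The test suite and the acceptance script use 500 × 300 px single-cell
fields, 20 cells per condition in the recovery studies, sweeps of 4 values,
and 100 random instances per brute-force oracle — sizes at which the exact
oracles (quadratic nearest-pixel search, full pairwise Feret, optimal
assignment, rank-sum enumeration) are still exact and fast.  Ties in the
matcher are broken by (distance, manual index, auto index); the threshold
comparison is strictly `<`.  Degenerate inputs fail loudly: single-pixel
instances, cells without nuclei, empty samples, zero baselines and
all-covering masks each raise instead of returning a default.
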