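# Methods

This note documents the models, conventions, parameter choices and known
limitations of the package. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Atlas representation

The annotation volume is an integer label array indexed `(ap, dv, ml)`,
voxel index 0 at the anterior pole; 0 is background. The physical
coordinate of voxel `i` along an axis is its center `(i + 0.5)·spacing`,
and nearest-voxel lookup is `floor(coord / spacing)` — center-of-voxel
sampling is symmetric under axis inversion, which keeps the mirror
arguments below exact. The hierarchy is a flat list of records with
explicit parent ids (`structures.json`), one root, children lists derived
from parent pointers; aggregation to a coarser level sums leaf counts onto
the ancestor at the requested tree depth and conserves totals by
construction. Bundles are directories (`annotation.tif` or
`annotation.nrrd`, `structures.json`, `meta.json`); the NRRD path is a
minimal raw-encoding reader/writer because only TIFF tooling is otherwise
required.

The synthetic atlas is an ellipsoid inset from the volume border, with
leaf regions as nearest-seed cells of points sampled in one hemisphere and
mirrored across the ML midplane. The label volume is therefore *exactly*
left/right mirror-symmetric — deliberately, so that the horizontal-flip
ambiguity of slice registration is a modeled property of the test domain
rather than an accident. Leaves are grouped by AP position into ≥ 2
"lobes" under the root.

## Registration

A slice pixel maps to the atlas as

```
hflip → center → rotate(θ) → scale(s) → translate(t + plane center)
      → TPS displacement → embed at ap
```

with rotation about the slice center and translation in atlas-plane µm.
Composition order is fixed; a zero transform maps the slice center onto
the section center. Region lookup is nearest-voxel (no partial-volume
weighting), matching count-in-region semantics. The elastic term is a
thin-plate-spline interpolant of per-control-point displacements on a
regular grid over the section plane; zero displacements encode the
identity exactly, and magnitudes are capped (default 300–500 µm) so the
inverse fixed-point iteration `r ← a − D(r)` is a contraction (round-trip
error is checked at < 0.5 px).

**Similarity.** Slice intensity vs. label section is scored by three
bounded terms: normalized mutual information (weight 0.35), the
correlation ratio — 1 minus within-label intensity variance over total
variance (0.35) — and Dice overlap of the foreground masks (0.30). The
correlation ratio was added after observing that NMI alone admits
wrong-basin rigid fits that score above the true alignment on realistic
synthetic slices: it peaks sharply when each atlas region maps onto
homogeneous intensity. The foreground threshold is half the Otsu value:
plain Otsu splits the multimodal *within-tissue* intensity distribution
instead of tissue-vs-background on images whose background is ≈ 0. All
terms are invariant to affine intensity rescaling of the slice.

**Search.** AP: exhaustive scan over sections (default step 1 voxel), both
flip states, slice resampled to the section grid; ties break toward
smaller AP and no flip. Rigid: coarse grid (rotation ±15° step 5°, scale
0.7–1.3 step 0.1, then translation over ±25% of the plane extent) followed
by bounded Powell refinement at 2× section resolution; parameters leaving
the box are clipped with a logged warning. Because the initial AP scan
compares the *unwarped* slice, `register_slice` alternates: fit rigid,
re-score all sections against the rigidly resampled slice, refit if the
best AP moves (≤ 3 rounds). Elastic refinement is coordinate-wise search
over control-point displacements and is **off by default** — non-rigid
fits should be reviewed, and externally edited displacements can be
dropped into the per-slice registration JSON (schema versioned,
losslessly round-tripping).

**Mirror ambiguity.** On a mirror-symmetric annotation,
`(hflip, θ, tx)` and `(no flip, −θ, −tx)` assign identical region labels
to every pixel, so recovery benchmarks canonicalize estimates over this
equivalence before computing parameter errors. Slices are treated as
strictly coronal; out-of-plane tilt is not modeled.

## Detection and co-labeling

The built-in detector normalizes the image to unit range, pre-smooths
with σ = max(1, σ_min/2) px to suppress pixel noise, and runs multi-scale
Laplacian-of-Gaussian peak detection over the configured diameter band
(σ = d/(2√2), widened for the pre-blur), keeping maxima above
`threshold` × the strongest response, followed by non-maximum suppression
at `min_diameter`. It is deterministic and translation-equivariant. The
`threshold` parameter is the knob to raise (≈ 0.35) when the signal
channel carries residual tissue contrast, whose region-boundary steps
otherwise produce large-scale edge responses. Learned segmenters stay
outside the package: their outputs enter through the detections CSV
(`slice_id, channel, x, y, units, intensity, area`, with a column map for
third-party headers and µm→px conversion).

Co-labeling merges detections across channels by greedy mutual-nearest
matching within a radius (default 15 µm): repeatedly merge the globally
closest pair of cells with disjoint channel sets, each being the other's
nearest eligible neighbor; merged positions are member centroids. The
procedure conserves channel-level detections (Σ|labels| = input count),
and is invariant to channel ordering (candidates are enumerated in sorted
channel order). The radius is a documented choice; overlap-based matching
would require segmentation masks, which the package does not model.

## Quantification

Counts are computed at leaf level; coarser levels only by aggregation.
The density denominator is the region area actually sampled by that
subject's registered slices (pixel counts of the transformed grid ×
pixel area), not the atlas volume of the region — slices sample regions
unevenly. Cells and areas are pooled over a subject's slices *before*
dividing, so densities are invariant to splitting a slice's detections.
Regions never sampled are emitted as missing, not zero; background cells
are excluded from counts and reported in a QC tally. Conservation (counts
to in-mask detections; areas to slice area, exactly in pixel units) is
asserted in the acceptance suite.

## Statistics

**Task PLS** is the mean-centered variant: `R = M − grand column means`,
`R = U S Vᵀ`. `Σ sₖ²` equals `‖R‖²_F` (checked to 1e-10 relative). With
`k` conditions, `R` has rank ≤ k−1; numerically-zero LVs get permutation
p = 1 and bootstrap ratio 0 rather than noise-driven values.

**Permutation test**: condition labels shuffled across subjects,
`p = (#{s* ≥ s} + 1)/(n_perm + 1)` (never exactly zero). Defaults
n_perm = n_boot = 1000; the restricted-permutation variants (e.g. within
cohorts) are not implemented.

**Bootstrap ratios**: subjects resampled with replacement within
condition; each replicate's centered condition-mean matrix is projected
onto the fixed observed condition saliences (`R_bᵀ u_k`; the observed
value on that scale is `s_k v_k`). This is the stable limit of re-running
the SVD per replicate and aligning LVs by inner product — per-replicate
SVD alignment concentrates replicates around the observed solution,
deflates the SE and measurably inflates the null flag rate. Significance
threshold |ratio| ≥ 2.576 (two-tailed p < 0.01). Zero-SE cells with
nonzero salience are flagged ±inf, never NaN.

**ANOVA layer**: one-way F per region across conditions (subjects missing
a region dropped per region, logged), Benjamini–Hochberg q across the
tested regions (the implementation is compared against an independent
brute-force step-up oracle in the tests), Bonferroni-adjusted pairwise
t-tests post hoc. Either densities or raw counts can be analyzed; density
is the default.

## Correlation networks

Pearson correlations across subjects within one condition (≥ 3 subjects;
zero-variance regions yield missing correlations). Edges where
`r ≥ threshold` (default 0.75 — strong positive co-activation; fully
exposed in config). Communities by greedy modularity agglomeration with
deterministic labeling (decreasing size, then smallest member).

The per-edge condition-uniqueness test draws, B times, as many subjects
as the target condition has from the pooled condition-blind set and
recomputes the correlation; `null_p = (#{r_null ≥ r_obs} + 1)/(B + 1)`,
one-sided because "unique to the condition" concerns excess correlation.
The draw is **without replacement** by default: under a global null it
then reproduces exactly the random assignment of subjects to the
condition, making the per-edge false-positive rate nominal (the
with-replacement bootstrap, available as `replace=True`, duplicates
subjects, widens the null correlation distribution and is measurably
conservative). A pooled-across-edges null is not provided.

## Synthetic experiments

The generator emulates a multi-condition activity-mapping study: three
conditions (`baseline`, `ingroup`, `outgroup`) with a multiplicative rate
effect planted in a subset of regions for one condition; 6 subjects per
condition; ~19 slices/brain for the single-channel activity preset and
~6 slices with three channels (`cFos`, `Drd1`, `Drd2`) for the multiplex
preset, where each cell carries the activity marker and extra markers by
independent Bernoulli draws (default 0.3 each). Per-region base rates are
drawn once from 20–60 cells/mm². Mounting warps are uniform over ±8°
rotation, 0.95–1.08 scale, ±200 µm translation (elastic off by default);
slices are cut at atlas voxel-center AP planes. Images carry a structural
`tissue` channel (full region contrast, no spots — what registration keys
on, as with DAPI/autofluorescence in practice) and signal channels with
5% tissue bleed-through plus Gaussian spots (SNR 8 over noise
σ = 0.02) and Gaussian pixel noise; stronger structured background in a
signal channel shows up as boundary false positives and calls for a
higher detection threshold. Cells are emitted both as rendered
spots and as ready-made detection CSVs so the statistics layer is
testable independently of the detector.

What the generator does **not** model: tears, folds, bubbles,
autofluorescence gradients, staining batch effects, out-of-plane tilt,
anisotropic deformation beyond the TPS field, or disordered free-floating
sections. Passing tests therefore demonstrate correctness of the
algorithms under idealized tissue, not robustness to real histology
artifacts; on real data the manual-correction path (edited registration
JSONs, imported detections) is expected to carry more weight.

## Benchmark problem sizes

Chosen to give adequate statistical resolution at desk scale; all seeded:

- Registration recovery: 20 slices at 50 µm/px (96×96), default warp
  ranges; pass = AP within ±2 voxels, rotation ≤ 1°, scale ≤ 2%,
  translation ≤ 2 px per axis (≥ 90% of slices).
- Transform round-trip: 10 random registrations (half with elastic),
  20×20 grid, < 0.5 px.
- Detection: 10 images, 50 spots each, 20–50 µm diameters at 5 µm/px,
  SNR 8; precision/recall ≥ 0.95.
- Permutation calibration: 200 null datasets (3×8 subjects, 20 regions,
  n_perm = 199); FPR 5% ± 3%.
- Bootstrap calibration: 20 null datasets × 50 regions (n_boot = 300);
  flag rate ≤ 8%.
- Power: 20 datasets, ×2 effect in 5/50 regions, n = 8/condition
  (n_perm = 499, n_boot = 500).
- Network: 20 seeds each for the global-null calibration (15 regions) and
  the planted unique edge (30 regions, r ≈ 0.9 target / ≈ 0 pooled),
  B = 500.
- End-to-end: 2 conditions × 8 subjects × 4 slices, 8 regions, 5 µm/px,
  25 µm spots, ×2 effect in 3 regions; rates pooled across subjects.

## Known limitations

- The AP search assumes the slice is comparable to sections after
  isotropic resampling; extreme anisotropic crops would need manual AP.
- Automatic elastic refinement is a local coordinate search; large
  non-rigid distortions need manual control points.
- The co-label rule is radius-based; overlapping cells of the same
  channel are never merged.
- Statistics assume one value per subject × region (no repeated-measures
  modeling) and complete cases after dropping incomplete regions.
- The bootstrap-ratio threshold treats ratios as z-scores; at very small
  n per condition the implied p-values are approximate.
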