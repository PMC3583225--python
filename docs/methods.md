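# Methods

This note documents the models, conventions, parameters and numerical
choices behind `qisp`, and what the synthetic-data tests do and do not
demonstrate about real atlas material.

## Radial densitometry model

A QISP is defined on a band ROI running from the ventricular surface
(sROI 1) to the pial surface (sROI 20); the ventricular endpoint is always
listed first in an `RoiSpec`, which fixes the orientation convention for
every downstream statistic (the deep ratio and the zone map both depend on
it). The band is partitioned along its axis into 20 contiguous segments of
equal axis fraction; segment boundaries land on `round(k·L/20)` pixels
(half-up), so for any axis length the segment sizes differ by at most one
pixel row and the partition is deterministic. A pixel belongs to the band
when its axis projection lies in `[0, L)` and its signed perpendicular
offset in `[-w/2, w/2)` — half-open on both coordinates so masks are
disjoint and tile the band exactly.

Optical density defaults to the linear absorbance proxy
`(white − I)/white ∈ [0, 1]`. Atlas section photographs are not calibrated
transmittance measurements, so a linear proxy is the honest default; a
`-log10(I/white)` mode is available for calibrated material, with
intensities floored at one count to avoid divergence. Background is a single
scalar measured over one user-specified tissue-free rectangle and subtracted
from every bin, floored at zero. Per-sROI background fields are out of
scope.

Smoothing averages each bin with its available neighbours only: a 3-bin
window in the interior, a 2-bin window at the two ends. No padding is
invented beyond the wall; this preserves monotonicity and never exceeds the
input's range.

## Deep-ratio validation

The validity statistic is `mean(sROI 1–2) / mean(sROI 3–20)`, computed on
the smoothed profile by default (the profiles that are clustered are the
smoothed ones; the variant is selectable). A gene is invalid when the ratio
*strictly exceeds* 1.0 — a uniform profile sits exactly at 1.0 and is valid.
Two numerical details:

* the strict comparison carries a 1e-9 guard, because the two bin means of
  an exactly constant profile can differ by ~1e-16 relative in floating
  point, and that rounding must not flip validity;
* a zero superficial mean makes the ratio undefined; such profiles are
  flagged invalid with reason "no superficial signal" rather than raised,
  since a pattern with all signal in the deep VZ is precisely what the
  criterion is meant to exclude.

The ratio is invariant under positive rescaling of the profile, so staining
intensity does not affect validity.

## Clustering and zonation

Profiles are standardized per gene ((x − mean)/SD, sample SD). With
correlation distance the standardization changes only centroids, never
distances, so this choice is cosmetic for the tree but fixes the centroid
scale. Constant profiles have no direction; they are detected by an exact
min == max test (a std == 0 test fails for the same representability reason
as above), excluded from the tree, and placed in singleton clusters with
zone "unassigned".

Distances are `d = 1 − r` (range [0, 2]); tiny negative values from
rounding are clipped to 0 before linkage. Agglomeration uses average
linkage by default — the conventional choice for correlation-based gene
clustering; complete and single are available. Leaves are processed in
lexicographic gene-id order so distance ties break deterministically and
repeated runs give identical trees. The flat cut removes the k−1 highest
merges (`scipy.cluster.hierarchy.cut_tree`); cluster ids are renumbered by
the order of each cluster's first member in the caller's input. k is a user
parameter with no automatic model selection.

Zone assignment is per cluster centroid: the compartment containing the
centroid's peak bin, with ties among equal-valued bins broken toward the
more superficial bin (differentiation proceeds ventricular → pial, so the
superficial reading is the conservative one for this lineage). The default
zone map is deep 1–10, middle 11–15, upper 16–20; only the deep boundary is
anatomically pinned (the VZ spans the deep half of the wall at this stage),
so the map is fully configurable. Zone percentages are reported both as
half-up-rounded integers and at one decimal; 49/317 is therefore printed as
15 (15.5), not 16.

The tree exports to Newick with branch lengths equal to merge-height
differences; the writer is ~15 lines because SciPy has no Newick
serializer, and a test checks the output against an independent parser.

## Expression screen

The threshold rule reconstructs the standard internal-standard procedure:
`mean + 2·SD` of the negative-control RMA values (sample SD), rounded up to
the nearest 0.5. Controls at 5.5 ± 0.7 yield 6.9 → 7.0, the usual RMA ≥ 7
expressed/not-expressed boundary; the threshold is always user-overridable.
Fold-changes are computed from group means on the log2 scale (difference of
means, then 2^·). Eligibility requires the *larger* of the two group means
to reach the threshold: a gene three-fold down in the target population may
sit below threshold there while being clearly expressed in the reference,
and the rule's purpose is to exclude genes expressed nowhere, not genes
turned off. Ties at exactly the fold cutoff are included (≥). Output is
sorted by descending |log2 FC| with gene-id tie-breaks.

## Synthetic data: what it emulates and what it does not

True radial profiles are sums of Gaussian bumps on the 1–20 sROI axis plus
an optional constant baseline. Default archetypes: VZ peak at sROI 6
(width 2.5), IZ peak at 12 (2.5), CP peak at 17 (2.0), dual peak at 4 + 17
(amplitudes 0.55/0.85, the VZ+CP double-band pattern typified by Dab1),
deep-invalid peak at sROI 1, and a flat profile at 0.35. Peak amplitudes
default to 0.85 optical-density units with 5% log-normal per-gene jitter.
Positions were chosen so each single-peak archetype peaks inside its
namesake zone and only `deep_invalid` violates the deep-ratio criterion on
its noise-free profile (VZ-peak ratio ≈ 0.6–0.8, dual ≈ 0.4–0.5,
deep-invalid ≈ 20). Archetype membership counts follow the requested mix
under largest-remainder rounding, so totals are exact and deterministic.

The renderer writes density piecewise-constant per sROI using the *same*
boundary function as the extractor, offset by the background level, then
applies an optional linear illumination ramp, per-pixel Gaussian noise
(default SD 0.01 density units) and bit-depth clamping. This makes the
noise-free render→extract round trip exact to quantization (≤ 1/255 for
8-bit), which is what lets geometry bugs surface as hard test failures
rather than tolerance erosion. Default raster: 200×120 px, 160 px wall
span, 40 px band.

Replicate jitter models repeated manual ROI placement on nearby sections as
a rigid ROI shift along the axis (SD 2 px ≈ 0.25 sROI), a small image
rotation about the band centre (SD 1.5°) and a multiplicative staining
factor (SD 0.05 on the log scale). Under these defaults five replicates of
the dual-peak profile show mean pairwise r ≈ 0.96–0.99 with peak positions
within 2 sROIs — the same regime as repeated quantification of a real
double-banded gene.

Expression matrices place each gene's reference-group mean uniformly in
[7.5, 10.5] log2 units (comfortably expressed, as screened genes are), add
the planted log2 fold-change for the target group, and per-sample Gaussian
noise (default SD 0.25). Planted fold-changes are uniform on
[log2 3, log2 72], spanning the range from the screen cutoff to the most
strongly regulated transcripts. Negative controls are i.i.d.
Normal(5.5, 0.7) in every sample. All generators are deterministic under a
single seed; the pipeline derives per-stage seeds from one top-level seed
via `SeedSequence.spawn`.

What passing tests show: the measurement geometry inverts correctly, the
statistics behave as specified on profiles of the documented shape family,
and the pipeline's bookkeeping conserves counts. What they do not show:
robustness to real histology — section tears, uneven staining chemistry,
colour-channel effects, or misidentified anatomy. The generator has no
model of those; noise magnitudes are calibration choices, not claims about
atlas data. ROI placement is likewise explicit input, as it is manual in
practice.

## Problem sizes

The default test suite and the acceptance script run at the scales the
method is actually used at: 328 genes for the validation bookkeeping
(matching the atlas-covered gene count, 11 of them deep-biased, the 317
valid ones split 44/49/224 across zones), 60 genes per clustering
simulation (20 per archetype, 10% amplitude noise, 20 seeds), 5 replicates
for concordance, and ≤ 200-gene random matrices for the screen oracle.
The full suite completes in a few seconds.

## Known limitations

* Background is scalar; strong illumination gradients bias deep vs
  superficial bins slightly (the default ramp amplitude is 0).
* The Newick writer emits the binary merge tree only, without internal node
  labels.
* `cut_tree` cluster counts assume distinct merge heights; exactly tied
  merges at the cut boundary could yield fewer than k clusters (never
  observed with correlation distances on continuous data).
* Down-regulated genes are screened but not validated or clustered by the
  pipeline stage ordering, which follows the up-regulated-gene workflow;
  their QISPs can still be processed through the library functions.
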