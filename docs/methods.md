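# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that an independent
reimplementation would need to reproduce our outputs exactly.

## Containers and conventions

All computation happens on a frames × voxels matrix extracted from a 4D
volume under a binary mask. The voxel linear order is fixed package-wide:
column-major over the spatial grid, X fastest, then Y, then Z; column 0 is
the in-mask voxel with the smallest linear index. Round-tripping through
`volume_to_matrix` / `matrix_to_volume` restores in-mask values exactly;
out-of-mask voxels take a configurable fill (default 0). Two images share a
grid when shapes match exactly and affines agree within 1e-4 per element.
TR is read from the NIfTI header time step; an explicit override wins, with
a warning when the two disagree. Gzipped and plain NIfTI-1 are handled
transparently in both directions.

## Denoising

The nuisance design stacks, per enabled block: an intercept (always),
linear + quadratic trend columns, the tissue mean series (white matter,
CSF, optionally the global signal), and the six realignment parameters.
Each base series contributes up to six columns: itself, its backward first
difference (zero-padded at frame 0), its one-frame lag (zero-padded), and
the elementwise squares of all three. With every block on this gives
1 + 2 + 3·6 + 6·6 = 57 columns with the global signal and 51 without.
Trends live inside the regression, not as a separate detrend pass.
Rotations are assumed to be radians (the realignment convention); a switch
accepts degrees.

Frame censoring precedes regression: frames with FD above threshold (we
default to 0.5 mm) are marked, betas are estimated on kept frames only, but
the residual is produced for *all* frames so the subsequent FFT-based filter
sees an unbroken series; censored frames should be dropped again at metric
time. A run retaining fewer than half its frames (configurable) is an
error. Whether the regression precedes or follows filtering is exposed to
the caller; the batch tasks regress first and filter second, which keeps
the filter from reintroducing nuisance structure at band edges. Rank-
deficient designs (e.g., a global signal nearly collinear with tissue
means) fall back to the pseudoinverse with a warning, never silently.

The band-pass filter is an ideal (square-wave) filter: each series is
extended to length 2T by appending its time reverse — an even extension
that removes the wrap-around discontinuity — transformed by FFT, and bins
with `low ≤ f ≤ high` (frequencies computed on the extended length) are
kept, including the Nyquist bin exactly when `high` equals Nyquist. The
first T samples of the inverse transform are returned. The filter is
idempotent to 1e-8 and passes an in-band sinusoid within 1% in RMS
amplitude; ringing from spectral truncation is confined to the series
boundaries.

## Quality control

FD follows the sum-of-absolute-deltas convention with rotations converted
to arc length on a 50 mm sphere; FD(0) = 0. The motion summary reports the
maximum absolute translation (mm) and rotation (degrees), the mean and
maximum of the per-frame displacement `sqrt(x²+y²+z²)`, the number of
inter-frame displacement changes above 0.1 mm ("micro displacements" — the
threshold is conventional, the exact quantity it applies to was an open
choice and is documented here as the change of the rms displacement), the
mean composite rotation angle
`arccos((cos p·cos y + cos p·cos r + cos y·cos r + sin p·sin y·sin r − 1)/2)`
in degrees, mean FD, and the count of frames with FD above threshold.
TSNR is the series mean over its N−1 standard deviation; zero-variance
voxels get 0 and never survive thresholding; group-level masks threshold
the across-subject mean TSNR map.

## Spontaneous-activity metrics

*Normalization.* Mean-normalization divides by the in-mask mean; z-scoring
centers and scales by the in-mask moments. Degenerate inputs (zero mean /
zero sd) are errors, not NaN maps.

*ALFF/fALFF.* The per-bin amplitude is `sqrt(|F_k|²/L)` from the one-sided
DFT of the unfiltered series. ALFF averages it over bins with
`low ≤ f ≤ high`; fALFF divides the in-band amplitude sum by the sum over
all bins `0 < f ≤ Nyquist`. The DC bin is excluded from both sums, so
fALFF ∈ [0, 1] by construction; voxels with no spectral power get 0. The
band must contain at least one bin at the given T and TR, otherwise the
call errors with the bin resolution.

*ReHo.* Kendall's W over the seed plus its face (6), edge (18), or vertex
(26) neighbors — K = 7, 19, or 27 including the seed, shrinking at mask
boundaries to the members actually present. Temporal ranks use midranks
for ties and no tie-correction term appears in the denominator, matching
the common neuroimaging implementations (a tie-corrected variant would run
slightly higher on heavily quantized data). A fully constant neighborhood
returns W = 0 with a warning.

*FCD.* For each seed, gFCD counts voxels with Pearson correlation strictly
above the threshold (default 0.6, the canonical choice for this family of
maps); lFCD is the size of the region grown from the seed by repeatedly
adding voxels that are spatially adjacent (vertex-connected by default) to
a current member *and* supra-threshold with the seed — membership is always
judged against the seed, not against region members; lrFCD = gFCD − lFCD.
The seed itself is never counted. The binarized connectivity is stored
bit-packed, one bit per pair (V·⌈V/8⌉ bytes, exactly 1/32 of a dense
float32 matrix), and the packed path returns maps identical to the dense
float reference. Zero-variance seeds get all three metrics 0 with a
warning. Results are independent of evaluation order and therefore of any
parallel chunking.

*FCS.* Correlations are Fisher-z transformed
(`z = 0.5·ln((1+r)/(1−r))`, with |r| = 1 clipped to 1 − 1e-7 so downstream
statistics stay finite) and FCS is the sum of z-values strictly above the
threshold, divided by V − 1 (the seed is excluded from both numerator and
denominator; using V instead would scale all maps by (V−1)/V).

## ROI connectivity

Sphere membership is voxel-center Euclidean distance ≤ radius; cube
membership bounds each |axis offset| by the half-width ("size" always means
half-width in mm). Overlaps resolve to the nearer center, ties to the lower
ROI index; a radius of 0 selects the single nearest voxel. Merging binary
masks assigns labels 1..k in input order and refuses overlapping masks with
the overlap count rather than applying silent precedence. ROI series are
unweighted means over in-mask member voxels; empty ROIs yield flagged NaN
rows. Partial correlation of a pair regresses each member on an intercept
plus the mean series of all *other* ROIs and correlates the residuals; it
requires more frames than ROIs and deliberately includes no trend columns
among the covariates (trends are assumed removed upstream). Connectivity
diagonals are stored as 0, keeping thresholded graphs self-loop free; the
upper-triangle flattening order is row-major i < j everywhere. ROI centers
are equal-weight means of member voxel world coordinates.

## Network analysis

Intensity thresholding keeps edges strictly above the value; sparsity
keeps the top ⌊s·N(N−1)/2⌋ edges by weight with ties broken in (i, j)
lexicographic order, so the edge count is a deterministic function of s and
N. Negative weights are discarded or absolute-valued before thresholding.
Weighted path lengths use 1/weight as edge distance (appropriate when
weights are correlation strengths); characteristic path length averages
finite distances only, and disconnected pairs contribute 0 to efficiency.
Betweenness is normalized by (N−1)(N−2)/2. The robustness measures are not
uniquely standardized in the literature, so each has one small function
with a documented choice: fault tolerance = mean over nodes of E₋ᵢ/E,
vulnerability = max over nodes of (E − E₋ᵢ)/E, and the resilience proxy is
the area under the largest-component-fraction curve under repeated removal
of the currently highest-degree node. Alternates can be swapped in without
touching anything else. Null models are degree-preserving double-edge
swaps (default 10 per edge, 100 nulls for small-worldness; tests use
smaller counts), fully seeded.

## Group statistics and meta-analysis

The voxel-wise GLM is solved in one matrix operation for all voxels; t is
the coefficient of interest over its standard error with df = n − p, and
p-values are two-sided by default (one-sided via a flag). Stouffer's
combiner sums z maps over √k; Fisher's sums −2·ln p against χ² with 2k df;
the fixed-effects combiner is inverse-variance weighting, and the mixed-
effects combiner adds the DerSimonian-Laird moment estimate of between-
study variance, floored at zero — chosen for its ubiquity; the estimator is
isolated and interchangeable. Worsley-Friston is the conjunction
(max p)^k; Nichols is the minimum-conjunction max p. Zero p-values are
clipped to the smallest positive double with a warning. FDR/FWER
corrections delegate to the standard step-up implementations and return
both reject flags and adjusted p-values.

## Synthetic data

The generator produces three kinds of ground-truth fixtures: phantoms
(baseline + per-region sinusoids, polynomial drifts, and white noise, with
noise drawn independently per voxel), motion traces (a seeded random walk
with injected step events), and atlases (disjoint connected blobs grown by
face-connected accretion). A single explicit integer seed determines every
output; no global random state is used. The phantoms deliberately omit
hemodynamic convolution, spatial autocorrelation of noise,
physiological-noise spectra, and scanner drift structure — passing tests
demonstrate algorithmic correctness on signals with known spectral and
spatial content, not performance on real BOLD data.

## Problem sizes and determinism

The test-suite and acceptance-script problem sizes are chosen so every
stage still exercises its full code path at desk scale: phantoms of
6³–10³ voxels with 100–200 frames, 200-voxel fixtures for the packed-vs-
dense connectivity comparison, graphs of up to 30 nodes with 200 random
instances for the all-pairs oracle, 2000 null simulations for t-test
calibration, and 3-subject batch runs for determinism checks. Batch
outputs are byte-identical across reruns and worker counts because
parallelism is across subjects only and each subject's computation is
deterministic.

## Known limitations

No slice-timing/realignment/normalization (the package starts from
spatially preprocessed images); no component- or ICA-based denoising; no
NIfTI-2/CIFTI; no modularity or network-based-statistic inference; the
first-level activation GLM and multi-group ANOVA are out of scope. ReHo's
tie handling (midranks without denominator correction) and the robustness
metric definitions are documented conventions, not universal standards.
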