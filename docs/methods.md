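# Methods

This note records the models behind each readout, the parameters that
matter, what the synthetic generators do and do not emulate, and the
numerical choices made where the procedure was genuinely open.

## Dual-channel puncta segmentation and the white fraction

Aggregates are detected per channel with a morphological white top-hat:
the image minus its opening with a disc structuring element, which
removes any structure the disc fits inside (flat background, smooth
gradients) and keeps bright features smaller than the disc. Radii are
given in µm and converted through the pixel calibration, rounded up to
at least 1 px (defaults: 10 µm green, 100 µm red, reflecting that the
red channel must tolerate larger, dimmer lysosomal accumulations). The
structuring element is skimage's disc decomposed into a sequence of
small footprints — roughly 40× faster at radius ≥ 50 px and within 0.1%
of the exact disc's amplitude on blob fields, which is far below the
threshold's discrimination scale.

The colour threshold (default 0.7) is applied to the top-hat output
normalized by the **raw frame's min–max intensity range**. Normalizing
by the filtered output's own range — the other available reading of a
"normalized-intensity threshold" — would amplify residual noise on a
featureless frame into a spurious mask; with the raw range as reference
a flat or gradient-only frame stays empty, and the behaviour on frames
containing puncta is essentially identical (the brightest punctum
dominates both ranges). The threshold remains invariant to adding a
constant to the image. Objects below `min_area_px` (default 4) are
removed; components use 8-connectivity.

The white mask is the pixel-wise intersection of the green and red
masks, and the white-area fraction divides its area by the red area
(0 with a warning when red is empty). For per-punctum statistics a red
object counts as white when ≥ 50% of its pixels are green-positive; the
area-based fraction is the primary readout. Every pipeline run asserts
white ⊆ green ∩ red and fraction ∈ [0, 1].

## Degradation rate, AUC, FRAP

The degradation rate is the negative unweighted-OLS slope of ln(values)
against time — deliberately the spreadsheet-SLOPE-on-log-values
estimator, exact on noiseless exponentials and invariant to scaling the
series (so percentages and fractions give the same rate). Because
neither a fit window nor zero handling is inherent to that recipe, the
defaults are: window from the first sample below 95% of the series
maximum (decay onset) to the last sample above the log floor, floor at
10⁻³ of the series maximum; excluded values are counted and logged, and
fewer than 3 usable points is an error. The reported goodness statistic
is the fraction of ln-variance explained.

A caveat worth stating: with N aggregates observed for duration T the
waiting-time sampling alone bounds the per-experiment precision of k̂ at
sd(k̂)/k ≈ 1/√(N(1−e^(−kT))) — about 7.4% for N = 200, k = 0.1 h⁻¹,
T = 24 h — and the log-OLS estimator sits near 9%. Single-movie rate
estimates at a few hundred aggregates therefore scatter by ~10% around
the truth even though the estimator is essentially unbiased (measured
end-to-end bias ≈ 2% across k ∈ {0.05, 0.1, 0.2} h⁻¹). Averaging
replicate movies, not tuning the fit, is the way to tighten it.

AUC is the trapezoidal integral over the observed time range (additive
over adjacent intervals; within 2% of a 10×-refined sampling for smooth
formation curves). FRAP traces are divided by the mean of the first
`n_prebleach` samples (error if that mean is non-positive); the readout
is scale-invariant and the normalized plateau of the noiseless
single-exponential model is i_post/i_pre + m·(1 − i_post/i_pre) for
mobile fraction m.

## SMLM pipeline

**Background.** A per-pixel running temporal median (odd window,
3 ≤ w ≤ n_frames) is subtracted and negatives clipped. The window must
be long relative to the on-time of any one emitter: if a cluster's
pixel is lit in close to half the frames the median absorbs signal into
the background estimate — the end-to-end test keeps ~0.2 emissions per
cluster per frame for this reason.

**Localization.** Local maxima above a threshold seed least-squares 2-D
Gaussian fits (amplitude, centre, width, offset) on a ±3σ window;
failed or out-of-window fits are discarded and counted. The
localization error is propagated from the fit covariance of the centre
and floored at 1 nm so rendering kernels stay well-defined for
noiseless fits.

**Rendering.** Each molecule contributes a Gaussian with s.d. equal to
its localization error, integrated exactly over each render pixel
(differences of the Gaussian CDF), so the kernel mass is 1 for any σ —
including σ below one render pixel, where point-sampling the density
would lose almost all mass. Total image mass equals the localization
count to 0.1%.

**Drift.** The table is split into temporal blocks of equal count, each
block rendered on a common grid, and block shifts estimated against the
first block by plain spatial cross-correlation with an upsampled
sub-pixel peak. Phase-normalized correlation is *not* used: whitening
amplifies the speckle of the disjoint molecule samples in each block
(measured error 0.65 vs 0.23 render pixels on dense fields). Each
localization has its own block's shift subtracted — piecewise-constant
over frames, which makes the correction idempotent for abrupt stage
jumps; smooth drift is followed by raising `n_blocks`.

**Local-density clustering.** Within one aggregate ROI, d̄ is the mean
nearest-neighbour distance, the density radius is r = 5·d̄ (multiplier
configurable), and D_i counts other molecules within the *closed* ball
of radius r (ties at exactly r count — deterministic and documented).
Molecules with D_i > 40 are cluster candidates; clusters are connected
components of candidates linked within r, kept at ≥ 3 members; cluster
area is the convex hull (degenerate hulls report no density). This is a
DBSCAN on the thresholded set with eps = r and min_samples = 1 followed
by a size filter, and is tested against sklearn's DBSCAN exactly that
way. Both d̄-scaling and counting make every quantity scale-equivariant:
rescaling coordinates leaves D_i, memberships and counts identical.

Two deliberate interpretations: (a) the published aggregate-inclusion
rule "< 100 localizations per aggregate" is taken as a typo for the
minimum an aggregate needs to support the statistic — the filter
defaults to ≥ 100 with both min and max configurable; (b) the density
threshold 40 is an acquisition-specific constant, exposed in config,
not a universal one — the D_i of a molecule in a pure Poisson cluster
is ≈ 6.25π ≈ 20 *independent of density* when r comes from the
cluster's own d̄, so exceeding 40 requires the mixture of dense clusters
with a sparse background that d̄ averages over. Fixtures that drop the
background entirely would sit below threshold regardless of how dense
their clusters are.

## Compaction profiles

Cross-sections are sampled by bilinear interpolation at ≥ 10 equally
spaced points (exact on affine images); placement is user-given
endpoints or a seeded uniform random chord within a mask. Each trace is
divided by its own mean (so per-aggregate normalized means are 1 within
10⁻¹²), pooled per condition, and binned into equal-width bins over the
shared range [0, max normalized value across conditions] (default 20
bins). The scalar spread statistic is the SD of the pooled normalized
values — the mean-normalized CV — chosen because the histogram alone
does not support cross-condition comparison; it is scale-invariant per
aggregate and strictly increasing in the generator CV.

## Synthetic generators: what they emulate and what they do not

All generators are deterministic given their seed.

*Time-lapse.* Aggregates are 2-D Gaussian blobs (default σ 3 µm,
amplitude 1000 photons ± 2%, background 100) on a jittered grid —
spacings always exceed twice the blob half-max radius, which real
fields do not guarantee. Conversion dual → red-only is one-way with
exponential waiting times (rate `k_deg`/h); partial acidification and
re-neutralization are not modelled. Fragmentation is a symmetric binary
split conserving footprint area within 1%, children inheriting the
parent's conversion clock (memoryless), so the expected white fraction
stays e^(−k_deg·t) with or without fragmentation. Pixel noise is
Poisson shot noise plus Gaussian read noise (sd 2); no vignetting,
focus drift, photobleaching or cell movement. Ground-truth white
fraction comes from noiseless half-maximum masks (or analytic blob
areas when rendering is skipped for large-N checks). Defaults:
1.5 µm/px, 240×240 px, 200 aggregates, 0.5 h frames for 24 h — sizes
chosen so a 20-seed end-to-end run stays within minutes.

*Localization fields.* Per labelled ROI, round(f·n) molecules are split
multinomially over Gaussian clusters (σ default 20 nm, truncated at
3σ), centres placed ≥ 3σ inside the footprint with pairwise separation
≥ 15·σ by default ("well-separated"); the rest is uniform on the
footprint. Localization error jitters every coordinate (truncated at
3.9σ so points stay within the 4×-error-dilated footprint). Frames are
uniform — no photophysics correlations, no repeated localizations of
one molecule.

*Raw movies.* Molecules emit in independent Bernoulli(blink) frames as
integrated-Gaussian PSF spots with Poisson noise; background is flat
plus optional ramp drift; stage drift is a recorded step between movie
halves. No multi-state blinking kinetics or bleaching.

*Profiles.* Zero-truncated normal with parent parameters
moment-matched (solved numerically) so the truncated distribution has
exactly the requested mean and CV — naive truncation would bias the CV
~8% low at CV 0.5. CV 0 returns a constant trace.

*FRAP.* Single-exponential recovery to the mobile plateau with optional
Gaussian noise; diffusion geometry is not modelled (the pipeline only
normalizes).

Passing tests on these generators demonstrates correctness of the
measurement code under known statistical structure — not robustness to
the segmentation-adversarial features of real data (overlapping
aggregates, uneven illumination, cell migration, emitter photophysics).

## Problem sizes and tolerances in the test suite

Oracle-equivalence tests (local density, nearest neighbour, component
labelling) are exact on ≤ 1000-point / ≤ 32² instances. Stochastic
recovery tests fix seed ranges: 20 seeds for end-to-end rate and
raw-movie cluster recovery, 100 for localization-field cluster
recovery, 50 per point of the density-vs-clustered-fraction monotonicity
grid. Drift tolerance is half a render pixel; rendering mass 10⁻³;
closed-form checks 10⁻⁶ or machine precision as stated in each test.
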