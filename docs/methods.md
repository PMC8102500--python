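# Methods

`nequant` quantifies four standard fluorescence-microscopy readouts of
nuclear-envelope (NE) biology — rim enrichment of an NE marker, protein
mobility by FRAP, two-channel colocalization with a rotation control, and
punctate foci counts — and ships a synthetic-image generator that produces
ground-truthed inputs for all of them, so every estimator can be validated
end to end without real microscopy data.

## Rim / nucleoplasm partition and the enrichment ratio

Nuclei are segmented from a DAPI-like channel by global thresholding
(Otsu by default, or a fixed value), hole filling, size filtering and
optional removal of border-touching objects. Labelling uses full
connectivity (8-connected in 2D, 26-connected in 3D); coordinates are
0-based (row, column) = (y, x) and distances Euclidean.

For each nucleus the Euclidean distance transform of its mask defines an
inner rim band — pixels at distance in `(rim_distance_px,
rim_distance_px + rim_width_px]` from the background — and a nucleoplasm
core (everything deeper). Defaults are `rim_distance_px = 0`,
`rim_width_px = 3`; both are configuration because the appropriate band
depends on magnification. The band is measured inward from the mask
boundary: NE markers sit at the inner face of the DAPI boundary at
typical confocal resolution. Objects whose core or band is empty at the
requested distances raise a degenerate-partition error and are excluded
and counted, never silently dropped.

The enrichment readout is the ratio of mean marker intensity over the rim
band to the mean over the core. Ratios strictly above 1.2 are classified
"Nuclear envelope enriched", anything else — including exactly 1.2 —
"diffuse in the nucleus"; the tie-breaking direction is a documented
convention. No background is subtracted by default (an optional constant
subtraction exists); multiplying the channel by a positive gain leaves
ratio and class unchanged, while adding a positive offset pulls the ratio
monotonically toward 1 — users comparing instruments should therefore
subtract the camera offset if it is large relative to signal. Condition
summaries aggregate per biological replicate first, so the reported
s.e.m. has n = replicates, not cells.

## FRAP

Time-lapse series are drift-corrected by translation-only registration
(phase cross-correlation against the first frame; integer shifts applied
cyclically, subpixel shifts by linear interpolation). A confidence check
warns when an aligned frame shares little structure with the reference.

Three ROI traces are extracted per frame (bleached region, whole
structure, camera-background region) and combined by double
normalization:

    N(t) = [(I_bleach(t) − I_bg(t)) / (I_bleach(t0) − I_bg(t0))]
         / [(I_total(t)  − I_bg(t)) / (I_total(t0)  − I_bg(t0))]

The reference t0 value is the mean over all pre-bleach frames by default
(configurable to the last pre-bleach frame); averaging reduces reference
noise without changing the identity N(t0) = 1 for a stationary
pre-bleach signal. The background trace is indexed per frame, not a
single constant. Frames whose corrected total intensity is non-positive
are flagged and excluded. N is invariant under affine intensity
rescaling applied to all three traces.

The recovery is fitted with a single-exponential reaction-limited model

    N(t) = D + M (1 − D) (1 − e^{−kt}),   t ≥ 0

with post-bleach depth D fixed to the first post-bleach value (or
co-fitted), mobile fraction M bounded to [0, 1] and rate k > 0
(half-time ln 2 / k). A single exponential is the simplest family
consistent with monotone saturating recovery and keeps (M, k)
identifiable; a flat trace sits in a degenerate small-k valley, which is
detected by the fitted recovery span (< 1e-4 over the observed window)
and reported as M = 0 with an undefined rate. Curves from several cells
are averaged pointwise on a common time base (linear resampling) with
s.e.m.

Two systematic limits of double normalization are worth knowing. First,
it treats all loss of total signal as acquisition bleaching; the signal
destroyed by the bleach pulse itself therefore inflates N by the factor
T_pre/T_post ≈ 1/(1 − f(1 − D/P)), where f is the bleached fraction of
the structure. With the ~2 µm bleach square of a typical acquisition
f ≈ 2–3% and the bias on M is below 0.03; validation runs use that
geometry. Second, the correction is exact only when acquisition
bleaching is spatially uniform, which the generator assumes.

The flow metric cross-checks mass balance: the background-corrected
summed gain of the bleached region is compared per frame against the
loss of the unbleached remainder, both corrected for acquisition
bleaching estimated from the log-linear trend of the total trace (the
correction is skipped when the fitted decay over the window is below
1e-9, so floating-point noise cannot masquerade as bleaching). For a
noise-free series without acquisition bleaching the residual is zero to
numerical precision, and the cumulative gain approaches
M (P − D) · n_bleach-pixels.

## Colocalization with the rotation null

The Pearson coefficient is computed over the pixels of a per-cell mask
(minimum 50 pixels, bounding its sampling variance). The null control
crops the second channel to the mask's bounding box, rotates it by a
multiple of 90° about the box center (no interpolation), recomposes it,
and correlates over the intersection of the original mask with the
rotated mask footprint; the intersection size is reported. Rotating by
360° restores the observed coefficient bit-exactly, and a radially
symmetric pattern centered on the box is rotation-invariant — both are
tested identities. The paired observed-vs-rotated comparison uses a
two-tailed paired t test; identical pairs yield the null result
(statistic 0, p = 1) rather than NaN.

## Foci counting

Chromocenters are segmented per nucleus in 3D: threshold at the 99.5th
percentile of the within-nucleus intensity histogram (whole-stack
percentile by flag), label 26-connected components, and keep components
with voxel volume in the inclusive window [7, 2000]. Inclusivity at both
bounds is a documented choice and tested at exactly 7 and 2000. Voxel
calibration factors (defaults 0.075, 0.075, 0.029, treated as opaque
scale factors) convert reported volumes only; the filter always acts on
raw voxel counts. Because the threshold is a percentile, counting is
invariant to global intensity rescaling — and, by the same token, the
bright fraction must stay below (100 − percentile)% of the thresholding
region or the threshold climbs into the foci themselves; the generator's
defaults respect this.

PLA foci are counted per cell in 2D after maximum projection of thin
z-stacks, with the same percentile/component/size-filter scheme (the
volume bounds act on pixel areas). The threshold can be taken over the
whole image instead of per cell, which is the right choice when some
cells carry no spots at all. Spots merged below the connectivity's
resolution count once. Counts are normalized as fold changes over a
control condition's mean count, so the control's mean fold is exactly 1.

## Statistics

Two-group comparisons default to Welch's unequal-variance t test (the
variance assumption is rarely defensible for cell-level readouts);
paired and equal-variance forms are available. Three or more groups use
one-way ANOVA followed by all pairwise t tests with Holm's step-down
adjustment, implemented directly (sort ascending, multiply the i-th by
m − i + 1, enforce monotonicity, cap at 1) and cross-checked in the
tests against both a definition-based oracle and statsmodels. The
Kruskal–Wallis test covers non-normal data; normality is never tested
automatically. Stars follow *P < 0.05, **P < 0.01, ***P < 0.001.

## The synthetic generator: what it emulates, and what it does not

The generator produces: elliptical nuclei with a distance-transform rim
shell whose rim:core intensity ratio is exactly the requested contrast;
FRAP series obeying S_b(t) = e^{−βt}[D + M(P − D)(1 − e^{−kt})] in the
bleached region with the unbleached remainder losing exactly what the
bleached region gains (signal conservation up to acquisition bleaching
e^{−βt}), plus optional whole-frame drift; channel pairs with exact
target Pearson correlation via the mixture ρ·z₁ + √(1−ρ²)·z₂ of
standardized smoothed fields followed by an affine (correlation-
preserving) rescale, with optional y-elongated anisotropy so the
rotation null has something to destroy; and 3D stacks with connected
bright components of exactly prescribed voxel volumes, grown
distance-ordered around random seeds with a one-voxel moat so separate
foci never merge. Noise is additive Gaussian, optionally Poisson at a
photon scale, always applied last so ground-truth masks stay exact.
Identical (spec, seed) pairs are bit-identical.

Deliberately absent: point-spread-function blur, 3D light propagation,
chromatin texture, intensity gradients, and touching nuclei. Passing the
validation suite therefore demonstrates correctness of the measurement
logic under the stated image model, not robustness to optical artifacts
of real confocal data; segmentation quality on real images remains the
user's responsibility.

Default study conditions used by the validation routines (see
`nequant.validation`): 200 nuclei per rim contrast in
{1.0, 1.2, 1.5, 2.0, 3.0} at signal-to-noise ratio 5; 50 FRAP series per
(M, k) pair over M ∈ {0.2, 0.5, 0.9} and k ∈ {0.01, 0.05, 0.2}/s with
300 post-bleach frames at 1 s intervals, 2% camera noise and acquisition
bleaching alternating 0 and 0.001 /s; 50 anisotropic correlation pairs
at ρ = 0.8; 100 random stacks up to 32³ voxels for the component oracle;
1000 null replicates for test-size calibration. Image fields are
64–128 px across — small enough for a desktop run, large enough that
every mask comfortably exceeds the minimum-pixel rules.

## Numerical choices

- Segmentation on an all-zero (or constant) image returns an empty mask
  rather than an error; non-finite pixels are an error.
- 16-bit TIFF export scales the data maximum to 65535 and records the
  scale and axis labels in the TIFF description for exact-to-quantization
  round-trip.
- Percentiles use NumPy's default (linear interpolation) definition.
- The recovery fit initializes k so that roughly one third of the
  observed window is a half-life, and bounds it away from 0 (1e-8).
- `holm_adjust` is permutation-invariant and agrees with the definition
  oracle to machine precision; ties are handled by stable sorting.

## Known limitations

- The rim band is anchored on whichever channel was segmented; anchoring
  on a dedicated NE-marker channel is supported by segmenting that
  channel instead, but mixed anchoring within one analysis is not.
- Touching nuclei are not split (no watershed); they merge into one
  object and should be excluded upstream by area/eccentricity filters.
- Registration is translation-only; rotational drift is out of scope.
- Diffusion-model FRAP (effective diffusion coefficients, bleach-profile
  deconvolution) is out of scope; the exponential model measures
  reaction-limited exchange only.
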