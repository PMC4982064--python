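# Methods

## Overview

`plateletquant` implements an automated morphometric analysis of two-channel
super-resolution platelet images: platelet segmentation from a tubulin
marginal-band channel, per-platelet counting of CD63-positive structures,
radial quantification of CD63 surface accumulation, and rank-based cohort
statistics. All image operators are pure functions on calibrated rasters
(`ImagePlane`: float64 pixels plus a pixel size in nm), so every stage is
individually testable against analytic or brute-force oracles.

## Platelet segmentation

The segmentation substrate is the pixelwise **sum** of the tubulin and CD63
channels (z-stacks are first maximum-intensity projected). The chain is:

1. **Rolling-ball background subtraction**, radius 20 px: the background is
   the grey-scale opening with a ball kernel (scikit-image's rolling-ball);
   output is clamped to `[0, input]`. Structures much smaller than the ball
   (marginal bands ~6 px wide, granules ~4 px) are preserved.
2. **Gaussian blur**, σ = 1.0 px (configurable): the smallest smoothing that
   suppresses single-pixel noise without affecting resolution. Boundary mode
   is edge replication, which conserves interior intensity to < 0.1 %.
3. **Minimum-error threshold** (Kittler–Illingworth): the grey level
   minimizing
   `J(t) = 1 + 2[P₁ln σ₁ + P₂ln σ₂] − 2[P₁ln P₁ + P₂ln P₂]`
   over a 256-bin histogram spanning `[min, max]` of the image (so float
   input is well defined). Pixels strictly above the threshold are
   foreground. Two numerical conventions matter and are fixed here: class
   variances are floored at 1/12 bin² (the quantization variance of one
   bin), making single-bin classes well defined; and because J is exactly
   flat across the empty gap of a well-separated histogram, ties are broken
   at the **middle of the minimal plateau**, i.e. a mid-gap threshold.
4. **Hole filling** (background 4-connected, foreground 8-connected — the
   standard duality), turning each marginal-band annulus into a solid disc.
5. **Watershed split** of touching platelets: the negated Euclidean distance
   transform is flooded from its regional maxima after h-maxima suppression
   (h = 1 px at platelet scale). No watershed lines are dropped: labels
   partition the foreground exactly.
6. **Filters**, applied per watershed fragment: area ≥ 2.0 µm², circularity
   `4π·area/perimeter² ≥ 0.7`. Perimeters use scikit-image's weighted
   boundary-step estimator; circularity tolerances in the tests are
   calibrated to it (a digital disc of radius 30 px measures ~0.93, an
   axis-aligned square π/4). Platelets touching the image border are
   discarded by default (their erosion and radial profiles are ill-defined);
   this is a policy choice, configurable.
7. **Interior demarcation**: each surviving mask is eroded by 3 px (3×3
   cross per iteration; ≈ 120 nm at 40-nm pixels) so that CD63 at the
   platelet surface is not attributed to the interior. The physical rim
   width is recorded in provenance. Platelets thinner than twice the erosion
   lose their interior and are flagged; they contribute no granule counts.

Record ids are assigned in raster order of centroids, making outputs
deterministic and reproducible byte for byte.

## Granule segmentation and counting

CD63 objects are segmented with **Tsai's moment-preserving threshold**: the
representative levels z₀ < z₁ and dark fraction p₀ preserving the first
three histogram moments are solved in closed form, and the threshold is the
grey level whose cumulative histogram is nearest p₀. Because bins span
`[min, max]`, the foreground partition is covariant under additive offsets.

Control images are thresholded from their own histogram; patient images use
a **batch reference threshold** — the arithmetic mean of the per-control-image
thresholds within the same acquisition batch ("same day"), never a value
derived from patient data (a test asserts the patient path cannot reach the
threshold selector). Before thresholding, the CD63 channel receives the same
rolling-ball (radius 20 px) and Gaussian (σ = 1 px) preprocessing as the
composite: transferring an *absolute* threshold between images is only
meaningful when their baselines are flattened, and the moment rule hugs the
background tail on sparse-foreground images, so unfiltered pixel noise would
otherwise seed spurious just-above-threshold objects. Both steps are
configurable (set radius None / σ 0 to disable).

Overlapping granules are split by the same distance-transform watershed but
with **h = 0.5 px**: granule distance transforms are only ~2–3 px tall, so
the platelet-scale h = 1 cannot separate legitimately distinct pairs.
Objects smaller than **0.01 µm²** are removed as background (a 150-nm
granule has area π·0.075² ≈ 0.018 µm², comfortably above the cut). Each
survivor is assigned to the platelet whose interior contains its centroid —
interiors are disjoint by construction, so assignment is single-valued;
granules in the eroded-away rim or outside all platelets stay unassigned and
are reported only as a summary counter. Zero-count platelets are retained as
data points. Raising either area floor is monotone non-increasing in counts.

## Radial CD63 distribution

Platelets passing a stricter circularity cut (> 0.85) are profiled in 20
concentric rings from the filled-mask centroid out to 1.3× the equivalent
radius (so the marginal band and just-outside-surface signal are captured; a
fixed ring count keeps profiles commensurable across platelet sizes). Ring
density is the **normalized integrated density**: sum of pixel values in the
ring divided by the ring's pixel count. The platelet **edge** is the ring of
maximum tubulin density (ties break outward — surface signal is the
phenotype of interest, and inward ties would truncate profiles). Radii are
normalized so the edge ring sits at exactly 1 (`(i + 0.5)/(edge + 0.5)`,
rings beyond the edge keep radius > 1) and densities by their per-platelet
maximum, making profiles independent of platelet size and brightness.

Subject curves are smoothed means of platelet curves on a common radius grid
(LOWESS with span 0.3 by default; smoothing spline and no smoothing are
options — only display depends on the smoother, no statistic does); group
curves are means of subject curves, keeping the subject as the statistical
unit. The scalar `surface_accumulation_index` is the mean normalized density
over normalized radius 0.8–1.0 divided by the mean below 0.8: 1 for a flat
profile, > 1 for surface accumulation.

## Cohort statistics

Per-platelet counts are Poisson-like, so comparisons are rank-based. The
Kruskal–Wallis H uses the standard tie correction with a χ² p-value at
k − 1 degrees of freedom (all-identical data yield H = 0, p = 1). The
"multiple comparison" is **Dunn's test**: pairwise z-statistics on pooled
mean ranks with the tie-corrected variance, Bonferroni-controlled over all
unordered subject pairs at α = 0.01 ("99 % confidence"); under a shared null
this is conservative (measured family-wise error ~0.002 at nominal 0.01).
Group summaries report the mean and SD of *subject mean* counts — the
dispersion across individuals, which is the clinically quoted number.
`sample_size_estimate` is a reporting utility only: a one-sample t-test
power calculation (statsmodels) for the platelets-per-sample needed to
detect the control–patient mean difference against the control SD.

## Synthetic data model

The generator emulates the statistical structure the analysis assumes, with
defaults fixed at the study conditions:

| parameter | default | rationale |
|---|---|---|
| pixel size | 40 nm | SIM-scale sampling |
| platelet diameter | U(2, 5) µm | reported platelet size range |
| marginal-band width | 250 nm | band areas then span ~1.4–3.7 µm², overlapping the measured 2.3–3.1 µm² |
| granule diameter | 150 nm | dense-granule scale |
| counts per platelet | Poisson, mean 6.8 (control) / 2.4 (patient) | observed CD63 group means; negative-binomial overdispersion optional |
| granule min separation | 300 nm (centre-to-centre) | twice the granule diameter, resolvable at SIM resolution |
| surface fraction | 0 (control), ~0.6 (HPS-like) | fraction of granules placed in the 0.9–1.05 R rim band |
| PSF σ | 60 nm | ~120-nm SIM resolution, granules stay resolvable |
| background | quadratic bowl, amplitude 10 | uneven illumination |
| noise | Gaussian, SD 5 (amplitudes 120/150) | high-SNR super-resolution data |

Platelet discs are placed without overlap (plus optional deliberately
overlapping "touching pairs" at 0.75 of the summed radii); interior granules
are area-uniform within 0.85 R, surface-biased granules area-uniform in the
0.9–1.05 R rim. Debris blobs (radius 3–8 px) fall below the 2.0-µm² filter.
Ground truth (masks, centroids, counts, surface flags) is recorded from the
pre-blur geometry, so imaging noise never touches it, and everything is a
pure function of the seed.

What the generator does **not** model: SIM reconstruction artifacts and
patterned-illumination physics, 3-D optical sectioning (z-stacks are
constant-plane), intensity heterogeneity between granules, platelet shape
irregularity (discs only), and spatially correlated noise. Passing tests
therefore demonstrate correctness of the *analysis chain* under the stated
statistical structure, not robustness to every property of real SIM data.

## Problem sizes used in the test suite

The validation studies run at desk scale, chosen once: ground-truth recovery
uses 50 fields of 384² px with 4 platelets each (200 platelets; measured
97 % exact per-platelet counts, mean absolute error 0.04); surface-
accumulation detection uses 50 paired batches of 40 control + 40
surface-biased single-platelet crops profiled at ground-truth geometry
(median rank-sum p ≈ 10⁻⁶); null calibration uses 500 simulated
10-subject × 281-platelet cohorts; cohort discrimination uses the full
7 × 281 vs 3 × 281 design.

## Known limitations

- A global threshold plus a 0.01-µm² floor occasionally admits a noise or
  halo cluster as a granule (~3 % of platelets gain a spurious count at the
  default noise level); counts are reported as segmented, not corrected.
- Granule pairs closer than ~300 nm centre-to-centre may merge; the
  watershed h trades splitting power against over-segmentation.
- Circularity depends on the perimeter estimator; values are comparable
  within this package but not bit-identical to other tools.
- Patient images in a batch with no readable control images cannot be
  thresholded in reference mode and are reported as per-image errors.
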