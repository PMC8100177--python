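# Methods

This note documents the models and numerical choices behind `rnflgray`:
a pipeline that measures the peripapillary retinal nerve fiber layer's
(pRNFL) grayscale value — the mean 8-bit reflectivity of the layer on a
circular SD-OCT B-scan — together with sectoral thickness, and analyses
its determinants in a normative cohort.

## The measurement model

A circular peripapillary scan samples 1024 A-scans on a 3.46 mm circle
around the optic disc and unrolls them into a B-scan (rows = depth at
5 µm/pixel, columns = angle). Column `c` maps to the angle
`360·c/N` degrees for right eyes, with 0° at the temporal horizontal
meridian and angles increasing through superior; left-eye scans are
mirrored into the same frame (`angle = (360 − 360·c/N) mod 360`), so
"temporal" is anatomically temporal for both lateralities. Six sectors
partition the circle: temporal [315°, 45°) and nasal [135°, 225°) span
90°, the four oblique sectors 45° each; intervals are half-open, so a
boundary angle belongs to the sector it opens.

Boundary traces live on the half-integer lattice: a value `r − 0.5`
separates pixel row `r − 1` from row `r`, and a layer's pixels in a
column are the rows in `[ceil(upper), ceil(lower))`. This convention
(a) gives every pixel to exactly one layer, and (b) makes the band
robust to sub-half-pixel segmentation jitter — a trace that wobbles by
±0.4 px around a true edge never flips a pixel in or out of the band,
which would otherwise bias grayscale means asymmetrically (the pixel
gained at one side of the band is darker than the one lost at the
other).

Grayscale values are pixel-weighted: the grayscale of a region is the
plain mean of its pixels, so the 360° average equals the
pixel-count-weighted mean of the six sector values exactly (closure).
A `column_weighted` dialect (mean of per-column band means) is provided
for sensitivity analysis; the two differ where thickness varies across
a region. Thickness is the per-column boundary distance times the
axial scale, averaged over columns. The overall averages are taken
over all 1024 columns, not over the six sector values (temporal and
nasal would otherwise be under-weighted).

## Synthetic cohorts

No patient images accompany this package; a generative model supplies
study-condition cohorts with known truth.

Covariates are independent truncated normals (sex is Bernoulli), with
defaults describing a healthy adult population: age 44.63 ± 16.43 y on
[18, 80], spherical equivalent −0.78 ± 1.85 D, BCVA 0.006 ± 0.075
logMAR, axial length 23.73 ± 1.13 mm on [20.7, 26.0], IOP
14.43 ± 2.87 mmHg, visual-field MD −1.01 ± 1.37 dB, scan quality
(ImageQ) 55.4 ± 4.35 on [45, 65], 49.4% male. RPE grayscale is
sampled at 170 ± 8 (no published moments exist for it; only its slope
matters downstream, and 170 is a typical bright-band value with
headroom below the 8-bit ceiling).

The eye's true average grayscale follows a linear determinant model

    avg_gray = β₀ + β_age·age + β_al·AL + β_rpe·RPE + β_q·ImageQ + ε,

with default effects β_age = −0.053, β_al = −0.664, β_rpe = 0.372,
β_q = 0.658 gray levels per covariate unit; sex, SE, BCVA, IOP and MD
are sampled but carry zero true effect by default (configurable). The
intercept is solved so the cohort expectation equals the normative
target 164.82, using truncated-covariate means; Var(ε) is solved so the
cohort SD equals 5.69, and a configuration whose effects explain more
variance than that budget is rejected at construction. Sector grayscale
truths are the eye average plus fixed offsets (+0.38 T, +0.79 IT,
+0.95 IN, −1.56 N, +0.27 SN, +0.27 ST), reproducing the nasal
depression of normative data. Sector thickness truths are the
normative sector profile (84.77 T, 144.34 IT, 123.74 IN, 79.59 N,
124.30 SN, 132.32 ST µm; 360° mean 106.68 µm) scaled per eye by a
truncated-normal average thickness (SD 8.89 µm, bounds 60–160 µm).

Because covariates are sampled independently (no correlation structure
is published for this population), univariable standardized
coefficients in synthetic cohorts will not match a real cohort's —
only the multivariable effects are calibrated quantities. Sector
grayscale SDs also inherit the eye-average SD rather than the larger
per-sector SDs of real data, so within-eye sector contrasts are
stronger here than in patients.

## Rendering

Each eye becomes a 480 × 1024 8-bit raster (default height; 5 µm/pixel)
with four zones: vitreous/choroid background (reflectivity 25), the
pRNFL band under a gently undulating ILM (row ≈ 120 ± 8 px), an inner
retinal zone (reflectivity 90, 180 µm thick), and a 25 µm RPE band
(reflectivity = the eye's RPE truth). The pRNFL thickness profile is a
circularly Gaussian-smoothed step over the six sector targets (σ = 10°)
plus a von-Mises double-hump ripple centred on the superior and
inferior meridians (the classic ISNT profile); a smoothed correction
field, iterated to convergence, drives every sector's mean onto its
target exactly while keeping the geometry free of multi-pixel steps at
sector borders. Per-column pRNFL reflectivity is constant within a
sector and equals the sector grayscale truth; the ground-truth sidecar
records exact boundaries (half-integer) and reflectivities.

Speckle is multiplicative unit-mean gamma noise (shape 60 by default).
Unit mean preserves the grayscale truth under averaging; shape 60
(≈13% coefficient of variation) represents a device-processed,
frame-averaged scan — raw OCT speckle is far heavier-tailed, but a
heavier law would clip against the 8-bit ceiling and make "the mean
reflectivity of the layer" ill-defined as a truth. Pixels are rounded
and clipped to [0, 255].

## Scan quality: degradation and proxy

The emulated device exports a quality factor with each scan, like its
clinical counterparts; the degradation operator and the pixel-based
proxy are calibrated as a pair.

Degradation injects additive zero-mean Gaussian noise with

    sd(q) = 3.24 · sqrt(exp(2·1.5·λ) − 1),   λ = (70 − q) / 30,

on the knob range [40, 70]; at q = 70 the image is returned
bit-identical. 3.24 is the measured background speckle SD of a
default-rendered scan, so the total background spread is 3.24·e^{1.5λ}
(variances add) and falls exponentially with quality. The operator is
deliberately mean-preserving on tissue: the effect of scan quality on
measured grayscale is represented *generatively* (the β_q slope), so
the imaging operator must not add a second, uncontrolled quality→gray
pathway. For the same reason no contrast attenuation is applied —
attenuating pixel values toward a pivot would shift layer means by
several gray levels per quality unit and destroy the calibrated effect
structure.

The proxy statistic is `s = ln(150 / spread)`, where `spread` is the
SD of the pixels at or below the image median (the background
half-sample; layers occupy a minority of rows) and 150 is a fixed
nominal tissue-to-background contrast. The numerator is deliberately
*not* a per-image bright percentile: a per-image numerator would leak
the eye's own RPE/RNFL reflectivity into the quality estimate and
cross-contaminate the determinant analysis. The proxy is the affine
map `q̂ = −18.38 + 20.69·s`, clipped to [0, 70], with the two constants
fitted once by least squares on default-rendered scans degraded over a
40–70 knob grid (RMS recovery error ≈ 0.7 units, worst ≈ 2 at the range
ends). A noise-free scan saturates at 70; a layer-free pure-noise
raster falls far below the 45-unit usability gate.

## Segmentation

Four boundaries are traced by sequential dynamic-programming
minimum-cost paths on signed vertical-gradient images (Gaussian
pre-smoothing σ = 1 px axially, 3 columns laterally, wrapped
horizontally because the scan is a closed circle):

1. ILM — the strongest dark→bright edge;
2. RPE outer — the strongest bright→dark edge at least 10 px below the
   ILM;
3. pRNFL posterior — bright→dark, confined between 1 and 2;
4. RPE inner — dark→bright, confined between 3 and 2.

The band confinement makes the anatomical ordering hold by
construction. The DP transition limit is 3 rows/column. To keep the
result exactly equivariant under horizontal mirroring, the path is
selected from the *direction-free* quantity
`total(r, c) = fwd(r, c) + bwd(r, c) − cost(r, c)` (the best full-path
cost through each cell), taking the per-column argmin with ties broken
toward the smaller row; a one-directional backtrace would break mirror
symmetry on ties. Integer edge rows are refined to sub-pixel precision
by a quadratic fit of the gradient peak, clipped to ±0.5 px and applied
on the half-integer lattice. A trace whose mean along-path gradient
falls below 6 gray/px raises a segmentation failure (featureless or
constant images) — a hard error distinct from QC flagging.

The misidentification screen applies three deterministic rules, any of
which flags the scan: median pRNFL thickness outside 30–250 µm; mean
absolute second difference of any trace above 1.5 px; pRNFL band mean
intensity not at least 5 gray levels above the vitreous mean. The
thresholds are configuration values — the human inspection they stand
in for cannot be reproduced, only approximated by explicit rules.

## Statistics

Age-group tables use bins {18–29, …, 60–69, ≥70} with sample SDs and a
Total row. Sector contrasts are paired t-tests on within-eye
differences over all 15 sector pairs, Bonferroni-adjusted
(`p' = min(1, 15p)`); the paired design follows from each eye
contributing all six sectors. The univariable screen fits one simple
OLS per covariate and reports the standardized coefficient (equal to
Pearson r in simple regression); covariates with p < 0.05 carry
forward to the multivariable OLS, into which axial length is forced
regardless — eye size shifts peripapillary anatomy even when its
marginal signal is weak. Fits are delegated to statsmodels.
Inter-observer agreement uses ICC(2,1) — two-way random effects,
absolute agreement, single measurement — computed from the two-way
ANOVA mean squares (formula in the docstring) and cross-checked against
pingouin in the tests.

In the pipeline's determinant regression the ImageQ covariate is the
device-exported value accompanying each scan (as in clinical datasets);
the pixel proxy serves images that arrive without one, and the
quality gate (exclude at ≤ 45).

## Study sizes and reference runs

The acceptance runner (`scripts/acceptance.py`) executes two studies:
a single 397-eye cohort through the full image pipeline (headline
normative means), and a 50-replicate × 100-eye parameter-recovery
simulation whose replicate-mean slopes estimate the multivariable
effects; 100-eye replicates keep the full design refittable while
full-size replicates would add nothing but runtime. All seeds
derive from one master seed via `SeedSequence` substreams; the studies
are pure functions of (seed, sizes).

## Known limitations

* Layer reflectivity is piecewise constant per sector plus speckle; real
  scans show axial reflectivity gradients, vessel shadows and motion
  artifacts, none of which are rendered (motion artifacts exist only as
  a manual exclusion flag).
* The segmentation is this package's own transparent stand-in for an
  unpublished device-era tool, not a reproduction of it.
* The quality proxy is calibrated on this renderer's background
  statistics; on real scans its affine constants would need refitting.
* Passing the end-to-end tests shows the pipeline recovers the
  *configured* generative structure through imaging, segmentation and
  regression — it cannot validate the generative model against real
  patients.
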