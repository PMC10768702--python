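# Methods

## Display model and colorimetry

Images are treated as gamma-encoded RGB as a typical uncalibrated display
renders them: a pure power-law transfer function `I = v^γ` with γ = 2.2
(configurable), deliberately not the piecewise IEC sRGB curve — the two
differ by up to ~0.005 in linear intensity at dark values, and the power
law matches the display model under which the analysis is defined.
Linear RGB maps to CIE XYZ through the IEC 61966-2-1 primary
chromaticities with the 3×3 matrix re-normalized so that RGB = (1, 1, 1)
lands exactly on the configured white point with Y = 1. The white point
defaults to D65 but is a free parameter (named D-series points are placed
on the CIE daylight locus at `nn × 100 K`; the CIE daylight polynomials
are extrapolated below 4000 K for labels like D30), because the assumed
display white is an assumption about viewing conditions, not a
measurement.

CIELAB follows the standard formulae including the linear segment below
the cube-root breakpoint; negative tristimulus values (possible for
out-of-gamut inputs) are clamped to zero with a logged warning. Polar
coordinates: chroma `C* = √(a*² + b*²)`, hue `atan2(b*, a*)` in [0, 360)
with hue defined as 0 at zero chroma (and excluded from hue statistics),
and saturation `C*/L*` with saturation defined as 0 at L* = 0 to avoid
division blow-up on black pixels. CIEDE2000 is implemented in full
(a* rescaling, hue rotation term, S_L/S_C/S_H weights, kL = kC = kH = 1)
and is verified in tests against an independent implementation to 1e−4.

### Color-matching functions

No measured CIE 1931 2° observer table is bundled; the color-matching
functions are evaluated from the multi-lobe asymmetric-Gaussian analytic
fit of Wyman, Sloan & Shirley (2013), accurate to about one percent of
peak. Every spectral computation in the package (Planckian locus, primary
basis fitting, round-trip checks) uses these same functions, so CCT/D_uv
estimation is internally consistent; absolute CCTs carry the
approximation's error (D65 evaluates to ≈ 6499 K against the canonical
6504 K). Tests that pin absolute CCT values therefore use a ±150 K band;
tests of locus recovery, where oracle and implementation share the
observer, are tight (10 K, |D_uv| < 1e−5).

### CCT and D_uv

CCT is the temperature of the black-body radiator with the nearest
chromaticity in CIE 1960 (u, v). The Planckian locus is tabulated at 1 K
resolution over 1000–25000 K (built lazily, once per process) and queried
through a k-d tree; the nearest table entry is refined by a local
parabola on squared distances, and the locus point and tangent at the
refined temperature are linearly interpolated from the table (the
interpolation error is orders of magnitude below the D_uv scale). D_uv is
the perpendicular offset signed by the cross product of the locus tangent
with the offset vector, oriented so the +v (greenish) side is positive.
Chromaticities farther than `duv_cap` (default 0.05) from the locus, and
pixels with luminance below 1e−4 (no usable chromaticity), get NaN CCT.
Because the per-pixel locus search is the cost hot spot, per-pixel CCT
maps are computed on a strided grid capped at 1e5 pixels by default
(`cct_pixel_cap`; an explicit `cct_stride` overrides it).

## Photoreceptor activations

A pixel's display spectrum is modeled as `S = r·P_R + g·P_G + b·P_B`.
The bundled primary spectra are smooth nonnegative curves fitted by
heavily weighted ridge NNLS over Gaussian bumps so each primary's
spectrum reproduces that primary's XYZ almost exactly; the
spectrum → XYZ → RGB round trip over the RGB cube corners errs below 1e−9
(tolerance 1e−3). The sensitivity curves bundled as
`*_synthetic.csv` are analytic stand-ins — asymmetric Gaussians at the
canonical peaks (L 570, M 543, S 442, rod 507, melanopsin 490 nm), unit
peak — not the measured Stockman–Sharpe / scotopic / melanopic tables;
they reproduce band positions and overlaps but not exact shapes, and can
be replaced by measured 2-column CSVs. Activations are reported in
arbitrary linear units normalized so the white pixel (1, 1, 1) activates
each receptor at 1; since the two linear steps collapse, activations are
evaluated as a precomputed 5×3 matrix on linear RGB, with the integral
path retained for verification. Activations are not normalized further
before averaging per image.

## The 30 image statistics

Fixed canonical order (names stable across versions):
luminance (CIE Y) mean/variance/skewness; mean luma (Rec. 709 weights
0.2126/0.7152/0.0722 on encoded values — configurable, since the
weighting standard is a convention); mean L/M/S-cone, rod, and melanopic
activations; RMS contrast of luminance and of the linear blue channel;
mean saturation; mean and min chroma; mean/min/SD of b*; Hasler–Süsstrunk
colorfulness (`√(σ_rg² + σ_yb²) + 0.3·√(μ_rg² + μ_yb²)` on linear
opponent channels); mean-image CCT; CCT range; mired (1e6/CCT) range;
saturation range; luminance-weighted CCT `Σ CCT·Y / Σ Y`; ΔE00 between
the brightest and darkest pixels (ties break to the first raster-scan
position); Pearson correlations of Y with b*, saturation, and chroma; and
the mean absolute pixel-wise distances between Y and each of those three
channels after per-image min–max normalization (which puts luminance and
chromatic channels on a common scale).

Conventions for degenerate inputs: moments are population moments with
skewness g1 = m3/m2^1.5, defined as 0 on constant maps; RMS contrast is
the coefficient of variation σ/μ (scale-free) and undefined for
non-positive means; correlations are 0 by convention when either channel
is constant; constant channels min–max normalize to all zeros; any
statistic that cannot be computed is NaN with a logged reason, never
silently dropped (NaNs are mean-imputed, with a logged count, before
PCA).

Membership notes: maximum and minimum luminance are not in the canonical
vector. For gamma-encoded reproductions of paintings they are
near-degenerate (≈ 1 and ≈ 0 for almost every image) and carry no
distributional information beyond the retained moments; b* likewise
enters through its mean, minimum, and SD only. "Mean-image CCT" is the
CCT of the mean image chromaticity (mean u, v over defined pixels), not
the mean of per-pixel CCTs, which would overweight noisy near-neutral
pixels.

## Airlight estimation

The dark channel — the patch-wise minimum (default 15×15) of the
channel-wise minimum — is high only where haze fills all three channels.
Pixels in its top quantile (default top 0.1%) are candidate airlight;
their 8-connected clusters are ranked by ascending-mean-luminance rank
minus ascending-mean-saturation rank (bright and achromatic wins; ties
break to the larger cluster, then the lower label), and the winning
cluster's mean linear RGB is the airlight, from which chromaticity and
CCT/D_uv follow. An all-black image yields a flagged, undefined estimate.

## Rating scales and scores

Categories in scored chronological order: sunrise(1), morning(2),
noon(3), afternoon(4), sunset(5), evening(6), night(7) — sunset is
deliberately placed before evening, preserving the scale's published
ordering. The 4-point merged scale scores sunrise/morning 1,
noon/afternoon 3, evening/sunset 5, night 7; the binary scale scores
morning 0 and evening 1. Per image we report the mean score, the
normalized mean (mean ÷ 7 for the 7-valued scales; the regression
response), per-category proportions (summing to 1), and the categorical
score: the mode of the *scores* (so categories merged by a scale pool
their counts), represented by the earliest chronological category
carrying the modal score; ties between modal scores break to the lower
(earlier) score and are flagged. Observers scoring below 80% correct on
designated catch images are removed before analysis; observers with no
catch trials are retained with a warning. Binary-scale images classify as
morning below a 0.5 threshold and evening above it, with exact-threshold
images flagged as ties and excluded from counts.

## PCA and model selection

PCA operates on z-scored statistics (sample SD; correlation-matrix PCA),
chosen because the 30 statistics carry heterogeneous units (kelvin,
unitless ratios, CIELAB units). Constant columns are dropped with a
warning. Components with eigenvalues greater than 1 (Kaiser criterion)
are retained. Since component signs are arbitrary, they are oriented
deterministically: mean luminance loads negatively on PC1 and mean
saturation negatively on PC2 (when present); every other component's
largest-magnitude loading is made positive.

Candidate regressions are the nested OLS fits on PC1; PC1+PC2; …, each
scored by `AIC = n·ln(RSS/n) + 2k` with k = number of predictors + 1
(the intercept; additive constants cancel in ΔAIC) and by Akaike weights
`exp(−ΔAIC/2)` normalized over the candidate set. Selection follows the
forward stepwise rule: components are added in order only while the AIC
strictly improves, stopping at the first non-improving addition. With
components ordered by explained variance the AIC profile is almost always
single-dipped, making this the minimum-AIC (maximum-weight) candidate;
the stepwise rule additionally keeps the expected false-inclusion rate of
trailing noise components below ~3%, where an unconditional minimum over
all candidates admits a noise component in roughly 8% of fits. The
published two-component model (intercept 0.583, coefficients 0.034 and
0.017 on PC1 and PC2, on the normalized 4-point response) is shipped as a
frozen JSON asset.

Per-category covariance ellipses are centered on the category mean with
axes along the covariance eigenvectors and semi-axes
`√(eigenvalue · χ²₂(coverage))`. The χ² quantile makes the *bivariate
region* enclose the target fraction of points (default 68%); a "one
standard deviation" ellipse would cover only ~39% of a bivariate normal
cloud, so the coverage target is taken as the defining property.

## Synthetic scenes and observers

A scene is a vertical sky gradient (whitened zenith toward the
illuminant chromaticity at the horizon, placed at 55% of image height),
a smooth-noise ground texture lit by the illuminant at the requested mean
luminance and contrast, an optional sun disk, and haze composited as
`I = J·t + A·(1−t)`. The illuminant is the Planckian-locus color at the
requested CCT displaced by a signed D_uv along the locus normal (default
+0.003, the slight greenish shift typical of landscape imagery); the
airlight A is the locus color at its own CCT. Depth is linear in image
row (1 at the top, 0.25 at the bottom: sky far, ground near) and
transmission is `t = (1 − haze_density)^(3·depth)`, so density 0 is
haze-free and density 1 collapses the image to the airlight color
everywhere. Scenes are encoded with the same power law the analysis
decodes with.

A study interpolates scene parameters between a morning pole
(7500 K illuminant, mean luminance 0.60, contrast 0.50, haze 0.45,
8000 K airlight) and an evening pole (3000 K, 0.18, 0.12, 0.10, 4000 K)
along latent scores evenly spaced over [0, 1] — bright/cool/contrasty/
hazier mornings versus dim/warm/flat evenings, the direction real
terrestrial illumination moves with solar elevation and the diurnal
humidity cycle. Observers respond with the category whose scale score is
nearest to `divisor · (latent + N(0, noise_sd))`, clipped to the scale
range; Gaussian noise on the latent score before quantization produces
the unimodal-to-bimodal rating spreads seen in human data as noise grows.
All randomness flows through one explicitly passed seeded generator; no
global state.

What the generator does *not* emulate: real paintings' pigment gamuts,
spatial composition, varnish yellowing, artist-specific palettes, sun
position cues, or observer response biases beyond symmetric Gaussian
noise. Passing end-to-end tests therefore demonstrates that the pipeline
recovers a latent illumination axis when one exists — not that real
paintings carry one; that claim needs real image sets and ratings.

## Problem sizes and defaults

Synthetic end-to-end checks use 96×128 (or 64×96) scenes, studies of
10–100 images with 8–20 observers and rating noise SD 0.1, and 20–200
seeded replicates, sizes at which every distributional property under
test is stable. Analysis of real images standardizes to 1,000 px on the
longer side (area-averaged downsampling only; smaller images pass
through unchanged) — at that size the default CCT pixel cap implies a
stride of 3.

## Known limitations

- Approximate observer and synthetic sensitivity curves (above): absolute
  colorimetric values are good to roughly one percent; rankings and
  correlations — everything the perception model consumes — are
  insensitive to this at the tested tolerances.
- CCT is reported even for chromaticities up to D_uv 0.05 from the locus;
  interpreting CCT beyond ~0.02 is conventional at best.
- The airlight estimator assumes haze is the brightest low-saturation
  structure; scenes with bright achromatic non-sky objects can fool it.
- No chromatic adaptation transform beyond white-point re-normalization,
  no ICC handling, no hypothesis tests on human data (out of scope).
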