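# Methods

This note documents the models behind `leaflux`, the parameters that
matter, the numerical conventions, and what the synthetic experiments do
and do not show about real aerial imagery.

## Forward model: scene, illumination, camera

The simulator generates the ground truth the pipeline tries to recover.

**Reflectance scene.** An H × W × 3 map of surface reflectance in percent
(0–100). Soil is a constant base — (24, 18, 12) % in R, G, B, dry-soil
ordering — with Gaussian texture (sd 0.5 %). Each of P plants is a disk of
canopy (default radius 14 px) whose reflectance is affine in the plant's
standardized chlorophyll `z`:

    ρ_R = 12 − 3 z,   ρ_G = 22 − 2 z,   ρ_B = 6 − 0.5 z   (percent)

with per-pixel texture (sd 0.3 %) and clipping to [0.5, 100]. Chlorophyll
is drawn per plant from N(50, 5²) (arbitrary units); `z` standardizes by
those nominal population parameters (not the sample moments) so a
single-plant field is well defined and the link is identical across
fields. Red darkens fastest with chlorophyll, which is what makes
greenness indices informative. Four grey panels (3.5, 20, 80, 84.5 %
nominal; spectrally flat, noise-free) sit in a strip at the top of the
frame; plants occupy three horizontal plot strips below, four plants per
plot in the default 12-plant design.

**Illumination.** Multiplicative: per-channel spectral gain ℓ times a
scalar spatial field F(x, y) ∈ (0, 1].

* *sunny*: ℓ = (1, 1, 1), F ≡ 1.
* *overcast*: ℓ = 0.45 · (0.9, 1.0, 1.1), F ≡ 1 — dimmer overall and
  blue-shifted, since short wavelengths scatter more under cloud.
* *variable*: sunny ℓ with F obtained by Gaussian low-pass filtering white
  noise at σ = 0.25 · min(H, W) and mapping affinely to [0.3, 1]; the
  resulting correlation length is a sizeable fraction of the frame,
  emulating smooth drifting cloud shadow. Shadow is also spectrally
  selective — a shadowed pixel is lit by blue-rich diffuse skylight — so
  each pixel is additionally tinted toward (0.9, 1.0, 1.1) linearly in its
  shadow depth (1 − F). `shadow_tint=None` gives a purely neutral field.

The smooth-field model is an assumption of this package, recorded in
configuration; sharp sun/shadow boundaries are approximated by steep but
smooth gradients.

**Camera.** 8-bit, with response deliberately chosen as the exact inverse
of the empirical-line exponential family:

    DN = clip(round(ln(e / a) / b), 0, 255),     e(DN) = a · exp(b · DN)

per channel, with a = (1.35, 0.877, 0.817) (percent units) and
b = (0.016, 0.017, 0.018) (per DN) — coefficients of a calibrated consumer
sensor under clear sky. Using the exact inverse isolates pipeline
correctness from model mismatch: ELM recovery is then testable to
quantization precision. Effective radiance below 10⁻³ % is clamped before
the log (guards −∞); optional Gaussian DN noise is off by default. Note
that at unit gain the two brightest panels (80, 84.5 %) saturate — the
84.5 % panel maps to an unclipped DN of 259 — which exercises the
saturated-panel exclusion path.

**SPAD.** The meter reading is affine in chlorophyll plus noise:
`spad = 19.25 + 0.56 · chl + N(0, 1.077²)`. With chl ~ N(50, 5²) the
population mean is 47.25 and the std exactly 3.00 SPAD units, the target
survey moments (CV 6.35 %).

**GSD.** `gsd(altitude, sensor_width, focal, width_px)` returns
centimetres per pixel; the default field geometry uses 0.0068 m/px, the
low-altitude (25 m) survey scale, making the 0.2 m plant buffer 29 px.

## Radiometric conventions and ELM

Two dimensionless value conventions for 8-bit data: *scaling* (DN/255) and
*normalization* (channel divided by channel sum — chromaticity, invariant
to per-pixel intensity; the all-zero triplet maps to (⅓, ⅓, ⅓), the grey
limit). Reflectance is carried in percent throughout, matching panel
nominals.

ELM fits `ln ρ = ln a + b · DN` per channel by ordinary least squares —
closed-form and deterministic — on the mean panel DNs, excluding any
panel-channel with ≥ 1 % of pixels at the DN rails (0 or 255). Goodness of
fit is reported on both the reflectance scale (primary) and the log scale.
ELM is applied only to uniform-illumination frames: under a varying field
the corrected reflectance is wrong by exactly F(x, y), a property the test
suite asserts.

## Retinex

Single-scale Retinex is `log(S + ε) − log(G_σ * S + ε)` with a unit-sum
Gaussian surround (kernel truncated at 3σ, reflect boundaries so borders
are not darkened); multi-scale Retinex is a weighted sum over scales with
weights summing to one. The automated configuration uses three scales
(0.01, 0.10, 0.30) · min(H, W) with equal weights — a deterministic,
size-proportional rule covering fine texture through field-scale
gradients — and ε = 10⁻⁶ on the [0, 1] scale (below the 1/255 quantization
resolution). With ε = 0 the decomposition is exactly invariant to global
gain.

**Output mapping.** The log-domain output is unbounded and must be mapped
to [0, 1]. Three modes are provided:

* `fixed` (default): `0.5 + x / (2 · log_span)` with log_span = 5, clipped.
  The map is image-independent: a log-ratio of 0 (pixel equals its
  surround) lands at 0.5 in every frame, so corrected images from
  different acquisitions share one scale. This matters: the module's
  purpose is cross-illumination comparability, and any per-image adaptive
  map re-injects image-dependent offsets and gains.
* `minmax`: rank-preserving per-channel map of the full range (display).
* `zscore`: the classical clipped μ ± kσ window (k = 2). Kept for display;
  note that when the informative class is a small minority far from the
  image bulk (12 canopy disks on soil are ~3 % of pixels, several σ dark
  in red), the window clips the whole class to 0 and destroys its
  within-class contrast — measured directly during development, which is
  why it is not the default for quantitative extraction.

## Vegetation indices

Sixteen indices E1–E16 (EXG, EXR, EXB, EXGR, GBDI, CIVE, GRRI, NGRDI,
NGBDI, MGRVI, VDVI, VEG, COM, VARI, IKAW, RGBVI), computed per pixel and
averaged over each plant's buffer ∩ mask region (not computed on averaged
triplets). VEG's exponent α = 0.667, the value from its source literature.
RGBVI is implemented as `(g² − b·r) / (b² + b·r)`; a `rgbvi_legacy` switch
selects the `g²`-denominator variant found elsewhere. Ratios with
|denominator| < 10⁻⁹ yield NaN (a flagged missing value); a plant with
more than 50 % missing pixels for an index is dropped from that index with
a warning. Six indices are channel differences, ten are ratios; the ratios
(except the mixed COM) are exactly invariant to per-pixel positive gain,
the differences are not — both directions are asserted in tests.

## Segmentation and zonal extraction

A two-class maximum-likelihood classifier (full-covariance Gaussian class
conditionals, empirical priors) separates vegetation from background on
per-pixel RGB features; training samples are drawn from the simulator's
label map (1000 per class by default), emulating analyst-drawn polygons.
Covariances get a relative ridge (10⁻⁶ · mean variance, floored at 10⁻¹²)
so constant synthetic regions stay invertible; ties classify as
background, the conservative error for index extraction. Buffers are
square, side 0.2 m converted via the GSD (`side_px = max(1, round(side_m /
gsd_m))`), centred on 0-based (row, col) pixel centres and clipped to the
frame.

## Evaluation

Three instruments per (method, condition): sample standard deviation
(n − 1) of each VI over the plants; Pearson correlation of each VI with
SPAD (computed from the centred cross-products; undefined for constant
vectors); and OLS of SPAD on the five VIs with highest |correlation|,
summarized by R² — defined as the squared Pearson correlation of observed
and fitted values, which for OLS with intercept equals 1 − SSE/SST (the
identity is asserted to 10⁻⁹). Five predictors limit overfitting at
n = 12; fits are in-sample, matching small-plot agronomic practice, with a
leave-one-out R² (via the hat matrix) reported as a clearly separated
extra. No multiple-testing correction: the correlations are descriptive.

**Feasible top-5 selection.** Several indices are exact linear
combinations of others (EXGR = EXG − EXR identically; on chromaticity
inputs all six difference indices span only two dimensions), so a naive
top-5 by |correlation| frequently yields a singular design. The
plain `select_top5` keeps the literal rule and `fit_top5_regression`
rejects collinear designs (condition number of the column-standardized
design above 10⁸ — standardized, because CIVE's +18.78745 offset would
otherwise inflate the number by pure units). `compare_methods` therefore
uses a deterministic greedy variant: visit VIs in decreasing
|correlation| (ties by index order) and skip any candidate that would
make the design numerically rank-deficient. Selection is re-done per
(method, condition) by default; a flag fixes one selection globally.

The ELM × variable cell of the R² grid is structurally absent, and absent
cells are reported as missing rather than errors.

## Problem sizes and determinism

Unit tests run on 160² frames; the phenomenology experiments use twenty
seeded 512² fields with 12 plants each (~1 minute total on one CPU), the
scale at which the acceptance script also operates. Every stochastic step
takes an explicit seed; an experiment derives independent child seeds for
the scene, the SPAD draw, each illumination field and the classifier
training sample, so runs are bit-reproducible and `manifest.json` suffices
to reproduce any run.

## What the simulator does not emulate — and one structural finding

Not modelled: canopy radiative transfer and BRDF, cast shadows with hard
edges, perspective and lens distortion, multi-frame mosaicking and its
seam artifacts, georeferencing, panel non-Lambertian behaviour, and sensor
noise beyond quantization (DN noise exists but defaults to off). Passing
tests therefore demonstrate the pipeline's correctness on its stated
generative model, not claims about real soybean physiology.

One consequence deserves emphasis. Because the camera response is exactly
logarithmic, a multiplicative illumination field becomes *additive* in DN
space: `DN_c = (ln ρ_c + ln ℓ_c F) / b_c`. Any difference index whose
channel weights satisfy Σ w_c / b_c = 0 then cancels the illumination
term identically — and for b = (0.016, 0.017, 0.018) the EXG weights
(−1, +2, −1) give Σ w_c / b_c ≈ −0.4, i.e. near-perfect cancellation
(log-chromaticity color constancy). CIVE behaves the same. Per-cell top-5
reselection finds these intrinsically robust indices, so the *uncorrected*
methods lose little SPAD-prediction accuracy under the simulated variable
illumination, unlike on real imagery where camera response is only
approximately exponential and illumination effects are not purely
multiplicative. The comparisons that do hold on the simulation — Retinex
matching or exceeding the uncorrected methods under variable skies,
ELM stabilizing the two uniform conditions, Retinex shrinking the
cross-condition dispersion of the leakage-prone indices — are the ones the
test suite asserts; the "uncorrected methods collapse" phenomenon is
outside what this generative model can produce and is documented as such
rather than forced.
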