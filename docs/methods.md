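# Methods

## Canopy-cover segmentation

A nadir RGB image is reduced to the per-pixel G−R index (green channel
minus red channel, signed, unclamped, range −255…255). A pixel is canopy
iff G−R is **strictly greater** than the threshold; pixels exactly at the
threshold are background. Canopy cover is the canopy-pixel fraction, a
pure ratio, so no resolution handling or sub-sampling is needed and all
pixels are used.

The default threshold is the fixed value 0: G−R > 0 is the natural sign
boundary of green dominance. An `auto` mode selects the threshold by
Otsu's criterion — the value maximizing the between-class variance of the
exact 511-bin histogram over the integers −255…255 — with ties broken
toward the lower threshold so the choice is deterministic. A constant map
has no bimodality to exploit and raises an error rather than returning an
arbitrary cut. No colour-profile management, white-balance correction or
shadow/illumination modelling is applied; JPEG/PNG files are decoded
as-is and an alpha channel, if present, is dropped (inputs are assumed
opaque). Other colour indices (ExG, NDI) and learned segmenters are out
of scope.

## Allometric model

Growth indices are linked to CC by Y = a·X^b. The parameter `a` is the
value of Y at full cover (X = 1, units of Y); `b` is the dimensionless
allometric exponent. The default fitting space is **log-linear**: OLS of
ln Y on ln X, because (i) multiplicative scatter around a power law is
additive Gaussian after the transform and (ii) the regression-comparison
test below is defined on linearized models. Standard errors and 95% CIs
come from the usual t quantiles on the log scale; the CI for `a` is the
back-transformed (hence asymmetric) log-scale interval. R² is reported in
the fitting space, and the space is recorded in the result so tables are
unambiguous. A nonlinear mode (original-scale least squares, initialized
from the log-linear estimates, delta-method CIs) exists for reporting
parity with original-scale tables. No weighting is applied. Degenerate
inputs fail loudly: non-positive X or Y raise a domain error naming the
offending rows; constant X raises a rank error; fewer than 3 points is an
error. When ln Y is exactly constant, R² is defined as 1 for a perfect
fit and 0 otherwise (the usual ratio is 0/0).

## Coincidence of regressions

Whether k per-group lines can be replaced by one pooled line is tested by
the extra-sum-of-squares decomposition: RSS of the single pooled OLS line
(df = n−2), summed RSS of the k individual lines (df = n−2k), their
difference on df 2(k−1), and

    F = [ss_diff / 2(k−1)] / [rss_within / (n−2k)]

compared with the upper-alpha F quantile (alpha defaults to 0.05, no
multiple-testing correction, one test per index/grouping). The F quantile
is scipy's, i.e. the inverse regularized incomplete beta. Allometric
comparisons are run in log-log space. Numerical policy: residual sums
below 1e−12 of the total y variation are treated as exact-fit round-off;
if the individual lines fit perfectly but the pooled line does not, F is
reported as infinite with `poolable = False` (rather than raising), and
if everything lies on one exact line F = 0 with `poolable = True`. The
degrees of freedom follow the standard bookkeeping above and are printed
with every result.

## Critical N curve and NNI

Critical N concentration: Nc = A·SDM^B with defaults A = 4.15 (% of dry
matter at SDM = 1 t ha⁻¹) and B = −0.38 (dilution exponent); SDM in
t ha⁻¹. Both are configurable; no plateau segment is modelled at low
biomass. NNI = SNC/Nc; classification uses a configurable tolerance band
(default ±0.05) around the optimum: NNI < 1−tol deficient, > 1+tol
surplus, else optimal. The band is a reporting convenience; the
scientific boundary is 1. Unit conversions are centralized:
SNA (kg ha⁻¹) = 10 · SDM (t ha⁻¹) · SNC (%).

Two CC→NNI estimators:

* **direct** — fit NNI = a·CC^b on observed pairs (log-linear OLS);
* **indirect** — compose fitted SNC = a_s·CC^b_s and SDM = a_d·CC^b_d
  through the definition of NNI. For a general curve (A, B) this gives,
  exactly and without fitting,

      a′ = a_s · a_d^(−B) / A        b′ = b_s − B·b_d

  reducing at the defaults to a′ = a_s·a_d^0.38/4.15 and
  b′ = b_s + 0.38·b_d. The identity holds pointwise for every CC, which
  the tests verify to 1e−12 relative error.

Note that when both routes are fitted in log space **on the same
records**, they coincide exactly: ln NNI = ln SNC + 0.38·ln SDM − ln 4.15
is a linear identity, and OLS is linear in the response. The two routes
differ only when the SNC/SDM components are fitted on different data than
the direct model, or in nonlinear space — which is their use case: SNC
and SDM can be calibrated where NNI itself was never measured.

Reference per-stage component parameters carried with the package
(Feekes 3: SNC = 11.97·CC^1.03, SDM = 2.71·CC^1.10; Feekes 5:
3.81·CC^0.50, 6.20·CC^1.74; Feekes 6: 3.46·CC^0.86, 5.19·CC^1.65) compose
to NNI = 4.21·CC^1.45, 1.84·CC^1.16 and 1.56·CC^1.49 respectively. Two
published per-stage indirect models are not internally consistent with
the composition algebra (one matches a_s/4.15 with b′ = b_s; another
prints b′ = 0.86 where the components give 1.16); this package follows
the algebra, which is exact, and does not attempt to reverse-engineer
those rows. The Feekes 6 exponent (1.49) and Feekes 5 coefficient (1.84)
are consistent both ways.

## Synthetic data

**Scenes.** Random slender ellipses ("leaves", semi-axes ~1/14 of the
short image side) are accumulated over a soil background until the mask
reaches the pixel count implied by the target cover; the last blob is
trimmed, and any shortfall painted pixel-by-pixel, so the ground-truth
cover is exact to the nearest pixel. Colours default to leaf RGB
(60, 130, 50) and soil (140, 70, 60) — G−R of +70 and −70 — with
independent per-channel Gaussian noise (SD 6, clipped to 0…255). The
magnitude-symmetric G−R means keep the sign-flip probability at threshold
0 negligible (≈1e−16 per pixel) and make block-averaged mixed pixels
classify by majority leaf fraction, so CC is stable under integer
downsampling. The scenes have no radiative-transfer or 3-D architecture
realism, no shadows, specularities or senescent material: passing the
segmentation tests shows the thresholding machinery is correct, not that
a threshold of 0 is optimal for field photographs.

**Trials.** The default design is 2 sites × 2 seasons × 4 cultivars ×
5 N rates (0…300 kg N ha⁻¹) × 3 replicates × 3 stages (Feekes 3, 5, 6) =
720 records, mirroring a multi-environment N-response experiment. Mean CC
interpolates linearly across stages between per-N-rate endpoints
(defaults: 0.18→0.61 at N0, 0.30→0.88 at N300, intermediate rates
linearly interpolated) with Gaussian plot jitter (SD 0.05, clipped to
0.02…0.98) — the endpoint means are the observed treatment means, the
jitter a plausible between-plot scatter. SDM, LAI and SNA follow the
cultivar power laws of CC (defaults are the published per-cultivar
estimates, e.g. AK58 SDM: a = 4.87, b = 1.92) with independent
multiplicative lognormal noise; SNC is then derived as SNA/(10·SDM) so
the accounting identity holds by construction — SNC inherits a declining
power of CC (N dilution) plus a noise ratio. The lognormal uses median 1
(E[ln ε] = 0, σ² = ln(1+CV²)) rather than mean 1, so log-space OLS is
exactly unbiased and t-based CIs achieve exact nominal coverage; the
default CV of 0.1 reproduces R² values in the 0.9 range for SDM, looser
for derived SNC. Within-treatment variance components are not published;
the CVs are free parameters with these documented defaults. All
randomness flows from one explicit integer seed per generator call; there
is no hidden global RNG state.

## Pipeline

`run_pipeline` assembles plot records (synthetic, or segmented images
inner-joined with a destructive-sampling CSV on site/season/cultivar/
N-rate/replicate/stage — duplicate keys are integrity errors, disjoint
keys a reconciliation warning), appends Nc/NNI/status columns, fits
per-cultivar, per-N-rate and pooled allometries, runs coincidence tests
overall and per stage (SDM and SNC across cultivars), and fits per-stage
direct plus composed indirect CC→NNI models. A pooled-over-stages CC→NNI
fit is emitted alongside the per-stage fits so the cross-stage
instability of a unified CC–NNI relation is visible as its lower R².
Stage labels form an ordered categorical (Feekes 3 < 5 < 6). Records are
sorted on the key columns and floats serialized at repr precision, so
reruns under the same configuration and seed are byte-identical.

## Problem sizes used in the test suite

Simulation studies run at sizes chosen to keep the default suite fast
while leaving comfortable statistical margins: segmentation accuracy on
50 scenes of 240×180 px (tolerance 0.01 against exact ground truth); CI
calibration with 200 replicates of 180-point fits (nominal 0.95, band
0.93–0.97); coincidence-test type-I error with 1,000 null simulations of
4×15 points (band 0.03–0.07, ≈3 binomial SDs); oracle agreement on 100
random instances at 1e−9. Distributional shape of the null F statistic is
checked by Kolmogorov–Smirnov on 400 simulated statistics.

## Known limitations

- The G−R + global threshold segmenter assumes green-dominant vegetation
  on red/brown soil under even illumination; it will misclassify shadowed
  soil, algae or purple-tinged stressed leaves. Real deployments should
  validate the threshold per camera and lighting protocol.
- The critical curve is treated as known; uncertainty in (A, B) is not
  propagated into NNI.
- CC saturates after canopy closure, so all CC-based models are limited
  to the early window the package targets (Feekes 3–6).
- Coincidence testing covers full coincidence only; slope-only or
  elevation-only ANCOVA stages are not implemented.
- The pooled-over-stages CC→NNI fit is reported for diagnosis, but no
  model selection between functional forms is attempted.
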