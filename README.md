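# wheatcc

Canopy-cover extraction from nadir RGB images and canopy-cover-based
modelling of growth and nitrogen status in winter wheat.

## The problem

During the early growth of winter wheat (Feekes 3–6), timely nitrogen
management needs a cheap, non-destructive proxy for crop N status. Canopy
cover (CC) — the fraction of ground covered by the vertical projection of
the canopy — can be measured from a single nadir photograph with a consumer
camera. `wheatcc` implements the full analysis chain that evaluates CC as
such a proxy, for agronomists and crop-phenotyping researchers:

1. **Segmentation.** Each pixel's G−R index (green minus red channel) is
   thresholded: pixels with G−R strictly greater than the threshold are
   canopy, the rest background; CC is the canopy-pixel fraction. The
   threshold defaults to 0 (green dominance) with an automatic Otsu mode.
2. **Allometry.** Growth indices — shoot dry matter (SDM, t ha⁻¹), leaf
   area index (LAI) and shoot N accumulation (SNA, kg ha⁻¹) — are related
   to CC by the allometric power law *Y* = *a*·CC*ᵇ*, fitted by OLS after
   log-linearization (ln *Y* = ln *a* + *b* ln CC).
3. **Poolability.** Whether per-cultivar (or per-N-rate) allometric lines
   may be merged into one is decided by a coincidence-of-regressions
   F test: the extra sum of squares of the single pooled line over the
   individual lines, on 2(*k*−1) and *n*−2*k* degrees of freedom.
4. **Nitrogen status.** The critical N concentration follows the dilution
   curve *N*c = 4.15·SDM^−0.38 (% of dry matter); the nitrogen nutrition
   index NNI = SNC/*N*c is 1 at optimum. NNI is estimated from CC either
   **directly** (fit NNI = *a*·CCᵇ) or **indirectly** by composing fitted
   SNC = *a*ₛ·CC^*b*ₛ and SDM = *a*d·CC^*b*d through the curve, which stays
   a power law with closed-form parameters
   *a*′ = *a*ₛ·*a*d^0.38/4.15 and *b*′ = *b*ₛ + 0.38·*b*d.

A synthetic-data module generates canopy scenes with exact ground-truth
masks and multi-site trial tables (4 cultivars × 5 N rates × 3 replicates
× 3 stages by default) with the allometric and N-dilution structure above,
so every stage of the pipeline is testable without field data.

## Worked example

```python
import wheatcc as w

# 1. segment a synthetic scene with known cover
cfg = w.ImageSceneConfig(width=320, height=240, target_cover=0.42, seed=9)
img, mask = w.generate_canopy_image(cfg)
seg = w.segment_canopy(w.compute_gr_index(img), threshold=0)
print(f"true cover = {mask.mean():.4f}   estimated CC = {seg.cc:.4f}")

# 2. fit the CC–SDM allometry for one cultivar of a synthetic trial
trial = w.generate_trial(w.TrialConfig(noise_cv=0.1, seed=7))
ak58 = trial[trial.cultivar == "AK58"]
print(w.AllometricModel.from_dataframe(ak58, y="sdm_t_ha", x="cc").fit().summary())

# 3. can the four cultivars share one CC–SDM line?
print(w.compare_from_dataframe(trial, y="sdm_t_ha", group="cultivar").summary())

# 4. indirect CC→NNI model for Feekes 6
model = w.compose_indirect(a_s=3.46, b_s=0.86, a_d=5.19, b_d=1.65)
print(model.equation(), f"| NNI at CC=0.6: {model.predict(0.6):.3f}")
```

prints

```
true cover = 0.4200   estimated CC = 0.4200
Allometric fit  Y = a * X^b
  space : log-linear   n = 180   R^2 = 0.991
  a = 4.921  95% CI [4.79, 5.057]  (SE of ln a: 0.0137)
  b = 1.939  95% CI [1.911, 1.966]  (SE: 0.014)
Comparison of 4 regression lines (n = 720, alpha = 0.05)
source                      SS    df          MS
single line             50.175   718
individual lines        7.0234   712   0.0098643
difference              43.152     6       7.192
F = 729.1   F_crit(6, 712) = 2.111   p = 4.691e-300
decision: lines differ; do not pool
NNI = 1.56 CC^1.49 | NNI at CC=0.6: 0.729
```

The segmentation recovers the generator's cover exactly; the fitted
(a, b) ≈ (4.92, 1.94) bracket the generating values (4.87, 1.92) within
their CIs; the F test correctly refuses to pool cultivars whose generating
parameters differ; and at CC = 0.6 the Feekes 6 canopy signals N
deficiency (NNI < 1).

The same steps are available from the shell:

```bash
wheatcc simulate trial --out trial.csv --seed 7
wheatcc fit --data trial.csv --y sdm_t_ha --group cultivar --out fits.json
wheatcc compare --data trial.csv --y sdm_t_ha --group cultivar --out cmp.json
wheatcc nni --data trial.csv --out nni.csv
wheatcc run --out report/           # full pipeline on a synthetic trial
```

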