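# scmospia — photophysical image analysis for sCMOS cameras

`scmospia` separates signal from background in sCMOS fluorescence-microscopy
images by modelling the camera physics instead of tuning heuristics.  It is
aimed at microscopists and image-analysis developers working in low photon
budgets (single-molecule DNA imaging, live bacterial cells, any regime where
the mean background is a handful of photoelectrons per pixel), where
intensity-histogram methods such as Otsu's give no handle on the
misclassification rate.

## The model

The digital count `n_ic` recorded in a pixel (in ADU) is a sum of four
independent terms

```
n_ic = g·n_oe + N_read + N_q + Δ
```

* `n_oe ~ Poisson(λ)` — photoelectrons; quantum efficiency and dark current
  are absorbed into the single Poisson mean λ,
* `g` — overall gain (ADU per photoelectron),
* `N_read ~ TL(Λ_TL, σ_TL)` — read noise, modelled by a zero-location
  Tukey-Lambda distribution, whose shape Λ_TL captures the heavy,
  non-Gaussian tails of fast sCMOS readout (Λ_TL ≈ 0.14 would be
  near-Gaussian, Λ_TL = 0 logistic),
* `N_q ~ U(−1/2, 1/2)` — quantization error, `Δ` — constant offset.

Because the terms are independent their characteristic functions multiply,
and the count PMF follows by trapezoidal Gil-Pelaez inversion of the product
CF over [0, π].  Everything downstream is built on that PMF:

* **Calibration** — gain from the photon-transfer (mean-variance) line
  `Var = g·(mean − Δ) + d` with `d = s²_TL + 1/12`; offset from the mean of
  a dark ("cap-on") frame; read-noise shape and scale by maximizing the
  probability-plot correlation coefficient (PPCC) of the dark-count
  quantiles over Λ_TL.
* **Background estimation** — the Poisson mean λ_bg of background pixels is
  the MLE of a *truncated* likelihood `∏ PMF(n_j)/CDF(T)` over counts below
  a truncation point `T`, chosen as the largest empirical quantile whose
  fit passes a Pearson χ² goodness-of-fit test at `p_GoF = 0.01`; signal
  pixels above `T` never enter the fit.
* **Thresholding and segmentation** — the acceptable false-positive
  fraction `p_binarize = 0.01` is inverted through the background CDF into
  a count threshold; white connected components (8-connectivity, 1-pixel
  gap bridging) are scored by the tail probability of their summed count
  under the background model (`p_seg`).

A forward-model simulator (`scmospia.simulate`) generates cap-on frames,
white-wall calibration stacks and mixed background/signal scenes with
exactly this statistical structure, so the whole pipeline is testable
without any camera data.

## Worked example

Simulate a 128×128 scene with background λ_bg = 102.6 photoelectrons/pixel
and one bright disc, then run the full pipeline:

```python
from scmospia import BackgroundSegmenter, CameraParams
from scmospia.simulate import Disc, SceneSpec, make_scene

params = CameraParams(gain=0.81, tl_shape=0.055, tl_scale=1.310, offset=100.10)
spec = SceneSpec(shape=(128, 128), background_lambda=102.6,
                 objects=[(Disc(40, 40, 5), 8 * 102.6)], seed=1)
image, truth = make_scene(spec, params)

seg = BackgroundSegmenter(params, tile_size=64)
labels = seg.fit_predict(image)
for (r, c), f in sorted(seg.tile_fits_.items()):
    print(f"tile ({r},{c}): lambda_bg = {f.lambda_bg:6.1f}   "
          f"trunc = {f.trunc_point}   GoF p = {f.gof_pvalue:.2f}   "
          f"threshold = {seg.tile_thresholds_[(r, c)]}")
obj = max(seg.objects_, key=lambda x: x.n_pixels)
print(f"largest object: {obj.n_pixels} px, summed count {obj.summed_count}, "
      f"p = {obj.p_value:.2e}")
print(f"white fraction outside truth: {seg.binary_image_[~truth].mean():.4f}")
```

prints

```
tile (1,1): lambda_bg =  102.3   trunc = 204   GoF p = 0.63   threshold = 203
tile (1,2): lambda_bg =  102.7   trunc = 220   GoF p = 0.72   threshold = 204
tile (2,1): lambda_bg =  102.4   trunc = 214   GoF p = 0.98   threshold = 203
tile (2,2): lambda_bg =  102.7   trunc = 212   GoF p = 0.35   threshold = 204
largest object: 70 px, summed count 52864, p = 0.00e+00
white fraction outside truth: 0.0080
```

Each 64×64 tile recovers the generating λ_bg = 102.6 to a few tenths of a
photoelectron; the per-tile thresholds (203–204 ADU) turn ~0.8% of the
background pixels white — inside the a-priori 1% bound — and the disc is
found as a single 70-pixel region whose summed count is astronomically
unlikely under the background model.

The same pipeline is scriptable from the shell:

```bash
scmos-pia simulate --out-dir bundle --seed 7
scmos-pia calibrate --dark bundle/capon.tiff \
    $(for f in bundle/whitewall_*.tiff; do echo --whitewall $f; done) \
    --out calib.json
scmos-pia estimate-bg --image bundle/scene.tiff --calib calib.json --out tiles.csv
scmos-pia threshold-segment --image bundle/scene.tiff --calib calib.json --out-prefix seg
```

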