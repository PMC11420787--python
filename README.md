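# hscompare

**Dual-camera hyperspectral comparison for intraoperative tissue imaging.**

Neurosurgical hyperspectral (HS) imaging faces a trade-off: pushbroom
*linescan* cameras deliver hundreds of narrow bands at high spatial
resolution but need more than a minute to scan a brain surface, while
*snapshot mosaic* cameras capture all of their 25 bands in a single
100 ms exposure at the cost of spectral and spatial resolution and a much
noisier 8-bit sensor. Whether the cheap, fast camera "sees" the same
tissue spectra as the slow reference camera determines whether real-time
intraoperative tumor delineation is feasible.

`hscompare` implements the full comparison methodology as a tested,
reusable pipeline, driven by a synthetic two-tissue phantom so that every
stage runs without any restricted clinical data:

1. **Synthetic scene** — a Beer–Lambert chromophore phantom
   (`R = 10^(−Σ_k c_k μ_a,k(λ) · l)`) with a healthy disk (higher HbO₂),
   a pathological disk (higher Hb), dark rubber-ring annuli, and simulated
   captures for both cameras: Gaussian band integration, 5×5 mosaic
   sampling with filter crosstalk, an additive ~850 nm rangefinder-laser
   peak (snapshot only), 8/16-bit quantization, and matched white/dark
   references.
2. **Preprocessing** — reflectance calibration
   `R = (I_raw − I_dark)/(I_white − I_dark)`, active-area crop + mosaic
   demosaicing or line stitching, spectral correction `R_sc = R · SCM`
   (snapshot), effective-band removal to 400–1000 nm (linescan).
3. **Noise filtering** — additive-noise estimation by regressing each band
   on all remaining bands; the residual cube is subtracted.
4. **Similarity** — per-tissue 5×5-pixel ROI mean signatures (the larger
   linescan ROI randomly subsampled to the same 25 pixels),
   nearest-wavelength band matching between the two grids, and the
   SAM, GFC and RMSE metrics with and without per-pixel min-max
   normalization, summarized across patients by quartiles and the
   interquartile range (IQR = Q3 − Q1).
5. **Chromophores** — absorbance `A = −log₁₀(R)` compared against
   chromophore absorption-coefficient spectra over 31-band peak windows
   (the peak wavelength ± 15 grid neighbours) using the scale-invariant
   spectral angle; peaks outside a camera's range are reported as
   unmeasurable.

The metric conventions: SAM = `(2/π)·arccos(⟨x,y⟩/‖x‖‖y‖)` ∈ [0, 1]
(0 = identical shape), GFC = `|⟨x,y⟩|/‖x‖‖y‖` ∈ [0, 1] (1 = proportional),
RMSE = `√mean((x−y)²)`. The linescan signature is always the reference.

## Worked example

Run a 10-patient synthetic cohort and summarize the inter-camera metric
distributions:

```python
from hscompare.pipeline import PipelineConfig, run_cohort, summarize_metrics

cfg = PipelineConfig(n_patients=10, seed=1)
metrics, _ = run_cohort(cfg)
summary = summarize_metrics(metrics)
print(summary[["metric", "tissue", "normalized", "q1", "q3", "iqr", "median"]]
      .round(4).to_string(index=False))
```

prints

```
metric       tissue  normalized     q1     q3    iqr  median
   sam      healthy       False 0.0151 0.0168 0.0016  0.0155
   gfc      healthy       False 0.9997 0.9997 0.0001  0.9997
  rmse      healthy       False 0.0147 0.0154 0.0007  0.0151
   sam      healthy        True 0.0795 0.0936 0.0141  0.0832
   gfc      healthy        True 0.9892 0.9922 0.0030  0.9915
  rmse      healthy        True 0.2313 0.2609 0.0296  0.2439
   sam pathological       False 0.0230 0.0286 0.0056  0.0260
   gfc pathological       False 0.9990 0.9993 0.0004  0.9992
  rmse pathological       False 0.0137 0.0141 0.0004  0.0140
   sam pathological        True 0.1003 0.1485 0.0482  0.1251
   gfc pathological        True 0.9728 0.9876 0.0148  0.9808
  rmse pathological        True 0.2734 0.3515 0.0781  0.3030
```

Read this as: on unnormalized (calibrated + denoised) data the two cameras
agree closely — median SAM ≈ 0.016 (healthy) and 0.026 (pathological) with
GFC ≈ 0.999 — and the distributions across patients are tight. After
per-pixel min-max normalization, every metric disperses (the SAM IQR grows
roughly ten-fold) because normalization stretches each noisy snapshot
spectrum onto [0, 1], amplifying the 8-bit sensor noise relative to the
signal. Unnormalized data therefore make the cameras look most similar,
and the normalized/unnormalized IQR gap is the pipeline's headline
diagnostic.

The same study is available from the shell:

```bash
hscompare run-all --seed 1 --out results/demo
# -> metrics.csv, summary.csv, peaks.csv, config.yaml, run.log
```

`peaks.csv` holds the chromophore search: one row per
camera × tissue × normalization × peak, with the matched-band count and
SAM value, and `measurable=False` for peaks a camera cannot reach (of the
21 default peaks only five fall inside the snapshot camera's
659.95–951.42 nm range; the 976 nm water peak is reachable only by the
linescan camera).

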