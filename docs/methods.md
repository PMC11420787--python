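# Methods

This note records the models, conventions, and numerical choices behind
`hscompare`, and what the synthetic data can and cannot demonstrate.

## Phantom model

Tissue reflectance is generated from the decadic Beer–Lambert law.  Per
pixel,

    A(λ) = l · ( Σ_k c_k · μ_a,k(λ) + μ_flat ),     R(λ) = 10^(−A(λ)),

clipped to [1e−6, 1].  The `c_k` are dimensionless scale factors applied
to reference chromophore absorption tables (so `c_HbO2 = 0.01` reads as a
1% blood-volume fraction at full oxygenation against the whole-blood
table), `l` is the optical path length in cm (default 0.5 cm), and
`μ_flat` is a wavelength-flat offset standing in for non-chromophore
losses (scattering out of the collection aperture, absorption by species
not modeled).  Defaults place healthy-tissue reflectance around 0.3–0.6
and pathological reflectance around 0.15–0.35 in the NIR, the ranges
typical of in vivo cortex, with the pathological disk carrying the higher
Hb fraction and the healthy disk the higher HbO₂ fraction.  Two disk ROIs
with dark ring annuli (flat μ_a = 2 cm⁻¹, mimicking rubber markers) define
the tissue regions.

A seeded smooth random field (Gaussian noise blurred with σ = 8 px,
scaled to ±15% on concentrations and ±20% on path length) produces the
within-ROI brightness variation that a curved, unevenly lit tissue surface
shows; without it, per-pixel min-max normalization would have nothing to
amplify.  Per-patient biological variability multiplies each composition
entry by `1 + 0.15·N(0,1)` (floored at 0).

The model deliberately excludes scattering transport, specular
reflections, and motion: it is a phantom for exercising the measurement
chain, not a tissue-optics simulator.  Consequences for interpretation
are listed under *Limitations*.

## Chromophore library

Real reference tables (hemoglobin extinction, cytochrome redox spectra,
water and lipid absorption) are external resources with unpinned
versions, so the package bundles a *synthetic* library: each chromophore
is a sum of Gaussian peaks over a small smooth baseline, with peak
positions at the literature values used throughout the analysis (HbO₂
414/542/576 nm, Hb 433/556/756 nm, water 976 nm, fat 756/830/930 nm,
oxidized cytochrome b 422 nm, oxidized cytochrome c 695 nm, reduced
cytochrome b with a deliberately narrow 555 nm alpha band, …) and
plausible amplitude scales (hemoglobin as molar extinction in
L·mol⁻¹·cm⁻¹, converted to μ_a via `μ_a = ln(10)·ε·c/M` with c = 150 g/L
whole-blood hemoglobin and M = 64 500 g/mol, both overridable; all other
species directly in cm⁻¹).  The default peak list holds 21 entries; five
lie inside the snapshot camera's range, which drives the
measurable/unmeasurable bookkeeping.  Real tables can be supplied through
the CSV schema (`wavelength_nm,value,unit_kind,name`) and are
interpolated onto the scene grid; a grid outside a table's coverage is a
hard error rather than an extrapolation.

Note one deliberate convention: phantom absorbance uses `A = μ_a·l`
literally (decadic), while the extinction conversion carries the ln(10)
factor.  Mixing the two conventions changes only the overall scale of
μ_a, which the scale-invariant SAM matching ignores; the default follows
the conversion formula as published by the extinction-table convention.

## Camera simulation

* **Band integration.** Each camera band integrates the scene spectrum
  with a Gaussian response of the nominal FWHM (15 nm snapshot, 5.8 nm
  linescan), truncated at ±3σ and normalized to unit weight.
* **Band grids.** The snapshot's 25 centers are spaced uniformly over
  659.95–951.42 nm (12.14 nm spacing, matching the published mean
  spacing of 12.11 ± 2.64 nm; the true center list is not public).  The
  linescan grid is 394 uniform points over the 365–1004 nm
  sensor-sensitive range, 369 of which survive the 400–1000 nm
  effective-band cut.
* **Mosaic geometry.** Band `b` of cube pixel `(y, x)` sits at sensor
  pixel `(5y + b div 5, 5x + b mod 5)` — row-major within each 5×5 tile.
  The true filter layout is not public; any fixed bijection is
  equivalent as long as demosaicing uses the same one, which the
  round-trip tests enforce.  The sensor is the active filter zone plus a
  3-row/3-column unfiltered border (2048×1088 → 2045×1085 at full scale);
  the simulator replicates edge responses into the border, and
  preprocessing crops it off.
* **Crosstalk.** Filter crosstalk is a row-stochastic mixing matrix
  applied in band space (default: 5% leakage to each adjacent band); its
  inverse plays the role of the manufacturer's spectral correction
  matrix, whose true values are proprietary.
* **Counts and noise.** A pixel seeing reflectance R reads
  `dark_level + gain·R (+ laser peak) + N(0, read_sd) + N(0, shot·signal)`
  rounded and clipped to the ADC range; `gain` puts the white reference
  at 92% of full scale so it never saturates.  Noise is additive by
  construction, matching the assumption of the denoising stage.  The
  rangefinder laser appears as an additive Gaussian bump in band space
  centered at 850 nm (FWHM 30 nm, 12 counts), on the raw snapshot capture
  only — the laser is off during linescan scans and absent from
  references.  Defaults: read SD 1 count and shot scale 0.01 at 8 bits;
  read SD 30 counts and shot scale 0.002 at 16 bits.
* **Determinism.** Every stochastic draw flows from an explicit integer
  seed through a PCG64 generator in a fixed order; identical
  (config, seed) give bit-identical captures, and the acceptance bundle
  records the seed and a config hash in every output table.

## Preprocessing conventions

* Calibration is elementwise, so it commutes with the purely positional
  cube-formation step; it is applied in mosaic/line space first
  (acquisition order), and a test asserts the equivalence.
* Calibration denominators ≤ 1e−9 counts are flagged invalid and set to
  0.  Reflectance outside [0, 1] (specular highlights, noise) is
  preserved by default and recorded in an out-of-range mask; `clip=True`
  maps into [0, 1].  Preserving values keeps the later min-max
  normalization faithful to the raw calibration.
* Band removal keeps both endpoints (`keep_min ≤ λ ≤ keep_max`); on the
  uniform 394-point stand-in grid this inclusive rule reproduces the
  published 369-band count.
* Coordinates are 0-based, row-major, `(row, col, band)` everywhere.

## Noise estimation

Each band's pixel vector is regressed on all remaining bands (bands
mean-centered first, equivalent to an intercept) and the residual is the
noise estimate; denoising subtracts the residual cube.  The per-band
solves reuse one inverse of the ridge-regularized band covariance via the
partitioned-inverse identity `resid_b = (X P)[:, b] / P[b, b]`, making the
whole estimate one B×B inverse plus a matmul.  The ridge default
`λ = 1e−6·trace(C)/B` guards near-collinear synthetic cubes; with λ = 0
residuals are exactly orthogonal to the regressors.  Per-band variance
uses the degrees-of-freedom-corrected residual sum of squares
(`SS/(n − B)`), which removes the small-sample downward bias; the
remaining upward bias from noisy regressors is below 10% at the problem
sizes used and is covered by the ±20% recovery tolerance.  Only the
estimation-plus-subtraction stage is implemented; signal-subspace
dimension selection is out of scope.

## Comparison stage

The linescan signature is the reference, the snapshot the arbitrary
signal.  Both ROIs contribute exactly 25 pixels (the larger linescan ROI
is subsampled uniformly without replacement, seeded).  Each snapshot band
is paired with its nearest linescan wavelength, ties breaking toward the
lower wavelength.  For normalized comparisons, min-max normalization is
applied per pixel *after* restricting to the matched wavelengths, so both
cameras normalize over the same spectral support; degenerate (constant)
pixels map to zero and are flagged.  SAM is scaled by 2/π so that
non-negative spectra map onto [0, 1]; GFC uses the absolute inner
product; quartiles use linear interpolation between order statistics
(type 7).  The ~850 nm laser-contaminated band is kept in all metrics by
default (it is part of the snapshot's acquisition conditions); an
`exclude-lidar` sensitivity variant can be built by passing a trimmed
pairing.

Cohort-mean absorbance spectra for the chromophore stage are computed as
`−log₁₀` of the cohort-mean ROI reflectance (floored at 1e−6 and flagged
where clipped); for normalized conditions the per-pixel normalization is
applied before averaging, so exact zeros at a pixel's minimum band
average out before the log except in degenerate cases, which the floor
absorbs.

## Problem sizes

Desk-scale defaults keep every stage exact but small: phantoms are
96×120 px on a 1 nm grid (360–1010 nm), giving a 24×30×25 snapshot cube
(sensor 123×153 with the same crop structure as the 2048×1088 original)
and a 96×120×369 linescan cube.  Replicate-cohort runs use 64×80 scenes
on a 2 nm grid.  The full-sensor counting rules (2045×1085 → 409×217×25;
500 × 1600×394 line stitching) are exercised at true size on synthetic
integer frames.  A 10-patient cohort runs in under a minute; the whole
acceptance script takes about two minutes on one CPU.

## What passing tests do and do not show

The synthetic study demonstrates that the *pipeline* is correct (every
operator matches its closed form or an independent oracle; the noiseless
chain recovers the phantom to within quantization) and that the
*qualitative* published trends emerge from the modeled physics: per-pixel
min-max normalization amplifies snapshot sensor noise, so normalized
metric distributions disperse (larger IQRs) while unnormalized data make
the cameras look most similar; chromophore peaks are only identifiable
where a camera has bands.  The numeric IQRs and peak SAM values depend on
the phantom's noise and composition settings and are *not* estimates of
the clinical values, which require the access-restricted patient data and
the proprietary correction matrix.

## Limitations

* Beer–Lambert only: no scattering transport, so absolute reflectance
  levels are stylized even though spectral shapes are realistic.
* No geometric registration between cameras — alignment is by
  construction, as the physical rings provide in the real protocol.
* The synthetic chromophore library reproduces peak positions, not
  exact band shapes; identifications on real data need real tables.
* The spectral correction matrix is modeled as the exact inverse of the
  simulated crosstalk; real sensors are known to deviate from their
  vendor matrix, which the simulation does not reproduce.
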