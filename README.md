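# cestq — multi-pool Lorentzian quantification of CEST-MRI Z-spectra

`cestq` implements a complete quantification chain for chemical exchange
saturation transfer (CEST) MRI, from raw saturated image stacks to
group-level statistics. The measured quantity is the Z-spectrum
Z(Δω) = S_sat/S0, the normalized water signal as a function of saturation
offset: exchangeable protons (amide at +3.5 ppm, amine at +2.0 ppm, the
relayed NOE at −3.5 ppm) appear as small dips riding on a large direct-
water-saturation (DS) line and a very broad semisolid magnetization
transfer (MT) background. The package separates these five pools per
voxel and turns the resulting amplitude maps into diagnostic features
and two-group statistics of the kind used for glioma grading and
molecular-marker prediction.

## The quantification chain

1. **Preprocessing** — optional subpixel in-plane registration
   (cross-correlation), multilinear SVD (MLSVD) tensor denoising of the
   (x, y, offset) stack with a noise-adaptive rank rule, and
   normalization by the unsaturated reference frame.
2. **B0 correction** — a per-voxel two-pool (water + MT) fit restricted
   to background offsets; the fitted water position serves as the B0
   surrogate, and each spectrum is spline-resampled to re-center water
   at 0 ppm. A spline-minimum estimator is available as an alternative.
3. **Background refit and Lorentzian difference** — the two-pool
   background is refit and MTR_LD(Δω) = Z_fit,ref(Δω) − Z(Δω) isolates
   the CEST peaks.
4. **Three-pool CEST fit** — amide, amine and NOE Lorentzians (plus a
   constant) are fit to MTR_LD; the fitted amplitudes are the metric
   maps. A simultaneous five-pool fit (`method="five_pool"`) is provided
   as a model-matched alternative.

Downstream, `cestq.metrics` computes MTR asymmetry maps (MTR_3.5, the
pH-weighted 3.0-ppm contrast, with an optional sigmoid pH calibration)
and six-number ROI histogram features; `cestq.stats` implements
normality-dependent group comparisons, ROC analysis with DeLong
confidence intervals and Youden cutoffs, a tolerance/VIF collinearity
screen, a combined logistic model, and inter-observer ICC.

Because real patient data cannot ship with the package, `cestq.phantom`
generates seeded synthetic phantoms and multi-subject cohorts from the
same five-pool forward model, with per-voxel biological jitter, smooth
B0 fields, Rician or Gaussian noise, and configurable group effects —
every output has known ground truth.

## Worked example

```python
import numpy as np
from cestq.phantom import PhantomConfig, generate_phantom
from cestq.pipeline import process_subject

phantom = generate_phantom(PhantomConfig(grid_shape=(12, 12),
                                         noise_sd=0.01, seed=42))
result, maps = process_subject(phantom, denoise=True)

tumor = phantom.masks["tumor"].voxels
print(f"convergence: {result.convergence_fraction:.3f}")
print(f"tumor amide amplitude: {np.nanmean(maps['amide'][tumor]):.4f} "
      f"(truth {phantom.truth['amplitude']['amide'][tumor].mean():.4f})")
print(f"tumor MTR_3.5: {np.nanmean(maps['mtr35'][tumor]):.4f}")
```

Output:

```
convergence: 1.000
tumor amide amplitude: 0.0465 (truth 0.0544)
tumor MTR_3.5: -0.0046
```

The amide amplitude is recovered to within the expected accuracy of the
sequential scheme (see *Known limitations*); MTR_3.5 is slightly negative
here because the NOE and MT contributions at −3.5 ppm outweigh the amide
dip — the asymmetry metric mixes pools by construction, which is exactly
why the Lorentzian amplitudes are the primary metrics.

The same run is available from the command line:

```bash
cest run-all --seed 7 --out results/run
```

## Repository layout

- `src/cestq/` — the library (`core`, `phantom`, `preprocess`,
  `lorentzian`, `metrics`, `stats`, `pipeline`, `io`, `cli`).
- `analysis/` — numbered narrative drivers: `01_simulate_phantom.py`,
  `02_fit_recovery.py` (recovery-error table across noise levels),
  `03_cohort_stats.py` (end-to-end two-group cohort analysis). Outputs
  land in `results/`.
- `tests/` — unit, property-based and acceptance tests.
- `scripts/acceptance.py` — recomputes the headline quantities from
  scratch and writes them to JSON.
- `docs/methods.md` — model equations, numerical choices and limitations.

## Reproduction

```bash
python -m pytest -q tests/                      # full suite, ~6 min
python scripts/acceptance.py --seed 1 --out results/acceptance.json  # ~2 min
python analysis/02_fit_recovery.py              # recovery table, ~1 min
```

All randomness is seeded; reruns are bit-identical for a given seed.

## Known limitations

- **The sequential 4-step scheme carries a structural bias.** The
  background fit uses only MT-range (±10…±100 ppm) and water-range
  (0…±1 ppm) offsets, but the tails of the CEST lines — above all the
  broad amine line at 2 ppm — leak into the water-range points. On
  noise-free phantoms the median amine amplitude error is ≈23%, amide
  ≈4%, with DS/MT/NOE at 1–3% (`analysis/02_fit_recovery.py` prints the
  table). One acceptance test asserts sub-1% noise-free recovery for all
  pools and **fails by design**; it documents this property rather than
  hiding it. The simultaneous five-pool fit recovers all amplitudes to
  numerical precision and is the recommended method when the acquisition
  model is trusted.
- The phantom generator shares its forward model with the analysis
  (Lorentzian line superposition, not Bloch–McConnell exchange
  dynamics), so recovery results measure estimator properties, not
  physical model error.
- The combined logistic model reports apparent (in-sample) ROC without
  cross-validation, matching single-cohort clinical reporting practice.

See `docs/methods.md` for details and parameter conventions.
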