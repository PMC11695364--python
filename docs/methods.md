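# Methods

## Signal model

The normalized Z-spectrum of a voxel is modeled as a constant baseline
minus a superposition of Lorentzian lines:

```
Z(Δω) = c − Σ_p L_p(Δω)
L_p(Δω) = A_p (Γ_p²/4) / (Γ_p²/4 + (Δω − δ_p)²)
```

with amplitude `A_p`, full width at half maximum `Γ_p` (ppm) and position
`δ_p` (ppm). Five pools are used:

| pool  | position (ppm) | default width | role |
|-------|---------------:|--------------:|------|
| DS    | 0              | 2.0           | direct water saturation |
| MT    | −1             | 40            | semisolid magnetization transfer |
| amide | +3.5           | 1.5           | mobile proteins/peptides (APT) |
| amine | +2.0           | 1.8           | fast-exchanging amine protons |
| NOE   | −3.5           | 3.0           | relayed nuclear Overhauser effect |

The water line optionally carries a saturated plateau of bandwidth BW:

```
L_w(Δω) = A Γ²/4 / (Γ²/4 + (x·Θ(x) + y·Θ(−y))²),   x = Δω − δ − BW/2,
                                                     y = Δω − δ + BW/2
```

where `Θ` is the Heaviside step. Inside the plateau the line equals `A`
exactly; at BW = 0 it reduces to the standard Lorentzian (both identities
are asserted in the test suite on dense grids). When the saturation pulse
duration needed to derive BW is not configured, BW = 0 is used and a
warning is emitted.

## Offset schedule

The default schedule has 64 frames: 0, ±0.25 … ±5 in 0.25-ppm steps,
±5.5 … ±7.5 in 0.5-ppm steps, ±10, ±15, ±20, ±25, ±30, ±100 ppm
(interleaved +v, −v; 31 negative offsets), plus a +300 ppm unsaturated
reference frame used as S0. Background subsets for the two-pool fit are
the MT range (±10, ±15, ±20, ±25, ±30, ±100) and the water range
(0, ±0.25, ±0.5, ±0.75, ±1) — 21 points.

## Quantification chain

1. **Registration** (optional): per-frame in-plane translation to the
   reference frame by upsampled cross-correlation (`normalization=None`;
   the default phase normalization is unreliable on smooth band-limited
   MR magnitude images). Constant or uncorrelated frames are left
   unshifted with a warning.
2. **MLSVD denoising**: the (x, y, offset) tensor is projected onto the
   leading left singular subspaces of each mode unfolding. The default
   rank rule estimates the noise-bulk edge from the Marchenko–Pastur
   support (σ̂ = s_min/(√n − √m); keep s > σ̂(√n + √m)) and skips
   truncation entirely for modes with fewer than 32 rows, where no noise
   bulk can be located; this makes the default denoiser an exact
   identity on noise-free data. Explicit per-mode ranks and an
   energy-fraction rule are available.
3. **Normalization**: Z = S_sat/S0 with the in-stack reference frame (or
   an explicit S0 image). Voxels with non-positive S0 are excluded and
   counted; implausible Z values (outside [−0.2, 1.5]) are flagged, not
   clamped.
4. **B0 estimation and correction**: a per-voxel two-pool (water + MT)
   fit restricted to the background offsets yields the water position as
   the B0 surrogate; alternatively the argmin of a cubic-spline
   interpolation of Z over |Δω| ≤ 2 ppm. Spectra are spline-resampled at
   Δω + B0; query points beyond the sampled range use spline
   extrapolation and are counted. Round-trip bias of the two-pool
   estimator over injected shifts in [−0.5, 0.5] ppm is < 0.002 ppm
   noise-free (asserted < 0.02 ppm).
5. **Background refit and Lorentzian difference**:
   MTR_LD(Δω) = Z_fit,ref(Δω) − Z(Δω) with the two-pool background
   refit on the corrected spectrum.
6. **Three-pool CEST fit**: constant + amide + amine + NOE Lorentzians
   fit to MTR_LD by trust-region least squares; pool positions are free
   within ±0.4 ppm of nominal. Fitted amplitudes are the metric maps.
   Non-converged voxels are flagged and NaN-masked, never silently
   filled.

A **simultaneous five-pool fit** of the full Z-spectrum is available via
`method="five_pool"`; it is model-matched to the generator and recovers
all amplitudes to numerical precision on noise-free data.

## Sequential-scheme bias

The 4-step scheme is biased even without noise: the background fit sees
only MT-range and water-range offsets, and the tails of the CEST lines
contaminate the water-range points (a 1.8-ppm-wide amine line at 2 ppm
retains ~25% of its peak at 1 ppm). The background therefore absorbs part
of the CEST signal and the difference spectrum underestimates the pools.
Measured on a 200-voxel jittered phantom (noise-free, medians of
per-voxel relative amplitude error): DS ≈ 0.9%, MT ≈ 2.6%, amide ≈ 4.3%,
NOE ≈ 2.9%, amine ≈ 23%. The corresponding acceptance test asserts < 1%
for all pools and fails; it is retained as an honest record of this
property. Fit-region variants and narrow-line configurations were
explored and do not remove the effect — it is structural to fitting the
background separately from the CEST pools. With noise SD 0.01 and
denoising, the pooled (voxel × pool) median relative error of the full
chain is ≈5%, within the 10% working tolerance.

## Contrast metrics

- MTR asymmetry: `MTR_asym(x) = (Z(−x) − Z(+x)) / M0` (M0 = 1 on
  normalized spectra); MTR_3.5 at 3.5 ppm, the pH-weighted contrast at
  3.0 ppm. Exact schedule points are used when present, spline
  interpolation otherwise. Note the sign convention: a positive-side
  pool (amide/amine) produces *positive* asymmetry.
- pH calibration: `asym(pH) = α + (β − α)/(1 + 10^E)` with
  `E = δ(κ − pH)` by default; the alternative literal reading
  `E = δ·κ·pH` is selectable (`exponent_form="kappa_times_ph"`). Both
  are strictly monotone and inverted in closed form; asymmetry values
  outside the open interval (α, β) are out of calibration and rejected.
- ROI histogram features: mean, median and the 10/25/75/90th percentiles
  (linear interpolation) over finite in-ROI voxels, with a 10-voxel
  minimum.

## Statistics

Two-group comparison uses Welch-free Student t when both groups pass
Shapiro–Wilk (α = 0.05), otherwise two-sided Mann–Whitney U; categorical
covariates use χ². ROC analysis reports the empirical AUC (orientation
flipped so AUC ≥ 0.5, as in diagnostic tables) with a DeLong
placement-value 95% CI, the Youden-optimal cutoff and "% (k/n)"
sensitivity/specificity cells. Features significant at α enter a greedy
tolerance/VIF screen (drop worst while VIF > 10 or Tol < 0.1), then a
maximum-likelihood logistic model (ridge-stabilized fallback on
separation, flagged); the combined ROC is apparent (in-sample).
Inter-observer agreement uses the two-way random, absolute-agreement,
single-measure ICC.

Calibration caveat: the orientation fold biases the *null* expectation of
the reported AUC upward (E[max(A, 1−A)] ≈ 0.53 at n = 100/group), so
calibration checks use the unfolded U/(n₁n₂) statistic. Measured over
1000 zero-effect cohorts: type-I error 0.043–0.056 (binomial 95% CI of
0.05 is ±0.0135), mean unfolded AUC 0.496.

## Synthetic phantom and cohorts

Phantoms are concentric (tumor disk, edema ring, normal background) with
class-wise pool parameters chosen at realistic tissue scales, per-voxel
uniform jitter (±10%) on amplitudes and widths, an optional smooth
polynomial B0 field (≤0.5 ppm), optional per-frame motion, and Gaussian
(default) or Rician noise on the saturated images (S0 = 1000).

Cohorts draw subjects with additive and/or multiplicative group effects
on pool amplitudes plus subject-level lognormal random effects
(σ = 0.2 default). Two generator-consistency choices: random effects
apply to the CEST solute pools only (water/MT between-subject variation
is far smaller in relative terms, and scaling them routinely violated the
physical amplitude-sum bound), and the underlying normal draw is
truncated at ±2.5σ (unbounded tails eventually violate any physical
bound). Seeding uses `SeedSequence` spawning: every subject, replicate
and noise draw is reproducible from one integer.

The generator deliberately shares its forward model with the analysis.
Recovery numbers therefore measure estimator properties (bias, noise
sensitivity) and not physical model error; no Bloch–McConnell exchange
dynamics, B1 inhomogeneity, or partial-volume effects are simulated.

## Numerical choices

- All fits: `scipy.optimize.least_squares` (TRF) with bounds, tolerance
  1e-12, seeded deterministic initialization; the initial objective is
  never exceeded by the returned solution.
- Spline operations use cubic splines on the sorted offset grid.
- Problem sizes in tests and scripts (200-voxel recovery phantoms,
  1000-replicate nulls, 12-per-group effect cohorts, 500-replicate
  Monte-Carlo oracle) were fixed once as desk-scale designs before
  freezing assertions; tolerances follow measured behavior documented
  above, except the deliberate noise-free < 1% assertion.
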