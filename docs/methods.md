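# Methods

## Signal model

A cone outer segment is bounded by two reflective interfaces, the
inner–outer segment junction (ISOS) and the cone outer segment tip (COST).
For A-scan i inside the cone's pixel region, the complex OCT samples at the
two layers are modelled as

    ISOS_i(t) = a_i · exp(j[ψ(t) + η_i(t)])
    COST_i(t) = a_i · exp(j[ψ(t) + 4π·ΔOPL(t)/λ + ν_i(t)])

where ψ(t) is a piston phase common to both layers at each volume (axial
bulk motion of the eye), λ is the imaging centre wavelength (default
1063 nm), a_i is a static per-A-scan reflectance, and η, ν are independent
circular phase-noise terms. The factor 4π (not 2π) arises because the probe
light traverses the outer segment twice.

The phase estimator averages conjugate products over the m brightest
A-scans, Δφ(t) = ∠((1/m) Σ COST_i·conj(ISOS_i)): ψ(t) cancels identically,
which the test suite asserts as an exact invariant. The referenced phase is
then unwrapped in time and scaled to nm by λ/(4π).

### Numerical choices in extraction

- **Baseline referencing on the circular scale.** The reference phase is the
  angle of the mean unit phasor over the unmasked pre-stimulus volumes,
  computed before unwrapping. Arithmetic averaging of wrapped angles fails
  when the two baseline phases straddle ±π (there is a regression test for
  exactly this case); the circular mean does not.
- **Angle convention** (−π, π] throughout (`np.angle`); nm is the only OPL
  unit.
- **A-scan selection** happens once per trial from the record's
  time-averaged amplitude map, with ties broken by lowest linear index.
  Per-timepoint reselection (from the product magnitudes) is available via
  `select_per_timepoint`; with static per-trial speckle amplitudes the two
  are nearly equivalent, but per-trial selection keeps the phasor
  population fixed over time, which is the safer default for a
  difference-over-time measurement.
- **Masked-gap unwrapping.** Timepoints lost to eye motion are skipped by
  the unwrapper; a run of more than `max_unwrap_gap` (default 3) missing
  volumes makes the 2π ambiguity across the gap untrustworthy and excludes
  the cone–trial with a logged reason. A cone is likewise excluded when
  every baseline volume is masked; a single surviving baseline volume is
  accepted (with `n_baseline_used` recorded).

## Response model and fitting

The stimulus-evoked OPL change is fit with the step response of an
overdamped RLC circuit,

    ΔOPL_fit(t) = A1·(exp(−τb·t) − exp(−τa·t)),   τa > τb > 0,

with A1 in nm and both rates in s⁻¹ (exponents are dimensionless products
rate × time). The curve rises with rate τa, peaks at
t_peak = ln(τa/τb)/(τa−τb), and returns with rate τb. Over a 1.4–1.5 s
recording the return is barely expressed, so τb is weakly identified and is
not reported as a figure of merit.

Fitting is unweighted nonlinear least squares (`scipy.optimize.least_squares`,
trust-region reflective) over post-stimulus (t ≥ 0), unmasked samples only;
baseline samples serve exclusively for phase referencing. Details:

- **Parametrization.** (A1, τa, ρ) with τb = ρ·τa, ρ ∈ [0.001, 0.995], so
  the ordering constraint is a box bound and the (τa, τb)-swap ambiguity of
  the curve (swapping the rates flips the sign of A1) is excluded by
  construction; every returned fit satisfies A1 > 0, τa > τb > 0 and the
  `RlcFit` type enforces it.
- **Bounds.** A1 ∈ [1, 1000] nm, τa ∈ [0.5, 100] s⁻¹ — bracketing typical
  in-vivo values by more than an order of magnitude.
- **Multi-start.** A1⁰ = 1.3 × max(trace) clipped to bounds;
  (τa⁰, τb⁰) ∈ {(8, 1), (4, 0.5), (16, 2)} s⁻¹; the lowest final RMS wins,
  ties by lower τa. The `converged` flag is false when the winner sits on a
  bound (within 1e−8) or the solver failed; such fits are retained for
  logging but excluded downstream.
- **Minimum support.** 8 unmasked post-stimulus points to fit; 5 to compute
  ΔOPL_max (the mean of the five highest raw samples, ties broken by
  earlier time).
- **RMS filter.** Fits with RMS residual ≥ 30 nm (or non-converged) are
  dropped; 20 and 40 nm thresholds are recomputed alongside for a
  sensitivity check.

ΔOPL_max is biased upward by selecting the five highest noisy samples,
while the fitted peak is not; the test suite demonstrates this selection
bias by Monte Carlo, matching the observation that direct maxima sit
consistently above fitted maxima on real data.

## Repeatability statistics

- **CoV** = 100 × sample SD (n−1 denominator) / mean, per cone across
  trials, computed only for cones retained in *all* trials (complete
  cases). Rows with non-positive mean are flagged and dropped from
  aggregation.
- **Aggregation** over the mosaic by RMS (default) or arithmetic mean; RMS
  ≥ mean always (power-mean inequality, property-tested).
- **ICC(2,1)** (Shrout–Fleiss; equivalently McGraw & Wong's ICC(A,1):
  two-way model, absolute agreement, single measure) from the two-way ANOVA
  mean squares with rows = cones and columns = trials:
  ICC = (MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n). The 95% CI uses the
  McGraw & Wong F-distribution method with Satterthwaite degrees of
  freedom. Negative estimates are reported as computed. MSE below 1e−12 ×
  MSR is treated as exact agreement (ICC 1 with a degenerate-CI flag) so
  that noise-free replicates, which differ only in the last floating-point
  bits, are reported as perfect. The implementation is cross-checked in the
  tests against a brute-force ANOVA (statsmodels OLS) to 1e−10 and against
  pingouin's ICC(A,1) including the CI. The label "ICC(2,1)" follows the
  Shrout–Fleiss numbering for the two-way design; some naming conventions
  reserve it for two-way *random* effects — the formula implemented is the
  absolute-agreement single-measure one given above.
- **Pooled statistics** use all retained cones per trial (the subsets may
  differ between trials, as they do in practice when eye motion changes
  which cones survive): per-trial mean and SD, then the CoV of the means
  and the CoV of the SDs across trials.

## Synthetic data generator

The generator emulates the study conditions of a repeated single-session
ORG experiment: 28 Hz volume rate, 2 pre-stimulus volumes, a 10 ms flash at
t = 0, 42 post-stimulus volumes, λ = 1063 nm, 7×7-pixel cone regions with
the 9 brightest A-scans used by the estimator, and three repeated trials.
Sampling places the first post-stimulus volume at t = 1/28 s (a
configurable sub-frame offset defaults to 0).

Population defaults: A1 ~ N(200, 46) nm, τa ~ N(8, 2) s⁻¹,
τb ~ N(1, 0.3) s⁻¹ (all truncated at zero, τa > τb enforced by bounded
resampling) — means and dispersions at the scale reported for healthy
cones at ~3–4° eccentricity. An S-cone-like fraction (default 5%, roughly
the S-cone share of the mosaic) receives amplitudes uniform in 30–50 nm,
reproducing the weak-response left tail of amplitude distributions.

Stochastic channels, each independently seeded per trial from one
`SeedSequence`:

- **Trial jitter**: cone-level trial-to-trial parameter variation;
  `trial_noise_sd` (default 10 nm ≈ 5% of the mean amplitude) acts
  multiplicatively on A1 and, at twice the relative SD, log-normally on
  both rates — reflecting that response kinetics vary more between trials
  than amplitudes. The decomposition is a modelling choice; single-session
  data quantify only its aggregate effect (the CoV summaries).
- **Phase noise**: per-layer, per-A-scan circular Gaussian with
  SD = 1/SNR (amplitude SNR, linear), the shot-noise-limited
  approximation; default 20 dB. Configurations implying SD > π are
  rejected.
- **Piston**: uniform(−π, π] per volume, applied to both layers.
- **Amplitudes**: static per-trial log-normal (σ = 0.5) speckle-like
  reflectances, making "brightest m" selection meaningful.
- **Baseline drift**: a per-cone Gaussian random walk rescaled to a target
  RMS (default 2.5 nm, the magnitude of system baseline OPL fluctuation
  reported for this class of instrument, ~15 nm peak-to-peak).
- **Dropout**: each volume lost independently with `dropout_rate`
  (default 5%).

Configurations whose clean ΔOPL steps ≥ λ/4 between consecutive volumes are
rejected, since a phase step ≥ π cannot be unwrapped.

A trace-level generator (`simulate_traces`) bypasses the complex-signal
encoding and adds i.i.d. Gaussian noise directly to model curves; the
cohort studies (`truncation_study`, `recovery_study`) use it with a 2.5 nm
RMS noise floor. At that floor, the Cramér–Rao bound for the default
42-sample design gives sd(τ̂a)/τa ≈ 2.9%, so the observed median recovery
error (< 5%) and amplitude bias (< 2%) indicate an essentially efficient
fitter; at several-fold higher noise the bound itself exceeds those
figures, i.e. no estimator could do better on single traces.

### What the generator does not emulate

No raster-scan geometry, speckle decorrelation, registration or
segmentation failures, chromatic stimulus effects, or photopigment
bleaching. In particular, because there is no registration/segmentation
failure mode, almost all synthetic fits pass the 30 nm RMS filter
(~99% retained), whereas real datasets lose 10–30% of cones to such
artifacts. Passing tests therefore validate the estimators and statistics
under the assumed signal model, not robustness to gross segmentation
errors.

## Truncation study

`truncation_study` refits each trace of a 300-cone cohort on supports
t ≤ 1.0, 1.1, 1.2 s and compares the cohort-mean τ̂a against the full
1.4 s support. The comparison is made at the pooled (cone-averaged) level —
the level at which τa is reported as a summary parameter — because
per-trace τ̂a carries a sampling SD of a few percent even at the noise
floor, which pooling over hundreds of cones suppresses. The pooled rate
changes by well under 0.4% across seeds, i.e. recordings longer than ~1 s
add essentially no information about the elongation rate.

## Problem sizes

Default cohorts are 300 cones × 3 trials (the order of co-registered cones
in a 1° field); Monte-Carlo recovery uses 200 replicates; the truncation
study fits 4 supports × 300 traces. These sizes put simulation error well
below the effects being measured while keeping any single study under a
minute on one CPU.

## Known limitations

- τb is reported by the fitter but should not be interpreted on 1.4 s
  recordings (weak identifiability).
- The phase-noise model is the small-angle shot-noise approximation; at
  very low SNR (SD approaching π) circular noise is no longer
  well-approximated and such configurations are rejected rather than
  simulated.
- The ICC CI assumes the normal two-way ANOVA model; heavy-tailed
  parameter distributions (e.g. a large S-cone fraction) make the CI
  approximate.
- Stages communicate via persisted artifacts (HDF5/CSV/JSON); determinism
  is guaranteed at the array level for a fixed seed and configuration.
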