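# coneorg

Phase-based optoretinography (ORG) of cone photoreceptors: simulation of
complex two-layer AO-OCT signals, extraction of stimulus-evoked
outer-segment optical path length changes, overdamped response-model
fitting, and single-cone / pooled test–retest repeatability statistics.

## The problem

In adaptive-optics OCT, the light reflected at the inner–outer segment
junction (ISOS) and at the cone outer segment tip (COST) interferes with a
phase difference proportional to the optical path length (OPL) of the cone
outer segment. A visible flash triggers an elongation of the outer segment
of a few hundred nanometres — far below the axial resolution of the system,
but readily measurable in the phase. `coneorg` implements the computational
half of such an experiment for researchers developing or validating ORG
pipelines:

1. **Phase extraction.** Per cone and timepoint, the phase difference is
   estimated from the m brightest A-scans in the cone's pixel region via
   the conjugate-product estimator

   Δφ(t) = ∠( (1/m) Σᵢ Aᵢ Bᵢ* ),

   where A is the complex COST signal and B* the conjugate ISOS signal.
   Any piston phase common to both layers (axial bulk motion) cancels
   exactly. After referencing to the pre-stimulus baseline (circular mean
   of the baseline phases) and temporal unwrapping, the OPL change is
   ΔOPL(t) = Δφ₀(t)·λ/(4π).

2. **Response model.** Each trace is fit with the step response of an
   overdamped RLC circuit,

   ΔOPL_fit(t) = A₁ (e^(−τ_b t) − e^(−τ_a t)),  τ_a > τ_b > 0,

   with A₁ in nm and rates in s⁻¹. Fits with RMS residual ≥ 30 nm are
   filtered out. Three figures of merit are extracted per cone and trial:
   ΔOPL_max (mean of the five highest samples), ΔOPL_fitting,max (the
   analytic peak of the fitted curve, attained at
   t_peak = ln(τ_a/τ_b)/(τ_a−τ_b)), and τ_a.

3. **Repeatability.** Per-cone coefficients of variation across repeated
   trials (aggregated by RMS over the mosaic), the single-measure
   intraclass correlation ICC(2,1) from a two-way ANOVA with an F-based
   95% CI, and pooled per-trial means/dispersions with their CoVs.

Because in-vivo recordings of this kind are not generally shareable, the
package ships a synthetic-data generator that produces complex two-layer
cone records with the statistical structure the analysis assumes
(population heterogeneity, an S-cone-like weak-response subpopulation,
per-volume piston phase, SNR-dependent phase noise, baseline drift, and
eye-motion dropout), together with the ground truth needed for recovery
testing.

## Worked example

```sh
coneorg run --seed 42 --outdir demo
```

simulates three repeated trials of a 300-cone population (A₁ ~ N(200, 46) nm,
τ_a ~ N(8, 2) s⁻¹, τ_b ~ N(1, 0.3) s⁻¹; 44 volumes at 28 Hz, two of them
pre-stimulus), extracts and fits all 900 traces, and writes `report.json`.
With this seed the report contains:

| parameter | single-cone CoV (RMS) | ICC(2,1) [95% CI] | pooled CoV of means |
|---|---|---|---|
| ΔOPL_max | 8.7 % | 0.95 [0.94, 0.96] | 0.21 % |
| ΔOPL_fitting,max | 9.1 % | 0.95 [0.94, 0.96] | 0.15 % |
| τ_a | 18.0 % | 0.64 [0.58, 0.69] | 0.88 % |

Read: the elongation amplitude of a single cone is highly repeatable
(CoV < 10 %, "excellent" ICC), the elongation rate is noisier, and pooling
over the mosaic drives the trial-to-trial CoV below 1 % — the amplitude of
the pooled response is a very stable functional biomarker. The per-trial
pooled means for ΔOPL_max were 124.3/124.7/124.8 nm with inter-cone SDs of
44.3/44.9/45.1 nm (CoV of the SDs: 1.0 %), i.e. the shape of the response
distribution over the mosaic is itself stable across trials.

Each stage is also available separately (`coneorg simulate|extract|fit|stats`)
and as library functions (`coneorg.simulate_dataset`, `extract_dataset`,
`fit_dataset`, `repeatability_report`, ...).

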