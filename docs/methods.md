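# Methods

This note documents the models, numerical choices and simulation design
behind `tdmri`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic experiments can and cannot show.

## Signal model

A voxel is modeled as two non-exchanging water pools:

    S(b, seq) = ν_in · S_in(b, seq; d, D_in) + (1 − ν_in) · exp(−b · D_ex)

* `d` — mean cell diameter (μm), one diameter per voxel (monodisperse);
* `ν_in` — intracellular volume fraction (dimensionless);
* `D_ex` — extracellular (hindered) diffusivity (μm²/ms), taken to be
  frequency-independent over the protocol's range;
* `D_in` — intrinsic intracellular diffusivity (μm²/ms), **fixed** at
  1.56 μm²/ms and not fitted. A three-parameter fit (d, ν_in, D_ex) is the
  standard configuration for this protocol class; the value is configurable
  everywhere it enters (`ImpulsedFitter(d_in=...)`,
  `MicrostructureParams(d_in=...)`). Joint estimation of D_in from two OGSE
  frequencies plus one PGSE shell is poorly conditioned, which is why it is
  pinned.

The intracellular signal uses the Gaussian phase approximation (GPA) for
diffusion inside an impermeable reflecting sphere of radius R = d/2. The
x-position autocovariance of a spin is an eigenmode sum

    ⟨x(t₁)x(t₂)⟩ = Σₙ Bₙ e^(−λₙ|t₁−t₂|),   Bₙ = 2R²/(αₙ²(αₙ²−2)),
    λₙ = αₙ² D_in / R²,

with αₙ the roots of j₁′(α) = 0 (α₁ ≈ 2.0815759778). Σₙ Bₙ = R²/5, the
x-variance of a uniform sphere — this sum rule is asserted in the tests.
The attenuation is

    −ln S_in = (γ²/2) Σₙ Bₙ ∬₀^TE g(t₁) g(t₂) e^(−λₙ|t₁−t₂|) dt₁ dt₂

with g(t) the effective (sign-inverted after refocusing) gradient waveform.

**Evaluation.** Waveforms are two rectangular (PGSE) or two integer-cycle
cosine (OGSE) lobes, so the double integral is evaluated piecewise
analytically: same-lobe terms in closed form, cross-lobe terms factorized
via e^(−λ(t₁−t₂)) = e^(−λt₁)·e^(λt₂), with growing exponentials folded into
differences of decaying ones for stability. For PGSE this reduces exactly
to the Murday–Cotts expression (asserted to 1e-12 against an independent
transcription). A nested adaptive-quadrature evaluation of the same double
integral (no shared algebra beyond the eigenbasis) agrees to 1e-8 and is
the normative fallback for waveform shapes without closed forms. The mode
sum is truncated at K = 20; K = 20 vs K = 50 changes signals by < 1e-5.

Because −ln S_in ∝ g² at fixed timing and b ∝ g², the GPA intracellular
signal is exactly monoexponential in b: S_in = exp(−b·D_app(seq; d, D_in)).
`sphere_adc` exposes D_app directly; restriction makes it increase with
oscillation frequency (ADC_50Hz ≥ ADC_25Hz ≥ ADC_PGSE), the time-dependence
the method exploits.

**Sign/prefactor validation.** Two independent checks pin the master
formula rather than trusting transcription: (i) the Monte Carlo engine with
reflections disabled reproduces the free-diffusion closed form e^(−b·D_in);
(ii) GPA signals match the restricted Monte Carlo engine to ≤ 0.01 absolute
across sequences and diameters (10⁵ walkers in the acceptance-level check).

**Monte Carlo engine.** Walkers start uniform in the sphere, take Gaussian
steps of variance 2·D_in·dt per axis (dt = 0.02 ms by default), and are
reflected by radial folding (overshoot distance folded back inside). Phase
accumulates as φ = γ Σ g(t)·x(t)·dt; S = |⟨e^{iφ}⟩|. Radial folding is
first-order accurate in step length; at the default step the residual
boundary bias is well inside the 0.01 comparison band.

## Acquisition model

The shipped protocol (`tdmri/data/breast_protocol.json`) encodes the
clinical 3T breast acquisition the package targets: cosine OGSE at 25 Hz
(one cycle/lobe, t_diff = 1/(4f) = 10 ms; b = 0–1000 s/mm²; averages
1,1,2,3,4) and 50 Hz (two cycles, t_diff = 5 ms; b = 0–250; averages
1,1,1,1), plus PGSE at t_diff = Δ − δ/3 = 78.4 ms (b = 0–1800; averages
1,1,2,3,4,5,6), TE = 105 ms.

Published timing gives t_diff but not the individual PGSE lobe timings;
the defaults δ = 12 ms, Δ = 82.4 ms satisfy Δ − δ/3 = 78.4 ms inside
TE = 105 ms and are configurable. OGSE lobes last δ = n_cycles/f = 40 ms;
their separation (Δ = 52 ms, a 12 ms refocusing gap) is likewise a
configurable default — OGSE attenuation is dominated by intra-lobe terms,
so the result is insensitive to the gap. Waveforms are idealized rectangles
and cosines (no ramps or apodisation; no slew data to model them).
b ↔ g conversions use the closed forms b = γ²g²δ²(Δ − δ/3) (PGSE) and
b = γ²g²δ/ω² (cosine OGSE, integer cycles, both lobes), verified round-trip
against the numerical q-space integral b = ∫|γ∫g|²dt to 1e-6 relative.

All internal computation is SI; user-facing units are ms, μm, μm²/ms and
s/mm² (ADC in μm²/ms is numerically the conventional ×10⁻³ mm²/s).

## Voxelwise fitting

Signals are normalized per voxel by each sequence's b = 0 mean, then fitted
by trust-region bounded least squares (ftol = xtol = gtol = 1e-10) inside
the physiological box 5 ≤ d ≤ 50 μm, 0 ≤ ν_in ≤ 1, 0 ≤ D_ex ≤ 3 μm²/ms.
Residuals are weighted by √nsa, the correct inverse-standard-deviation
weight when each b-shell is an nsa-fold average. A fixed 4×4×3 start grid
(d ∈ {8,15,25,40}; ν_in ∈ {0.1,0.3,0.5,0.7}; D_ex ∈ {0.5,1.5,2.5}) is
screened by initial RSS and the best 6 starts are polished; the lowest-RSS
solution wins, ties broken by smaller d. The fit is fully deterministic.
Polishing all 48 starts instead of 6 changed nothing on 300 noisy
replicates of the malignant group-mean voxel; 6 keeps cohort-scale runs
about three times faster.

Estimates cannot leave the box; voxels whose best fit sits on a bound
(within 1e-4 of the parameter range) are flagged in a boundary mask so
map consumers can treat them as censored rather than interior estimates.

D_app(seq; d) is precomputed on a 0.05 μm diameter grid per sequence and
interpolated with a cubic spline (error ≤ 1e-9 μm²/ms, asserted), making a
voxel fit a few tens of milliseconds.

ADC per sequence is the slope of an nsa-weighted linear regression of
−ln S on b over the sequence's full b-list, with a free intercept to absorb
normalization error, clipped at zero. The PGSE ADC uses the full b ≤ 1800
range (configurable upper limit for sensitivity analyses).

**Known estimator behavior.** No Rician bias correction is applied (the
reference workflow applies none either). At SNR 25 the dominant noise
effect is not the Rician floor (σ²/2S is negligible at these shell SNRs)
but the propagation of b = 0 reference noise through normalization plus the
curvature of the model manifold: fitted ν_in is biased upward by roughly
+0.01–0.03 and d by a few percent at group level. The noiseless pipeline is
unbiased to < 1%. This matters when comparing simulation-recovered group
means against published fitted values (see Limitations).

## Synthetic cohorts and phantoms

`draw_cohort` draws (d, ν_in, D_ex) independently per lesion from
truncated normals with the published malignant (n = 27: 17.26 ± 2.88 μm,
0.38 ± 0.10, 1.88 ± 0.25 μm²/ms) and benign (n = 18: 24.13 ± 4.54 μm,
0.24 ± 0.10, 2.24 ± 0.17 μm²/ms) group statistics, truncated to the fitting
bounds so noiseless recovery is well posed. No covariances are published,
so draws are independent; consequently the simulated cellularity
(ν_in/d × 100) group means (≈ 2.3 / 0.9) do not exactly reproduce the
published cellularity row (2.48 / 1.13), which reflects the correlation of
ν_in and d in real tumors. The cellularity *AUC* survives independence
(simulated ≈ 0.93 vs published 0.936).

ER/PR/HER2/Ki67 labels are assigned to malignant lesions as independent
Bernoulli draws with the published marginal frequencies (Ki67 ≥ 14% defines
positivity). By default the labels carry no parameter effect (the null the
subgroup tests should not reject); `pr_negative_v_in_shift` adds a ν_in
offset to PR-negative lesions for power experiments.

`render_phantom` lays ellipsoidal lesions (semi-axes ≈ 2.3–2.9 × 1.7–2.1
voxels, inflated until ≥ 30 voxels — small clinical lesions at a 2×2×5 mm
voxel grid) on a block lattice over free water (D = 3.0 μm²/ms). Voxel
truths jitter around the lesion truth with a 10% coefficient of variation
(a declared assumption; real intra-lesion heterogeneity is unknown),
truncated to bounds. Signals come from the forward model with S(0) = 1;
Rician noise uses σ = 1/(snr·√nsa) per acquisition with SNR 25 at b = 0 by
default (typical clinical breast DWI). Everything is seeded and exactly
reproducible.

What the phantom does **not** emulate: breast anatomy and coil profiles,
fat suppression, partial-volume mixtures at lesion rims (voxels are purely
lesion or purely background), motion/eddy artifacts, polydisperse cell
sizes, membrane exchange. Passing recovery tests therefore demonstrates
estimator correctness under the declared noise model, not clinical
robustness.

## ROI workflow and statistics

Masks are eroded by one 6-connected iteration (partial-volume guard from
the reference workflow); an erosion that would leave < 5 voxels is skipped
with a warning. Per-lesion records are means over eroded ∩ converged
voxels. Cellularity is the mean of the voxelwise ratio (ratio-then-average)
— averaging a ratio map, as parameter maps are read in practice, differs
from the ratio of averages; this convention is applied consistently.
A second reader is emulated by one-voxel mask jitter; agreement uses
ICC(2,1) — two-way random effects, absolute agreement, single measures
(pingouin's ANOVA estimator, cross-checked against a hand-written ANOVA
table in the tests) with an F-distribution CI. The variant is a
documented choice; the reference analysis names no ICC form.

Group comparisons use Welch's unpaired t by default (robust to the unequal
group sds; Student's pooled test is available). No multiplicity correction
is applied by default, matching how such tables are conventionally
reported; a Holm option exists. ROC analysis uses the empirical
(Mann–Whitney) AUC oriented so AUC ≥ 0.5, DeLong structural-component
variance for Wald CIs (coverage verified 92–98% at n = 45 in simulation),
and a Youden-index cutoff for sensitivity/specificity. Paired AUC
comparisons use the paired DeLong test (variance cross-checked against a
bootstrap). Combined models are unpenalized in-sample logistic regressions
on standardized predictors; their ROC is computed on fitted probabilities,
so a single-predictor model reproduces that predictor's AUC exactly.

## Problem sizes

Cohort-scale experiments use 45-lesion phantoms (27 malignant / 18 benign,
≈ 40–60 voxels per lesion). The test suite runs 3 replicate cohorts
end-to-end; the acceptance script runs 5 (its t3/t4/t6) and 200 lightweight
truth-level cohorts for the AUC benchmarks (t7/t9). Monte Carlo checks use
2×10⁴ walkers in unit tests and 10⁵ in the acceptance-level check.

## Known limitations

* Independent parameter draws understate the published cellularity group
  means (see above); the discrimination benchmarks are unaffected.
* The noise-induced upward bias of fitted ν_in (+3–10% at group level at
  SNR 25) is inherent to normalize-then-fit without Rician correction.
  Published fitted values carry the same estimator applied once to real
  data; the simulation applies it a second time on top of distributions
  that already reflect one application, so simulation-recovered ν_in group
  means can sit just outside a 5% band around the published values. The
  corresponding end-to-end check reports this honestly rather than
  absorbing it into the generator.
* Fitted-map AUCs are diluted relative to truth-level AUCs by voxel-fit
  noise averaged over small ROIs (≈ 10–20 eroded voxels); the fitted cell
  diameter AUC lands around 0.84–0.85 vs a truth level of 0.90.
* Monodisperse impermeable spheres; no exchange, no polydispersity, no
  frequency dependence of D_ex.
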