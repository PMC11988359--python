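# tdmri — time-dependent diffusion MRI microstructure mapping

`tdmri` implements joint PGSE/OGSE ("IMPULSED") microstructure mapping for
breast diffusion MRI, for imaging scientists who want to fit cellular
parameters from multi-diffusion-time DWI and benchmark the whole analysis
without patient data.

Conventional DWI probes water displacement over tens of milliseconds and
collapses the tissue into a single apparent diffusion coefficient (ADC).
Oscillating-gradient (OGSE) acquisitions shorten the effective diffusion
time to 1/(4f), and the diffusion-time dependence of the signal carries
cell-scale structure. `tdmri` models a voxel as impermeable spheres in a
hindered extracellular space,

S(b) = ν_in·S_in(b; d, D_in) + (1 − ν_in)·e^(−b·D_ex),

with S_in the Gaussian-phase-approximation signal of water restricted in a
sphere of diameter d, and fits d (cell diameter, μm), ν_in (intracellular
volume fraction) and D_ex (extracellular diffusivity, μm²/ms) voxelwise
from a combined protocol (OGSE 25 Hz and 50 Hz + PGSE at t_diff = 78.4 ms).
Cellularity is reported as ν_in/d × 100. Per-frequency ADC maps
(ADC_0Hz, ADC_25Hz, ADC_50Hz) come from log-linear fits per sequence.

The package contains the full study loop:

* `tdmri.acquisition` — sequence/protocol descriptors, waveforms, b ↔ g;
* `tdmri.impulsed` — the forward signal model (closed-form GPA, adaptive
  quadrature, and a Monte Carlo random-walk oracle);
* `tdmri.mapfit` — voxelwise bounded least-squares parameter maps and ADC;
* `tdmri.cohort` — synthetic lesion cohorts and Rician-noise phantoms with
  known ground truth, matching the published malignant/benign group
  distributions;
* `tdmri.roi` — mask erosion, per-lesion summaries, inter-reader ICC(2,1);
* `tdmri.stats` — Welch/Student t-tests, empirical ROC with DeLong CIs,
  paired AUC comparison, combined logistic models, IHC subgroup tests.

See `docs/methods.md` for the model, assumptions, and numerical choices.

## Worked example

Simulate a 45-lesion phantom at SNR 25, fit it, summarize ROIs and compare
groups — either through the CLI (`tdmri simulate / fit / roi / compare /
roc`) or the library:

```python
import tdmri
from tdmri.cohort import draw_cohort, render_phantom

protocol = tdmri.breast_protocol()
for seq in protocol.sequences:
    print(seq.label, tdmri.effective_diffusion_time(seq), "ms")

lesions = draw_cohort(seed=0)                       # 27 malignant + 18 benign
stack, labels, truth = render_phantom(lesions, protocol, snr=25, seed=1000)
maps = tdmri.ImpulsedFitter(protocol).fit_volume(stack, labels > 0)
records = tdmri.summarize_lesions(maps, labels, truth)
table = tdmri.group_comparison_table(
    records, parameters=("v_in", "d", "cellularity", "d_ex"))
print(table[["parameter", "malignant_mean", "benign_mean", "p", "auc"]]
      .round(3).to_string(index=False))
```

prints

```
ogse25 10.0 ms
ogse50 5.0 ms
pgse 78.4 ms
  parameter  malignant_mean  benign_mean   p   auc
       v_in           0.412        0.252 0.0 0.893
          d          17.688       25.165 0.0 0.850
cellularity           2.545        1.037 0.0 0.967
       d_ex           1.954        2.416 0.0 0.912
```

Reading the output: the effective diffusion times are the time scales each
sequence probes (1/(4f) for OGSE, Δ − δ/3 for PGSE). In the recovered
cohort, simulated malignant lesions show smaller cells, higher
intracellular fraction and cellularity, and lower extracellular diffusivity
than benign ones — all separating at p « 0.001 — and cellularity is the
strongest single discriminator (AUC 0.967 in this replicate), mirroring the
clinical finding the phantom is built to emulate.

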