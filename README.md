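# tumorhab

Habitat-informed forecasting of breast-tumor response to neoadjuvant
chemotherapy from multiparametric MRI, built around a mechanically coupled
reaction–diffusion model and exercised end to end on synthetic virtual
patients with known ground truth.

## The problem

Predicting which breast-cancer patients will respond to pre-surgical
chemotherapy from imaging acquired early in treatment is a calibration
problem: fit a biological growth-and-kill model to the first two MRI
visits, then run it forward.  The proliferation rate can be fitted as one
value per tumor (cheap, spatially blind), one per voxel (expressive,
expensive, prone to overfitting), or — the middle ground studied here —
one per *habitat*: a cluster of voxels with similar longitudinal imaging
features.  This package implements the full analysis for researchers in
image-based tumor forecasting: imaging-derived maps, cohort habitat
clustering, PDE calibration at all three granularities, forecasting, and
the statistical comparison machinery.

## The model

Tumor cell number N(x,t) per voxel (carrying capacity θ from sphere
packing) evolves as

    ∂N/∂t = ∇·(D∇N) + k(x) N (1 − N/θ) − α N C(x) Σᵢⱼ exp(−βⱼ(t − τᵢⱼ))

with cell diffusivity damped by von Mises tissue stress,
D = D₀ exp(−γ σ_vm), σ_vm from linear-elastic equilibrium with an
isotropic tumor-expansion load.  Inputs come from imaging: N via the
ADC–cellularity inversion N = θ(ADC_w − ADC)/(ADC_w − ADC_min) of
two-b-value diffusion MRI, and the drug-delivery map C(x) from the
normalized area under the dynamic contrast-enhanced (DCE) curve.
Habitats are k-means clusters of the pooled voxel vectors
{ADC(V1), ADC(V2), Q(V1), Q(V2)}, Q ∈ {MSI, PEI, SER}.  k(x) (global /
per-habitat / per-voxel) and a global α are fitted to the visit-1 → visit-2
change by Levenberg–Marquardt and the model is run to visit 3.

See `docs/methods.md` for every equation, default, and design choice.

## Worked example

```python
import numpy as np
from tumorhab import phantom, pipeline, calibration

# one noiseless virtual patient on a small grid
cfg = phantom.PhantomConfig(grid_shape=(20, 20, 10),
                            tumor_semiaxes_mm=(4.0, 4.0, 3.5),
                            breast_semiaxes_mm=(8.5, 8.5, 6.0),
                            stress_interval_days=7.0, dt_days=0.5, seed=7)
patient = phantom.generate_virtual_patient(cfg)
feats = pipeline.compute_patient_features(patient)

study = pipeline.StudyConfig(phantom=cfg, dt=0.5, stress_interval=7.0)
problem = pipeline.build_problem(
    patient, feats, "habitat", study,
    habitat_map=patient.ground_truth["region_labels"])
fit = calibration.levenberg_marquardt(problem)

true_k = [a.k for a in cfg.region_archetypes[:3]]
print("fitted k per habitat:", np.round(fit.k, 4))
print("true k per region:   ", np.round(true_k, 4))
print("fitted alpha:", round(fit.alpha, 4), " true:", cfg.alpha)
```

prints

```
fitted k per habitat: [0.15  0.12  0.002]
true k per region:    [0.15  0.12  0.002]
fitted alpha: 3.0  true: 3.0
```

— on noiseless data the three per-region proliferation rates (day⁻¹) and
the drug efficacy (day⁻¹) are recovered exactly, because the virtual
patient's follow-up visits were produced by the same forward model the
calibration inverts.  Measurement noise, within-region heterogeneity, and
per-patient parameter jitter (used by `phantom.generate_cohort`) make the
inverse problem progressively harder; the analysis scripts quantify how
each calibration scheme degrades.

## The analysis

Numbered drivers under `analysis/` run the study at desk scale and write
tables under `results/`:

1. `01_generate_cohorts.py` — a noiseless recovery cohort (10 patients,
   32×32×16) and a noisy comparison cohort (12 patients, 20×20×10).
2. `02_habitats_and_connectivity.py` — cohort habitat maps for H = 2..4
   and their spatial-contiguity diagnostics.
3. `03_parameter_recovery.py` — habitat-scheme calibration against known
   per-region rates.
4. `04_scheme_comparison.py` — global / habitat / local calibration of the
   noisy cohort, V3 prediction, error and efficiency tables.
5. `05_evaluation_report.py` — optimal habitat count (Kolmogorov–Smirnov
   procedure), scheme tests, response ROC with DeLong comparisons.

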