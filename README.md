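# compartdwi

Compartmentalized diffusion-weighted MRI (DWI) modelling for breast lesion
characterization: voxel-wise fitting of the mono-exponential, intravoxel
incoherent motion (IVIM) and restriction spectrum imaging (RSI) signal
models to multi-b-value DWI, synthetic phantom/cohort generation,
inter-observer agreement metrics, and the group-comparison / ROC /
cross-validated logistic-model statistical layer.

## Who this is for

Researchers in quantitative diffusion MRI who want a tested, scriptable
implementation of the three standard compartmentalized analyses of breast
DWI — and a synthetic data generator with realistic class structure
(malignant / benign / normal fibroglandular tissue) for validating such
pipelines when patient data are unavailable.

## The models

For a voxel signal S_b acquired at diffusion weighting b (s/mm²):

- **Mono-exponential**: S_b/S₀ = exp(−b·ADC), estimated from the (0, 750)
  b-value pair.
- **IVIM (bi-exponential)**:
  S_b/S₀ = (1−f)·exp(−b·Dt) + f·exp(−b·(Dt+Dp)),
  with tissue diffusivity Dt, pseudo-diffusion Dp and perfusion fraction
  f ∈ [0, 1]; fitted on b ≤ 1000 with a bounded trust-region least-squares
  solver started from a segmented (log-linear tail) estimate.
- **RSI (three fixed-diffusivity compartments)**:
  S_b = C₁ + C₂·exp(−b·1.4×10⁻³) + C₃·exp(−b·10.2×10⁻³),
  restricted / hindered / free-water pools; linear in the contributions
  C_i ≥ 0, fitted on all nine b-values (0–2000). Signal fractions
  F_i normalize the contributions at b = 0 so F₁+F₂+F₃ = 1; the products
  C₁C₂ and F₁F₂ are derived markers.

The statistical layer compares the 12 fitted parameters across tissue
classes (Kruskal–Wallis; pairwise Mann–Whitney at α = 0.0167), evaluates
per-parameter ROC curves with Youden-threshold operating points, fits
unpenalized logistic diagnostic models (ADC / IVIM / RSI / IVIM+RSI) under
stratified five-fold cross-validation, and compares AUCs with the DeLong
test. Reader agreement is quantified by Dice/recall/precision and the
two-way random-effects absolute-agreement ICC.

## Worked example

Fit the IVIM model to 200 simulated voxels of a malignant-class lesion
(Dt = 0.662×10⁻³ mm²/s, Dp = 0.022 mm²/s, f = 0.235) at SNR 50:

```python
import numpy as np
from compartdwi import DEFAULT_SCHEME, IVIMParams, ivim_signal, add_rician_noise
from compartdwi.fitting import IVIMModel

truth = IVIMParams(dt=0.662e-3, dp=0.022, f=0.235)
clean = np.asarray(ivim_signal(truth, 2.527, DEFAULT_SCHEME.array))
signals = add_rician_noise(np.tile(clean, (200, 1)), snr=50, seed=0)
print(IVIMModel(signals).fit().summary())
```

```
IVIM fit results
========================================
voxels fitted:        200
converged:            200
flagged:              2
median residual norm: 3.084e-02
----------------------------------------
parameter           mean          SD
dt            0.00066223  7.4603e-05
dp              0.028153    0.048452
f                0.23528    0.034624
```

The batch mean recovers Dt and f essentially unbiased; Dp is the
noisiest parameter (its exponential has decayed by b ≈ 250), which is the
expected behaviour of the joint IVIM fit. Cross-validated diagnostic
models over a simulated cohort:

```python
from compartdwi import generate_cohort
from compartdwi.stats import model_comparison_report

cohort = generate_cohort(n_malignant=30, n_benign=20, n_normal=0,
                         voxels_per_lesion=20, snr=50, seed=0)
rep = model_comparison_report(cohort, ("malignant", "benign"), folds=5, seed=0)
for name, m in rep["models"].items():
    print(f"{name:<10} mean CV AUC = {m['mean_auc']:.3f}")
```

```
ADC        mean CV AUC = 0.792
IVIM       mean CV AUC = 0.758
RSI        mean CV AUC = 0.775
IVIM+RSI   mean CV AUC = 0.750
```

Each AUC is the mean over the five held-out folds; at this small cohort
size the model ranking is dominated by cross-validation noise (the DeLong
test on the pooled out-of-fold scores returns p = 0.83 for ADC vs
IVIM+RSI).

## Command line

```bash
compartdwi simulate --config config.yaml --out outputs     # phantom + cohort
compartdwi fit outputs/phantom_dwi.nii.gz outputs/phantom_dwi.bval \
    --model ivim --mask outputs/mask_lesion_00.nii.gz --out maps
compartdwi analyze outputs/cohort.csv --out reports        # tables + CV models
```

Volumes are NIfTI with FSL-style `.bval` sidecars; lesion tables are CSV;
reports are CSV/JSON. Every stage writes a manifest with the config hash
and seed.

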