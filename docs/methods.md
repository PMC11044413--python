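# Methods

## Signal models and units

All diffusivities are carried internally in mm²/s; only the reporting
layer rescales ADC and Dt to the ×10⁻³ mm²/s display convention. This
removes an entire class of unit errors between fitting, simulation and
statistics.

Three forward models describe a voxel's decay over the nine-point b-value
scheme {0, 50, 100, 250, 500, 750, 1000, 1500, 2000} s/mm²:

* mono-exponential, S_b/S₀ = exp(−b·ADC);
* IVIM bi-exponential, S_b/S₀ = (1−f)exp(−b·Dt) + f·exp(−b·(Dt+Dp));
* RSI three-compartment, S_b = Σᵢ Cᵢ·exp(−b·ADCᵢ) with fixed
  diffusivities (0, 1.4×10⁻³, 10.2×10⁻³) mm²/s — the breast-specific
  restricted / hindered / free-water triple. The zero-diffusivity
  exponential is evaluated as an explicit constant 1, so there is no
  0·∞ edge case at any b.

Signal fractions are the contributions divided by the b = 0 signal and
renormalized so F₁+F₂+F₃ = 1 exactly; because of the renormalization the
fractions depend only on the contribution ratios. The composite markers
C₁C₂ and F₁F₂ are computed per voxel and then averaged over the ROI, not
taken as products of ROI means: group descriptives of F₁F₂ in published
breast cohorts differ from mean(F₁)·mean(F₂), consistent with per-voxel
products. This is a documented choice, not an assertion about how any
particular study computed them.

## Fitting

**Mono-exponential.** ADC = ln(S₀/S₇₅₀)/750, the exact two-point
inversion; with two points the least-squares line coincides with the
closed form. Negative estimates (possible under noise) are clipped to 0
and flagged. Whether a published analysis used all b-values or the
(0, 750) pair is usually ambiguous; the two-point definition is
implemented literally here.

**IVIM.** Fitted on the normalized signal S_b/S₀ over b ≤ 1000 (the
perfusion term is fully decayed above that, and the two models' b-lists
are deliberately different). The joint problem is ill-conditioned, so the
solver is started from a segmented estimate: a log-linear regression over
b ≥ 250 gives Dt⁰ and an extrapolated intercept A, f⁰ = clip(1−A, 0.01,
0.6), Dp⁰ = 0.02 mm²/s. Refinement uses `scipy.optimize.least_squares`
(trust-region reflective with analytic Jacobian) under the box
Dt ∈ [10⁻⁵, 3×10⁻³], Dp ∈ [10⁻³, 0.5], f ∈ [0, 1]; tolerances 10⁻¹⁴,
at most 500 function evaluations. Non-convergence returns the best
iterate flagged. A fitted f ≤ 0.01 flags Dp as non-identifiable (the
perfusion term carries no signal); estimates pinned at a bound are
flagged `at_bound`. The optimum is verified in tests against a dense
50×50×50 grid search over the box: the solver's residual norm is never
worse than the best grid point.

**RSI.** Fitted on the raw signal over all nine b-values. With the
diffusivities fixed the model is linear in (C₁, C₂, C₃); the same bounded
solver is used (non-negativity enforced — contributions are physically
non-negative) and is required, in tests, to agree with an independent
non-negative least-squares solution to 10⁻⁶ relative on every voxel.
Nine equations, three unknowns, full-rank design: noiseless recovery is
exact.

Unfittable voxels (S₀ ≤ 0, all-zero signal, fewer than 4 usable b-values)
carry a NaN sentinel that propagates through maps and is excluded from
ROI statistics.

## Synthetic data

The generator replaces patient data with surrogates having the published
class structure. Three tissue classes (malignant, benign, normal
fibroglandular) carry generative means and SDs for (Dt, Dp, f, C₁, C₂,
C₃), transcribed from group descriptives of a breast multi-b-value DWI
cohort; the benign C₂ SD is printed ambiguously in that table
("1.00080") and 1.000 is used. Per-lesion truths are drawn from
Gaussians truncated to the fitting bounds (rejection sampling), so every
lesion is fittable by construction; all oracle calculations treat the
truncated Gaussian as the stated distribution (truncation at 0 shifts
the mean of C₃ noticeably — the tests use the closed-form truncated
moments, not the raw ones).

Each voxel's noiseless signal is the IVIM curve scaled so its b = 0
amplitude equals C₁+C₂+C₃. ADC, fractions and products are *emergent* —
always obtained by fitting, never drawn — keeping one self-consistent
signal per voxel across all three fitted models. A consequence worth
stating plainly: a bi-exponential curve does not lie in the fixed-rate
three-compartment family, so the RSI fit of a noiseless voxel converges
to the non-negative least-squares *projection* of its curve rather than
to the drawn contributions. Round-trip tests therefore assert exact
recovery for ADC/Dt/Dp/f and agreement with the NNLS projection for the
RSI maps; the drawn contributions act as class-separating amplitude
parameters. Similarly, the emergent ADC distribution is close to, but
not identical with, the published ADC descriptives (ADC ≈ Dt +
ln(1/(1−f))/750 under this law), which is why the closed-form
two-Gaussian AUC oracle is checked with a ±0.05 band.

Within-lesion heterogeneity is a 5% multiplicative jitter on the drawn
parameters (configurable). Noise is Rician — sqrt((S+n₁)² + n₂²) with
independent Gaussian channels of SD S₀/snr — the magnitude-MRI noise
law; default SNR 50 at b = 0, typical of breast DWI. Phantoms are
spherical lesions on a uniform background grid; a second reader is
emulated by flipping ROI boundary voxels (inner and outer 6-connected
shells) with a given probability. Everything is a pure function of
(specification, seed).

What the generator does **not** emulate: acquisition physics (EPI
distortion, eddy currents, fat saturation, coil profiles), spatially
correlated noise, non-mass lesion morphologies, partial-volume mixing at
lesion boundaries, and T2/proton-density weighting of the compartment
amplitudes. Passing tests therefore validate the estimators and the
statistical machinery under the stated generative law — not the clinical
performance of these models on scanner data.

## ROI analysis and agreement

ROI summaries are arithmetic means over in-mask non-sentinel voxels (the
per-lesion reduction is a documented choice; group descriptives are
conventionally reported as mean ± SD). Overlap between readers uses
Dice = 2|A∩B|/(|A|+|B|), with recall and precision oriented by reader A
as the reference. The ICC variant is two-way random effects, absolute
agreement, single measures — the standard choice for two interchangeable
raters (computed via pingouin); agreement bands follow the conventional
cut-points (0.81–1.00 excellent, 0.61–0.80 good, 0.41–0.60 moderate,
0.21–0.40 fair, ≤0.20 slight). The absolute-agreement form is
scale-sensitive, so no rescaling invariance is claimed.

## Statistics

Omnibus comparisons across the three classes use the tie-corrected
Kruskal–Wallis test at α = 0.05; pairwise comparisons use the two-sided
Mann–Whitney U test at α = 0.0167 (0.05/3, guarding the three pairwise
contrasts). The U test enumerates the exact null when n₁·n₂ ≤ 400 and
the data are tie-free; otherwise it uses the normal approximation with
tie-corrected variance and a continuity correction — the correction is
what keeps the exact and approximate p-values within 0.01 of each other
at n ≥ 15 and the null rejection rate at its nominal level (both
verified by simulation in the tests).

Per-parameter ROC curves are empirical over all thresholds; AUC is the
trapezoidal area and equals the normalized Mann–Whitney statistic
U/(n₁n₂) (asserted to 10⁻¹²). The direction is auto-chosen so AUC ≥ 0.5
and reported with its `> / ≤` convention; the operating threshold
maximizes Youden's J and is placed midway between the decision value and
the nearest lower observation.

Diagnostic models are unpenalized maximum-likelihood logistic
regressions over the feature sets ADC, (Dt, Dp, f), the eight RSI
parameters, and their union. Evaluation is stratified five-fold
cross-validation with features standardized on each training split only
(no leakage); the fold assignment is shuffled once from the run seed and
recorded. Separation-induced non-convergence is reported, not silently
regularized away. The DeLong comparison of cross-validated models is
applied to the pooled out-of-fold scores (per-fold AUC lists are also
exported); for single parameters it applies directly. The DeLong
estimator uses placement values; its type-I error is Monte-Carlo
verified at the 5% level.

Stratification requires at least 2·k lesions per class for k folds;
smaller contrasts are reported without CV models.

## Problem sizes and determinism

The shipped tests and the acceptance script run at deliberately modest
sizes chosen to exercise every code path while staying quick on a
laptop: 1,000-voxel fitting batches, 5×5×5 noiseless round-trip grids
spanning the class means ± 2 SD, 2,000/500 null simulations for the
calibration checks, and one full cohort at the emulated study sizes
(116/41/41 lesions, 50 voxels per lesion). Every stochastic stage takes
an explicit seed; cohort generation is byte-reproducible given its
arguments.

## Known limitations

* The IVIM fit is a single joint refinement from one segmented start; a
  multi-start strategy would be more robust in pathological corners of
  the parameter box (the grid-search dominance test bounds how much this
  can matter).
* Dp is weakly identified at low SNR or low f; flags communicate this
  but no Bayesian shrinkage is attempted.
* The generative law cannot make both the IVIM and the RSI fits recover
  drawn parameters exactly (see above); RSI-parameter group contrasts in
  synthetic cohorts are driven by amplitude and curve-shape differences
  and should not be read as calibrated to published RSI descriptives.
* ICC confidence intervals are reported at the 2-decimal resolution of
  the underlying library.
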