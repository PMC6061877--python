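# Methods

## The model

A tumor's diffusion MRI data enter the analysis as a paired histogram
`H(ADC, t)`: voxelwise apparent diffusion coefficients (ADC, mm²/s) binned
on a shared grid, with one column per imaging time point (baseline, i.e.
pre-treatment, and a post-treatment scan at 72 h). Spatial structure is
deliberately discarded; the unit of information is the joint distribution of
ADC across the two time points.

The linear Poisson model describes a cohort of such histograms as a
non-negative linear combination of shared probability mass functions (PMFs):

    H_i(ADC, t) ~ Poisson( Σ_k P_k(ADC, t) · q_ik )

Each component `P_k` is a non-parametric PMF over the B×2 grid summing to
one, interpretable as one mode of tissue behavior (its baseline ADC profile
and where that tissue's ADC moves by 72 h). The quantity `q_ik ≥ 0` is the
expected number of voxels of tumor `i` attributed to component `k`. The
extended Poisson likelihood

    ln L = Σ_i Σ_cells H_i ln M_i − Σ_i Σ_k q_ik,   M_i = Σ_k P_k q_ik

treats each tumor's total expected count as fitted, so at any maximum
Σ_k q_ik equals the observed voxel count.

Training is two-staged. Control components are learnt from the control
cohort alone. Treatment components are then learnt from the treated cohort
with the control PMFs frozen, so they can only describe variability the
control model cannot express. A treated tumor's responding volume is the sum
of its treatment quantities Σ_T Q_T — a lower bound on the truly responding
tissue, since response indistinguishable from control variation is credited
to the control components.

## EM, initialization, and identifiability

The EM updates coincide with the multiplicative updates of non-negative
matrix factorization under generalized Kullback-Leibler divergence, using
one set of responsibilities per iteration (jointly updating quantities and
free PMFs), which keeps the likelihood monotone. Convergence is declared at
a relative log-likelihood change below 1e-8 (cap 2000 iterations; both
configurable and recorded in the training metadata). The best of `restarts`
(default 5) seeded initializations is kept; ties go to the earliest restart.

Two identifiability measures matter in practice and are deliberate design
choices of this package:

* **Control-stage initialization.** Flat random PMF initializations tend to
  converge to duplicated blends of the true modes, which narrows the cone of
  histograms the control model can express and lets later stages
  misattribute control behavior to treatment. Components therefore start as
  quantile-spaced Gaussian bumps along the ADC axis (positions jittered per
  restart), reflecting the domain prior that tissue sub-populations are
  unimodal in ADC.

* **Treatment-stage support restriction.** Radiotherapy is delivered after
  the baseline scan, so treatment-specific behavior can only surface in the
  post-treatment column; at baseline, treated and control tumors are
  exchangeable by randomization. Accordingly, a treatment component's
  post-column support is restricted to cells where the treated cohort shows
  a significant excess over control-only fits (pooled signed residual above
  `support_sigma` — default 2 — times its Poisson scale); multiplicative EM
  preserves exact zeros, so the support never regrows. The baseline column
  stays unrestricted. Without this restriction the treatment components
  slowly absorb shared noise and control-model generalization error, which
  inflates responding volumes (by several percentage points of tumor volume
  in simulation at 10⁴ voxels) and mis-calibrates null studies. Initial
  treatment PMFs are randomized splits of the positive pooled residual.

After the treatment stage, any control mixture that is elementwise-feasible
inside a fitted treatment PMF is stripped by a small linear program and
moved into the control quantities. This leaves every model histogram — and
hence the likelihood — exactly unchanged; among likelihood-equivalent
solutions it selects the minimal-treatment-quantity representative,
matching the lower-bound semantics of the responding volume.

Quantity-only fits of a trained model to a single histogram (used for every
reported per-tumor statistic) maximize a concave objective, so EM reaches
the global optimum; they agree with an independent Nelder–Mead optimization
of the same objective to better than 1e-4 relative in the test suite.

## Goodness of fit and model order

Fit quality is the variance-stabilized chi-square per degree of freedom

    χ²_D = (1/D) Σ_cells (√H − √M)² / (1/4)

The square roots turn Poisson counts into approximately Gaussian variables
with variance 1/4, so χ²_D is near one for a correct model. Cells empty in
both data and model are excluded; `D` subtracts the free parameters —
`K(n_cells − 1) + K·S` for shared training, `K` for a frozen-PMF fit (this
counting rule is a package convention, recorded in every report).

Component counts are selected by scanning candidate orders and minimizing
the *held-out* χ²_D under leave-one-out cross-validation (each tumor
excluded from PMF training, then quantity-fitted); the in-sample curve is
reported alongside. Orders within 1% of the minimum are tied and resolved
toward the smaller order. In simulations with three well-separated control
components the true order is recovered in essentially every replicate.

## Error propagation

At a frozen-PMF optimum the quantities satisfy score equations whose
implicit differentiation gives the sensitivities ∂Q/∂H of the fitted
quantities to each histogram cell. Assuming independent Poisson cell errors
with σ²_H = max(H, 1) (the floor prevents empty cells from being treated as
noiseless), the quantity covariance is

    C = s · Σ_cells (∂Q_i/∂H)(∂Q_j/∂H) σ²_H

The scale `s` is the fit's χ²_D clamped at ≥ 1: a poor fit inflates errors,
an over-good fit is not allowed to shrink them. Three derivative routes are
provided: `analytic` (implicit differentiation; the default), 
`finite_difference` (central differences re-running the quantity fit with
each cell perturbed by δ = max(1, 0.01·H); the independent check), and
`full_training_propagation`, which additionally perturbs every occupied
training-cohort cell and re-runs both EM stages warm-started from the
converged solution, capturing the systematic error of learning the PMFs.
The full mode runs all perturbed retrains as one batched, vectorized EM with
an unperturbed reference per stage (so residual convergence drift cancels
in the one-sided differences), making it cheap enough for routine use; its
warm-retrain horizon (300 iterations at relative tolerance 1e-9) measures
the local response and deliberately excludes slow drift along
likelihood-flat directions, which is not identifiable from the data. The
Monte-Carlo resampling oracle in the test suite checks the analytic
diagonal to within 25%.

Per-tumor outputs are the responding fraction `effect = 100·ΣQ_T/ΣQ` with a
delta-method error from `C`, and `Z = ΣQ_T / sd(ΣQ_T)` with
`sd(ΣQ_T) = √(1ᵀ C_TT 1)` including off-diagonal terms. When every
treatment quantity is pinned at zero the response is reported as Z = 0.

## Cohort statistics and validation

Per-tumor Z-scores are combined across a cohort by root sum of squares; the
null distribution of that statistic is chi with k degrees of freedom, so the
combined p-value is the χ²_k tail of ΣZ². This combination rule reproduces
the published combined values of both cohorts from their per-tumor entries.
All p-values are two-tailed normal probabilities; text outputs print values
below 1e-6 as "<0.000001".

The null-hypothesis validation fits the fully trained model (control plus
treatment components) to the control cohort: control tumors must show
treated quantities consistent with zero, and in simulated null studies they
do (|Z| < 2 throughout, mean Z ≈ 0.1–0.3). Leave-one-out validation
retrains both stages with each control tumor excluded and re-assesses it as
an independent sample; a held-out Z ≥ 2 flags the tumor as a potential
outlier, which is reported but never removed. Note the asymmetry that the
test suite documents: tumors *inside* the treatment-stage training cohort of
a null study can show inflated Z under the default frozen-PMF errors,
because the treatment components were fitted to that same cohort's noise;
the validation design above (control tumors, held out of treatment
training) is the calibrated null check, exactly as the leave-one-out
machinery is the calibrated check for control tumors.

The conventional benchmark arm applies equal-variance two-sample Student
t-tests (Welch behind a flag) to the three per-tumor summary changes —
volume, mean ADC, IQR (75th − 25th percentile, linear-interpolation
convention) — converts each two-tailed p to a signed normal-quantile Z, and
combines the three by the same root-sum-square rule.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
tumor biology. Control components are truncated-Gaussian ADC profiles with
baseline means spread over 0.75–1.35×10⁻³ mm²/s and a small upward drift at
72 h (growth); treatment components pair a normal-looking baseline column
with a post column centered at 1.9–2.45×10⁻³ mm²/s, placing ≥ 60% of their
post mass above the control post mode (therapy elevates ADC). Tumor
compositions over control components are Dirichlet(5) draws — moderate
between-tumor heterogeneity; treated tumors assign a specified responding
fraction (default 0.4, mid-range of responding volumes reported for
effective single-dose radiotherapy) to the treatment components. Counts are
independent Poisson draws per cell with an expected budget of 15,000 voxels
per tumor per time point (roughly a 300–400 mm³ tumor at a preclinical
acquisition's voxel size); simulation-heavy tests and the acceptance script
use 10,000. Presets mirror two small-study designs: `lovo_like`
(8 controls + 10 treated; 3 + 2 components) and `hct116_like`
(13 + 15; 4 + 5).

What passing simulations do not show: real tumors violate the shared-PMF
assumption (each tumor's modes differ slightly), segmentation and motion
introduce non-Poisson noise, and true responding fractions vary across
tumors. Synthetic recovery quality is therefore an upper bound on real-data
performance.

## Numerical choices and limitations

* Logarithms of the model histogram are floored at 1e-12 during iteration;
  cells empty in both data and model are skipped in all statistics.
* Histogram bins are half-open with the last bin closed; out-of-range ADC
  values are clipped into the edge bins with a logged warning (volume
  conservation over silent loss).
* The default binning (64 uniform bins over [0, 3.0]×10⁻³ mm²/s) covers
  free water at body temperature with resolution well below typical
  distribution widths.
* Degenerate inputs fail loudly: empty histograms, missing time points,
  more components than non-empty cells, over-parameterized χ² reports.
* The responding volume is a lower bound by construction; if the control
  cohort under-represents control variation, residual control behavior in
  treated tumors is attributed to treatment. The support restriction and
  purification reduce, but cannot eliminate, this at very small control
  cohorts.
* Voxel-level response maps are out of scope: the model fits distributions,
  not voxel correspondences.
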