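# lpmadc

Linear Poisson modeling of paired tumor ADC histograms: per-tumor
quantification of the volume of tissue responding to therapy from
diffusion-MRI data, with calibrated errors at preclinical sample sizes.

## The problem

In small imaging studies (8–15 tumors per arm), biological heterogeneity in
the control group can swamp real treatment effects: conventional analysis
reduces each tumor's apparent diffusion coefficient (ADC) distribution to a
few summary numbers (volume, mean, interquartile range) and compares groups
with t-tests, discarding the shape of the distributions and making
per-tumor response calls impossible. This package implements an alternative
for researchers running such studies: model the full paired histogram
`H(ADC, t)` of each tumor (ADC binned at baseline and at a post-treatment
scan) as a non-negative linear combination of shared probability mass
functions,

    H_i(ADC, t) ≈ Σ_C P(ADC, t | C) Q_Ci + Σ_T P(ADC, t | T) Q_Ti

where control components `C` are learnt from untreated tumors, treatment
components `T` are learnt afterwards from the treated cohort with the
control components frozen, and the quantities `Q` are expected voxel
counts fitted per tumor under the extended Poisson likelihood

    ln L = Σ_i [ Σ_cells H_i ln(Σ_k P_k Q_ki) − Σ_k Q_ki ].

A tumor's responding volume is `Σ_T Q_T`; dividing by its propagated 1-SD
error gives a per-tumor Z-score, and `100·Σ_T Q_T / Σ Q` is the responding
fraction in percent. Component counts are chosen by minimizing the
variance-stabilized χ² per degree of freedom, `(1/D) Σ (√H − √M)²/(1/4)`,
under leave-one-out cross-validation. Per-tumor Z-scores combine across a
cohort as `√(Σ Z²)`. Leave-one-out retraining of the control model flags
outlier control tumors, and a conventional t-test arm (volume, mean ADC,
IQR changes) provides the benchmark comparison. See `docs/methods.md` for
the full model description, error propagation, and design choices.

## Worked example

Simulate a small radiotherapy study (8 controls, 10 treated tumors, three
control + two treatment components, 40% of each treated tumor's volume
responding) and run the full pipeline:

```sh
lpmadc simulate --preset lovo_like --seed 1 --voxels 10000 --out study/
lpmadc run-all --data study/ --seed 1 \
    --n-control-components 3 --n-treatment-components 2 --out results/
```

which prints (abridged):

```json
{
  "conventional": {
    "combined_p": 1.3717818427219732e-22,
    "combined_z": 10.242156254550524
  },
  "leave_one_out": { "flagged": [] },
  "lpm": {
    "control_mean_z": 0.0,
    "treated_combined_p": 0.0,
    "treated_combined_z": 220.8256513471046
  }
}
```

`results/treated_responses.csv` holds the per-tumor table (Z, two-tailed P,
responding volume % and its 1-SD error %); its first row here reads
`T1, z=71.8, p<0.000001, effect 40.29%, error 0.48%` — the simulated
tumor's true responding fraction (40%) recovered within error. Control
tumors fitted with the same full model (`control_responses.csv`) show
responses consistent with zero (every Z rounds to 0.0), the conventional
t-test arm detects the effect only at cohort level (combined Z 10.2 versus
220.8 for the histogram model), and no control tumor is flagged as an
outlier by leave-one-out validation.

The same stages are available individually (`lpmadc simulate | histogram |
select | fit | respond | loo | benchmark`), and as library functions
(`lpmadc.em_fit_control`, `extend_with_treatment`, `fit_quantities`,
`select_order`, `quantity_covariance`, `analyze_cohort`, `leave_one_out`,
`conventional_arm`, ...).

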