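# batkinetics

Quantitative machinery for human studies of brown adipose tissue (BAT) and
lipid metabolism: stable-isotope tracer kinetics of VLDL-triglyceride,
VLDL-apoB and free fatty acids, BARCIST-1.0 BAT quantification on PET-CT,
and the two-group cohort statistics that connect them. It is written for
metabolic researchers who want a tested, scriptable alternative to the mix
of spreadsheet formulas, vendor imaging software and point-and-click
statistics such studies usually rely on — exercised end-to-end on seeded
synthetic data with known ground truth.

## What it computes

**Steady-state FFA kinetics.** During a constant [U-¹³C]palmitate infusion
(rate *F*, nmol/kg/min) the plasma palmitate rate of appearance is
*Ra = F·BW / TTR_plateau* with the plateau TTR averaged over a
configurable window (default 240–360 min), and plasma clearance is
*Ra / C_palmitate* (reported in L/h).

**VLDL-TG / VLDL-apoB compartmental kinetics.** The measured plasma
precursor enrichment (free glycerol after a bolus, free leucine during a
primed constant infusion) forces a chain of *n* identical first-order
hepatic delay compartments (rate *k*, default *n* = 4) feeding a single
plasma VLDL pool with fractional catabolic rate FCR (pools/h):

    dq₁/dt = k(e_p(t) − q₁),  dqᵢ/dt = k(qᵢ₋₁ − qᵢ),  de_v/dt = FCR(qₙ − e_v)

FCR and *k* are estimated by bounded weighted nonlinear least squares
(weights ∝ 1/TTR², three fixed starting points). Derived rates use the
steady-state identities: secretion = FCR × concentration × PV,
clearance = FCR × PV, with plasma volume PV = 0.055 L/kg fat-free mass.
The systemic share of VLDL-TG fatty acids is the plateau ratio of the
VLDL-bound to plasma-free palmitate TTR (isotopic dilution).

**BAT segmentation (BARCIST 1.0).** A voxel is BAT when its CT
radiodensity lies in the fat range (−190 to −10 HU, inclusive) and its
lean-body-mass normalised uptake SUV_LBM exceeds 1.2 g/mL scaled by
LBM/body mass (strict inequality). Metrics: volume, SUV_mean, SUV_max,
activity (volume × SUV_mean) and mean radiodensity.

**Cohort statistics.** Shapiro–Wilk-gated summaries (mean ± SD vs median
(Q1, Q3)), Student's t vs Mann–Whitney U between groups (exact for small
samples), paired t vs Wilcoxon signed-rank within group, Bonferroni
correction, Pearson vs Spearman correlation, OLS multivariable regression
with log-transformed predictors and standardized betas, and noncentral-t
sample-size estimation.

## Worked example

```python
from batkinetics import fit_fcr, derive_kinetics
from batkinetics.synthetic import generate_kinetic_subject

subject = generate_kinetic_subject(true_fcr=0.6, true_k_delay=1.5,
                                   noise_cv=0.05, seed=2)
fit = fit_fcr(subject.vldl, subject.precursor)
derived = derive_kinetics(fit.fcr_hat, concentration_mg_dl=29.8, ffm_kg=47.8)
print(fit.fcr_hat, derived.secretion, derived.clearance_ml_h)
```

prints (for this seed)

```
fitted FCR: 0.669 pools/h (converged=True)
plasma volume : 2.629 L  (0.055 L/kg FFM)
secretion rate: 524 mg/h
clearance rate: 1759 mL/h
```

i.e. a single noisy subject's estimated fractional catabolic rate, the
plasma volume implied by their fat-free mass, and the secretion and
clearance rates the identities derive from it. The `examples/` directory
holds one short script per capability (steady-state palmitate, FCR
fitting, BAT segmentation, cohort statistics, full study run), and the
`batkinetics` command exposes the same stages from a shell
(`batkinetics run --seed 1 --calibrate --out results/`).

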