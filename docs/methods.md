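# Methods

## Steady-state palmitate kinetics

A constant tracer infusion at rate *F* (nmol/kg/min) into a pool at
steady state yields, once enrichment plateaus, Ra = F·BW / TTR_plateau.
The plateau is the arithmetic mean of all TTR samples inside a window,
by default 240–360 min after the glycerol bolus (i.e. hours 8–10 of the
palmitate infusion, the protocol's designated steady-state interval); all
samples in the window are used, not only the hourly ones. Steadiness is
judged by the sample coefficient of variation of the in-window points
with a 10% tolerance; exceeding it sets a warning flag on the result
rather than raising, since a drifting plateau biases but does not
invalidate the estimate. Clearance = Ra / concentration, converted
μmol/min ÷ μmol/mL → mL/min → L/h. Both quantities are definitional, so
the tests assert the algebraic identities (Ra × plateau = F·BW;
clearance × concentration = Ra) to machine precision.

## Compartmental VLDL model

The literature describes VLDL tracer models at varying levels of detail;
this package fixes one canonical, identifiable structure:

* the measured plasma precursor TTR (free glycerol or free leucine) is a
  piecewise-linear forcing function — the precursor pool is measured, not
  modelled;
* a chain of `n_delay` identical first-order compartments with shared
  rate `k_delay` (1/h) represents hepatic assembly/secretion delay;
  `n_delay = 4` is the conventional delay-chain order for VLDL models and
  is configurable in {1..6}, with optional selection by residual weighted
  SS (off by default);
* a single plasma VLDL pool turns over with the fractional catabolic
  rate FCR (pools/h). All states start at zero at the bolus (t = 0);
  pre-bolus samples are excluded from fits.

Because the system is linear with piecewise-affine forcing, each
inter-knot interval is propagated *exactly* with one matrix exponential
of the augmented system (state ⊕ elapsed-time ⊕ constant). This removes
integration error as a confounder of the fit: the unit tests compare the
propagator against an independent adaptive stiff integration
(`solve_ivp`, Radau, rtol 1e-10) and agree to better than 1e-6 relative.

Fitting is bounded nonlinear least squares over (FCR, k_delay), bounds
[1e-3, 1e2] on both, from three fixed starting points ((0.2, 1.0),
(0.8, 2.0), (2.0, 0.8)) keeping the lowest weighted SS; parameter
tolerance 1e-8. Weights are 1/max(TTR, 1e-4)² — constant relative error,
the standard assumption for GC/MS enrichment measurements; the floor
prevents near-zero early samples from dominating. A fit at a bound is
flagged; optimiser failure returns `converged=False` with diagnostics
instead of raising. A covariance proxy is computed as
WSS/(n−2) · (JᵀJ)⁻¹; the Monte-Carlo spread of estimates agrees with it
within a factor of two in the tests.

Derived quantities are definitions, asserted exactly: plasma volume
0.055 L/kg fat-free mass; secretion = FCR × concentration (mg/L) × PV;
clearance = FCR × PV (also reported in mL/h). The apoB model reuses the
same topology with the leucine precursor; the priming dose only matters
to the synthetic generator (it puts the precursor on its plateau).

The systemic/non-systemic fatty-acid partition is implemented as the
plateau ratio of VLDL-bound to plasma-free palmitate TTR. A model-based
dilution estimate would be a possible extension; the plateau ratio is the
transparent special case and is what the partition's identity tests pin
down (fractions sum to one; ratio clipped to [0, 1] with a flag).

## BAT segmentation

The BARCIST criteria are two voxelwise thresholds: HU ∈ [−190, −10] with
inclusive endpoints, and SUV_LBM strictly greater than
1.2 / (LBM / body mass). SUV_LBM uses grams of LBM in the dose
normalisation (activity · LBM·1000 / dose); the convention is isolated in
`suv_lbm` so a kg-based variant is a one-line change. No
connected-component filtering is applied by default (a 26-neighbour
minimum-cluster filter is available behind `min_cluster`); anatomic
bounds are an optional axial slab (`z_range`) — no anatomy detection is
attempted. Dose decay correction is assumed done upstream; a ¹⁸F
half-life helper (109.77 min) is provided but never applied implicitly.
Empty masks are valid outcomes: volume 0 with the intensive metrics
reported as undefined (`None`), never as 0.

## Cohort statistics

The normality gate is Shapiro–Wilk at α = 0.05, applied per group (or to
paired differences, or to each correlate). It is deterministic and
seed-free. Gated choices: mean±SD vs median (Q1, Q3); Student's t vs
Mann–Whitney U (exact when combined n ≤ 20 without ties, otherwise the
tie-corrected normal approximation); paired t vs Wilcoxon signed-rank —
the within-pair context reads "rank-sum" comparisons of paired data as
the signed-rank test; Pearson vs Spearman. Degenerate inputs are handled
explicitly: identical values across groups give p = 1 with a flag; an
exact constant paired shift has zero-variance differences and is flagged
rather than dividing by zero. Bonferroni uses m = number of tests in the
call unless given. Regression is OLS with natural-log transforms where
flagged (non-positive values are an error — no offset fudges), and
standardized beta = b·SD(x)/SD(y). The body-fat-distribution covariate is
the SAT:VAT mass ratio.

Sample size uses the exact noncentral-t power function with pooled SD
√((s₁²+s₂²)/2). For the pilot numbers sometimes quoted for this design
(1146 ± 432 vs 2016 ± 77.4 mL/h, power 0.8, α 0.05) this computation
gives n = 4 per group, not 10; the larger published figure is not
reproducible from the pooled-SD noncentral-t formula and is therefore
*not* hard-coded — the function returns the standard result.

## Synthetic data

The generators emulate the study protocols: sampling hourly from −4 h to
12 h plus 5/15/30/60/90/120 min post-bolus (21 unique times); palmitate
at 6 nmol/kg/min from −4 h; a biexponential glycerol precursor after the
75 μmol/kg bolus (defaults A₁ = 0.25, λ₁ = 0.05/min; A₂ = 0.08,
λ₂ = 0.004/min — a fast mixing phase over a slow turnover tail of
plausible bolus-TTR magnitude); a leucine plateau of 0.08 for the
primed-constant protocol; multiplicative log-normal TTR noise with unit
mean (default CV 5%, a typical GC/MS repeatability). The plasma palmitate
TTR approaches a plateau of 0.006 with a 20-min rise constant,
corresponding to a Ra of ≈80 μmol/min at the default body weight.

Cohorts follow the two-group characteristics table of the design being
emulated: log-normal BAT volume with group medians 2.6 and 72.9 mL
(log-SDs back-computed from the printed quartiles), log-normal VLDL-TG
(medians 53.3 / 29.8 mg/dL), roughly normal concentrations and
anthropometrics, and kinetic columns constructed so the clearance and
secretion identities hold exactly. Group labels are re-derived from the
20-mL BAT-volume rule. VLDL-TG FCR group medians (0.45 vs 0.65 pools/h)
were chosen to put clearance in the low-thousands mL/h range with the
faster clearance in the high-BAT group; palmitate Ra is drawn identically
in both groups so concentration differences drive clearance differences.

An optional calibration mode rescales each group's skewed headline
variables so the *sample* medians equal the configured targets exactly
and shifts ages to the target group means — this is how "inject the
reference medians and reproduce the headline contrasts" is realised;
tail values crossing the 20-mL threshold after rescaling are nudged to
the correct side (medians sit far from the threshold, so they are
unaffected). Default draws are uncalibrated.

Phantoms guarantee exact recoverability: depot SUV_LBM is drawn at least
20% above the subject threshold, background uptake at least 20% below,
depot HU well inside the fat window, so segmentation equals the
implanted mask under floating point. Phantom realism is deliberately
limited to what the segmentation logic consumes (HU ranges, uptake
contrast); there is no scanner noise, partial-volume effect or anatomy.

Seeding is counter-based: every stream is
`SeedSequence(root_seed, spawn_key=(kind, group, index))`, so adding
subjects never perturbs earlier draws and identical configs are
byte-identical.

## What the tests do and do not show

Passing tests demonstrate internal correctness — the fit recovers known
parameters on the study's schedule (to 0.5% noise-free, <3% mean bias at
5% noise), segmentation equals brute-force voxel classification, the
statistical layer is calibrated under the null — on data generated by
the package's own forward models. They do not validate the delay-chain
topology against real VLDL tracer data, the phantom against real PET-CT
image statistics, or the cohort generator against biological covariance
structure (variables are drawn independently within subject apart from
the constructed identities).

## Problem sizes

Default test/acceptance sizes: 21-point schedules; 200 Monte-Carlo fit
replicates; 50 phantoms of 14×14×8 voxels (the default phantom is
24×24×12); 2,000 null simulations at n = 10 per group; cohorts of
11 + 14. These match the scale of the emulated study while keeping a
full run in seconds.

## Known limitations

Single VLDL pool (no VLDL1/VLDL2 cascade), no population/NLME fitting,
no Bayesian uncertainty; no Steele non-steady-state FFA equations; no
image registration or attenuation/scatter handling; figure generation is
out of scope (outputs are tidy CSV/JSON for external plotting).
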