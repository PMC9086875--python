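# boxcea

Trial-based cost-utility analysis of remote (eHealth) outpatient follow-up
versus regular in-office follow-up after acute myocardial infarction (AMI),
from the perspective of a cardiology department over a one-year horizon.

The package is aimed at health-economics analysts who want a reusable,
tested implementation of the full analysis chain for a two-arm trial with
per-item resource use, patient-reported utilities at a few timepoints, and
partially missing questionnaire data — plus a calibrated synthetic trial
generator, so the whole pipeline can be exercised, tested and taught
without access to patient-level data.

## The analysis

For each patient *i* in arm *a*, the department-perspective cost is a sum
over priced resource items (monitoring hardware, e-visits, in-office
visits, Holter, echocardiography, emergency visits, admissions,
catheterisations, revascularisations, allocated technical support):

  C_i = Σ_k  cost_ik        (2020 euros)

Health outcomes are one-year quality-adjusted life years from utilities
u(1), u(6), u(12) measured at months 1, 6 and 12 (1 = perfect health,
0 = as bad as dead), by the area-under-the-curve method with the month-1
value carried back to baseline:

  QALY_i = [ u(1)·1 + (u(1)+u(6))/2 · 5 + (u(6)+u(12))/2 · 6 ] / 12

Missing utilities are multiply imputed (m = 20 sequential Bayesian
regressions per arm, covariates: age, sex, STEMI/NSTEMI, log peak
troponin, earlier utilities) and arm estimates are pooled with Rubin's
rules. Uncertainty in the incremental pair (ΔC, ΔE) = intervention −
control is taken from a nonparametric bootstrap stratified by arm
(B = 1000, cycling over the imputed datasets). The cost-effectiveness
acceptability curve reports, for each willingness to pay λ per QALY,

  CEAC(λ) = P( λ·ΔE − ΔC > 0 )

estimated as the fraction of bootstrap pairs with positive net monetary
benefit. A sensitivity analysis widens the perspective with
patient-related costs: round-trip travel (2×7 km at €0.19/km), parking
(€3.20), 4.5 h lost per in-office visit and 0.5 h per e-visit valued at a
70/30 blend of €37.05 and €13.33 hourly wages, and 10 min/week of home
measurement time at the non-productive wage.

Because the original trial's patient-level records are not public, the
`synthetic_data` module generates trials (100 + 100 enrolled, 12/8 early
dropouts excluded by a modified intention-to-treat filter, leaving 88/92)
whose per-item two-part cost models and correlated utility trajectories
are calibrated to the published per-arm summary tables; see
`docs/methods.md` for the model and its limits.

## Worked example

```
$ boxcea run --seed 42 --out demo
run bundle written to demo
delta cost (intervention - control): -480 EUR  (p=0.14)
delta QALY: +0.071  (p=0.000)

$ boxcea report demo
run: seed=42 perspective=department B=1000 m=20
mean total cost: intervention 2290±1825 EUR, control 2770±2429 EUR
mean QALY intervention: 0.77
mean QALY control: 0.70
delta cost -480 EUR, delta QALY +0.071 (dominant)
CEAC minimum over grid: 0.935
```

This simulates one synthetic trial (seed 42), filters early dropouts,
costs every patient from the shipped unit-cost table, imputes missing
utilities 20 times, and bootstraps the incremental pair 1000 times. Here
remote follow-up costs €480 less per patient on average and yields 0.071
more QALYs, so it *dominates* regular follow-up; the cost difference alone
is not statistically significant (p = 0.14) — the typical pattern for this
analysis. The CEAC value means that at every willingness-to-pay level on
the 0–100,000 €/QALY grid, at least 93.5% of bootstrap replicates favour
the intervention. Any single simulated trial scatters around the
calibration targets (mean costs ≈ €2417 vs €2888, QALYs ≈ 0.74 vs 0.69);
seed-ensemble averages recover them.

The bundle directory contains `records.csv` (patient level),
`cost_summary.csv` (per-item per-arm mean ± SD with t-tests),
`qaly_summary.csv`, `incremental.csv` (ΔC, ΔE, CIs, ICER label, national
extrapolation), `ce_draws.csv` (the CE plane), `ceac.csv` and a
`manifest.json` with seed, versions and file hashes. The same stages are
available piecewise (`boxcea simulate | cost | qaly | cea | report`) and
as library functions; `--perspective combined` adds the patient-related
cost tables.

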