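# Methods

This note records the models, parameter choices and numerical conventions
behind the package, and what the synthetic-data calibration does and does
not establish.

## Study setting being emulated

A two-arm randomized trial in post-AMI patients: the intervention arm
received home monitoring devices (blood pressure, weight, single-lead ECG,
step count) and had two in-office outpatient visits replaced by video
e-visits; the control arm followed the standard four-visit protocol.
Analysis population is modified intention-to-treat: of 100 patients
enrolled per arm, 12 (intervention) and 8 (control) withdrew within two
weeks and are excluded, leaving 88 and 92. Costs are restricted to the
cardiology department (base case) over a one-year horizon, in 2020 euros;
a fixed €1 = US$1.0994 conversion is available for reporting.

## Synthetic trial generator

The generator's defaults are the study conditions; they reproduce the
published per-arm summaries in expectation and are not meant to be tuned
per run.

**Costs.** Each resource item follows a two-part (frequency × severity)
model per arm:

* *Deterministic* items — the monitoring kit (€318) and the allocated
  technical support ((15,367 + 1,758)/88 ≈ €195) — hit every intervention
  patient exactly once.
* *Scheduled* items (e-visits, in-office visits, Holter, transthoracic and
  stress echocardiography) are incurred by essentially all patients; the
  per-patient annual cost is gamma with the published per-arm mean and SD.
  These items are calibrated to the published per-patient cost column
  rather than to count × unit price, because the published counts, unit
  prices and per-patient means are mutually inconsistent for them (e.g.
  148 e-visits × €44 / 88 = €74 against a printed per-patient mean of
  €34). Integer visit counts are drawn separately — floor(mean count) plus
  a Bernoulli remainder, so scheduled-care counts have realistic low
  dispersion — and drive only the patient-related costs of the
  sensitivity analysis.
* *Event* items (emergency visits, admissions, catheterisations, single-
  and multi-vessel PCI) are Bernoulli(p) × gamma severity with
  p = published events / arm size, and the severity mean and SD solved in
  closed form so the per-patient mean and SD match the published values
  exactly in expectation (`solve_event_severity`). The solved severity
  means recover the published unit prices (≈€684/night admissions,
  ≈€2,085 catheterisations, ≈€6,000 single-vessel PCI), which is a useful
  internal consistency check. The published single-vessel PCI event counts
  only reproduce the published per-patient means when swapped between arms
  (4 intervention / 10 control); the generator uses the swapped counts.
* Items are drawn independently across patients and items. Real cost data
  correlate events within a patient (a PCI implies a catheterisation and
  an admission), so the synthetic arm-total SDs (~1,900/~2,600) sit
  somewhat below the published ~2,043/~2,961. Arm means are unaffected.

**Utilities.** (u1, u6, u12) are multivariate normal with exchangeable
correlation 0.6 and SD 0.18, clipped to [0, 1]. Clipping at the upper
bound would bias means downward by up to ~0.007, so the latent means are
numerically compensated (Brent root-finding on the closed-form clipped
mean) to make the post-clip marginal means equal the configured targets:
intervention (0.745, 0.740, 0.735), control (0.710, 0.685, 0.680). The
trapezoidal AUC of these triples is 0.740 and 0.691 — the published 0.74
and 0.69 — and the per-timepoint differences match the published −0.03 /
−0.05 / −0.05. Full rejection truncation was considered and dropped: at
mean ≈ 0.74 and SD 0.18 it shifts the mean by ≈ −0.03, which cannot be
compensated without distorting the correlation structure. The SD (0.18),
correlation (0.6) and 20% base missingness are plausible values for
SF-6D-type utilities in a cardiac population; they are defaults, not
published quantities.

**Missingness** is MAR: the per-timepoint deletion probability is the base
rate tilted by +0.004 per year of age above 60 and −0.3 per utility unit
of the most recent *observed* utility above 0.7, clipped to [0, 0.95].
This makes the imputation stage consequential (complete-case analysis is
biased toward healthier responders) while keeping the overall rate near
the configured 20%.

**Covariates** (age ~ N(59, 9.5²) clipped to [30, 90]; 78% male; 55%
STEMI; log-normal peak troponin) match the published population medians
where available and are otherwise conventional for a PCI-treated AMI
cohort. They feed the missingness model and the imputation model.

## Costing

Department costs are sums of per-item euro amounts; the shipped unit-cost
table carries each item's price year, and all amounts pass through a CPI
ratio to 2020 (a ratio of 1 for prices already in 2020 euros, keeping one
code path). Visit unit costs come from top-down micro-costing: hospital
components × 1.44 overhead for in-office visits; video-system subscription
/ 5,500 annual capacity × 1.22 overhead for e-visits. The €44 e-visit
price is validated only by inversion (the subscription fee is not public).
Full precision is kept internally; rounding to whole euros (banker's
rounding) happens at report time only.

Patient-related costs (sensitivity analysis): per in-office visit,
round-trip travel 2 × 7 km × €0.19 + €3.20 parking + 4.5 h × blended wage,
where the blended wage is 0.70 × €37.05 + 0.30 × €13.33 ≈ €29.93/h
(the 70% economically-productive share is applied as an expected wage per
hour, not resolved per patient); per e-visit, 0.5 h × blended wage; for
intervention patients, 10 min/week of measurement time over a **50-week**
year at the non-productive wage (€111.08/year). The 50-week year matches
the clinic year used in the e-visit capacity calculation and reproduces
the published intervention patient-related mean (€426) and between-arm
difference (€144) to within 0.4%; a 52-week year misses the difference by
2.7%. One-way travel was rejected because it cannot reproduce the
published €570 control-arm mean. The €0.19/km tariff is the Dutch costing
manual value (not printed in the source tables) and is configurable.

## QALYs and multiple imputation

The AUC uses the piecewise-linear trajectory over months 0–12 with
u(0) := u(1) (carry-back), i.e. weights (3.5, 5.5, 3)/12 on (u1, u6, u12).
Carry-back is the simplest convention consistent with the published
magnitudes; any baseline convention is confined to the first month and
shifts QALYs by < 0.01 for these trajectories. Deceased patients are
retained with utility 0 from the month of death (helper provided; the
generator itself does not simulate deaths). Conversion of SF-36
questionnaires to utilities is a pluggable interface only: the SF-6D
algorithm is licensed and the default scorer refuses with a notice; a toy
linear scorer, clearly labelled, exists for tests.

Imputation is sequential regression u1 → u6 → u12 within each arm:
for each target, a normal linear model on standardized age, sex, index
event, log troponin and all earlier (observed-or-imputed) utilities is
fitted on the rows observed at that timepoint, posterior parameter draws
are taken under the standard noninformative prior (σ² from scaled inverse
chi-square, β from its conditional normal), and missing cells are filled
from the posterior predictive, clipped to [0, 1]. Per-arm fitting keeps
the imputation model saturated in the treatment factor, so imputation
cannot shrink the between-arm contrast. Predictive-mean matching (5
donors) is available as an alternative. m defaults to 20. An arm with a
completely unobserved timepoint is refused with a diagnostic rather than
extrapolated. Arm means and the arm difference are pooled with Rubin's
rules; the t reference uses the classical Rubin degrees of freedom.

## Bootstrap CEA

B = 1000 replicates resample patients with replacement within each arm at
the original arm sizes (stratification preserves the randomization
structure), with replicate b drawn from completed dataset b mod m, so
imputation variability enters the draws without the cost of a nested
MI-within-bootstrap. The CEAC counts strict positive net monetary benefit;
ties count against the intervention (conservative). The default grid is
0–100,000 €/QALY in steps of 500, covering the Dutch 20,000–80,000
threshold range. ICERs are reported with quadrant labels (dominant /
dominated / undefined at ΔE = 0) because a ratio alone is sign-ambiguous
on the CE plane. p-values are descriptive; nothing is gated on them and no
multiplicity correction is applied.

## Problem sizes and Monte-Carlo precision

Every analysis runs the full trial (n = 180 analysed, m = 20, B = 1000) in
well under a second. Seed-ensemble summaries use 30 trials in the test
suite and 400 (costs) / 60 (imputation + bootstrap) in the acceptance
script: arm-mean costs have a between-seed SD near €230 — dominated by the
rare, heavy-tailed revascularisation and admission items — so a ~€470 cost
difference needs a few hundred seeds for a Monte-Carlo SE comfortably
below its own magnitude, while QALY means (between-seed SD ≈ 0.017) and
the deterministic patient-related model need far fewer.

One reproduction target is intrinsically borderline: the minimum CEAC
probability over the grid occurs at λ = 0, where it equals the bootstrap
fraction of negative cost differences. At the calibrated effect size
(ΔC ≈ −470, within-trial SE ≈ 340) that fraction is ≈ 0.92 in expectation,
but single trials scatter widely, and the seed-median of the grid minimum
sits at ≈ 0.90 — exactly the published floor. The published ">0.9
everywhere" claim was itself a single-dataset bootstrap statement at the
edge of its own sampling noise.

## Known limitations

* Item independence understates cost variance and between-item
  correlation; CEAC values on synthetic data are correspondingly slightly
  optimistic.
* Visit counts and visit costs are calibrated to two mutually
  inconsistent published columns and are therefore decoupled in the
  generator.
* The generator does not simulate deaths, telemetry streams, or
  clinical-event survival processes; utilities and events are exchangeable
  across patients given arm.
* The imputation model is linear-normal with clipping; strongly skewed
  utility distributions would need a transform.
* Passing calibration tests shows the pipeline recovers the published
  summaries under these synthetic conditions; it does not validate the
  clinical findings themselves, which would require the original data.
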