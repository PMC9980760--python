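# Methods

## Scope and design

The package evaluates (i) bedside severity scores as predictors of
30-day mortality in patients treated for infection, and (ii)
administrative data items as proxy markers for Sepsis-3 sepsis. It is
organised as the analysis runs: score engines → Sepsis-3 labelling →
administrative indicators → diagnostic-accuracy statistics, with a
synthetic cohort generator standing in for patient-level EHR data,
which cannot be distributed.

## Score calculation

All four instruments apply **missing-as-normal**: an uncharted
parameter contributes zero points. This mirrors ward practice, where
absence of a measurement usually reflects absence of clinical concern,
but it biases scores downward for genuinely unmeasured sick patients.

* **NEWS** uses the RCP 2012 bands over respiratory rate, SpO2,
  supplemental oxygen, temperature, systolic BP, heart rate and AVPU
  (aggregate 0–20). Published band tables are integer-valued; the
  implementation extends each band over the real line by carrying it to
  the start of the next band (e.g. respiratory rate 11.5 scores as the
  9–11 band).
* **SIRS** counts WCC < 4 or > 12 ×10⁹/L, HR > 90, RR > 20, and
  T < 36 or > 38 °C, with strict inequalities.
* **qSOFA** counts RR ≥ 22, systolic BP ≤ 100 mmHg and altered
  mentation (GCS ≤ 13; when GCS is absent, AVPU below Alert).
* **SOFA** scores six organ systems 0–4. Two substitutions make it
  computable from ward observations:
  * *Respiration*: with a blood gas, the PaO2/FiO2 ratio (kPa → mmHg,
    ×7.50062; bands 400/300/200/100, ratios under 200 scoring 3–4 only
    with respiratory support, for which the supplemental-oxygen flag is
    the available proxy, else capped at 2). Without one, SpO2 91–94 % →
    1 point, < 91 % → 2. A blood gas in the period takes precedence.
  * *Neurology*: recorded GCS is banded (15/13–14/10–12/6–9/<6); when
    GCS was never charted, AVPU maps to a surrogate GCS A→15, V→13,
    P→8, U→3 (module constants, overridable — the V→13 surrogate in
    particular is a convention, not a measurement).
  * *Cardiovascular*: MAP = DBP + (SBP − DBP)/3 when both pressures are
    present (the period-worst MAP is taken from a single observation's
    pressure pair, not from independent minima, which would understate
    it); MAP < 70 scores 1. Vasopressor doses score 2–4 when supplied
    but are default-absent, capping the component at 1 — ward case
    notes rarely carry dose data.
  * *Renal*: creatinine bands 110/171/300/440 µmol/L; a daily urine
    output below 500/200 mL can raise the component (worse criterion
    wins) but is optional.

Laboratory units are UK convention: platelets/WCC ×10⁹/L,
bilirubin/creatinine µmol/L, PaO2 kPa, FiO2 as a fraction.

## Sepsis-3 labelling

Infection requires a documented source plus at least one antibiotic
dose; **onset** is the earlier of first blood culture and first
antibiotic. The analysis window is onset ±48 h, split into four 24 h
periods, closed-open (`[start, end)`), so an event exactly at +48 h is
outside the window.

NEWS, qSOFA and SIRS are evaluated at the **point of highest acuity**:
the observation with maximal NEWS in the window, earliest timestamp on
ties (the tie rule is a convention; any fixed rule gives identical
aggregate results on data with dense observations). SIRS takes the WCC
nearest in time to that observation. SOFA is computed per period from
directionally worst values (lowest platelets/MAP/SpO2/GCS, highest
bilirubin/creatinine).

**Sepsis** = infection plus max period SOFA ≥ 2 (ward patients,
baseline assumed zero) or plus ΔSOFA ≥ 2 (patients in critical care at
any point within 48 h of onset). The baseline for Δ is not fixed by the
Sepsis-3 operationalisation when pre-illness scores are unknown; the
default takes the *minimum of the two pre-onset period scores* (empty
periods count 0), a conservative reading of "acute rise". `first_pre`
and `zero` are available as `baseline_mode` options; `zero` collapses
the critical-care rule onto the ward rule.

Mortality endpoints: death within 720 h of onset (inclusive), within
720 h of admission, and before discharge. One admission carries at most
one infection episode: the first qualifying one.

## Administrative indicators

ICD-10 codes are canonicalised to dotted uppercase (A419 → A41.9) and
matched by prefix, any diagnosis position. Explicit sepsis codes
default to A40\*, A41\*, R57.2. The packaged infection-code list is a
**documented reconstruction** seeded from the three chapters that
dominate infection coding (respiratory J, infectious/parasitic A–B,
genitourinary N) plus common infection codes elsewhere; it is a plain
text file the user should replace with a locally validated list. The
two lists are made disjoint at load time (sepsis wins). Contaminated
blood cultures count as sampled, never as positive.

## Statistics

* Sensitivity/specificity/PPV/NPV use Clopper-Pearson exact 95 % CIs by
  default. The exact method was chosen as the package default because
  it is conservative and standard for diagnostic 2×2 tables; Wilson is
  available by option. Zero denominators leave the statistic undefined
  and flagged, never silently zero.
* A binary indicator's AUROC is (sensitivity + specificity)/2 — the
  trapezoidal area through its single operating point — with a CI from
  the DeLong variance of the two-valued predictor.
* Graded-score AUROC uses the rank (Mann-Whitney) estimator with
  mid-rank ties, identical to trapezoidal integration of the empirical
  ROC. DeLong's test compares paired AUROCs via placement-value
  covariances; identical score vectors return z = 0, p = 1 with a
  warning. p-values are two-sided with no multiplicity adjustment.
* Display rounding is decimal half-up (0.25 → 0.3); full precision is
  kept internally.

## Synthetic cohort generator

The generator emulates an infection-enriched matched cohort; its
defaults are the study conditions the package is calibrated to:
infection prevalence 0.657; sepsis among infected 0.551; 30-day
mortality from admission 0.199/0.053/0.040 by category
(sepsis / infection without sepsis / no infection); blood-culture
sampling 0.660/0.703/0.155; positivity given sampling 0.114/0.080/0;
explicit-sepsis coding probability 0.078/0.035/0.015 and
infection coding 0.651/0.550/0.130 (the non-sepsis values are chosen so
the aggregate false-positive coding rates match the marginal 2×2s the
package evaluates); critical care within 48 h of onset 0.133/0.046
(0.067 anywhere in stay for the uninfected); log-normal length of stay
with category medians 5.8/3.9/3.8 days and σ = 0.75.

Vitals are drawn every 4–8 h as *per-admission Gaussian baselines* plus
small observation noise, plus a category-conditional perturbation that
peaks at onset and decays exponentially (τ = 24 h; labs daily with
τ = 36 h). Two design points matter:

* **Variance placement.** Most variance sits in the per-admission
  random effect, not observation noise. The labelling pipeline takes
  worst-values over ~18 observations per window, so even small
  per-observation tail probabilities are inflated roughly 18-fold;
  rare-event probabilities (altered AVPU in non-septic patients) are
  correspondingly kept low. With this placement the Sepsis-3 label
  recovers the latent category for >99 % of admissions, and the
  labelled sepsis-given-infection fraction stays within ±0.02 of the
  0.551 target.
* **Severity coupling.** A per-admission severity factor (higher in
  those who die) scales the vitals perturbation, giving NEWS a graded
  association with mortality (AUROC ≈ 0.70 on synthetic cohorts).
  Laboratory effects are *not* scaled by severity, so the SOFA-based
  label stays calibrated to the latent category.

Deaths are placed within 720 h of admission (60 % in-hospital,
truncating the stay); mortality beyond 30 days is not modelled.
Randomness uses one named substream per data domain from a single seed,
so extending one component never perturbs another's draws.

What the generator does **not** emulate: organism-level microbiology,
real vitals autocorrelation and circadian structure, measurement
artefacts, informative missingness (observation frequency is
independent of illness), hospital occupancy, and coding that depends on
anything but the latent category. Passing recovery tests therefore
shows the pipeline is correct and calibrated under the stated
generative model — not that the scores would achieve the same accuracy
on real case-note data.

## Study-design operations

Eligibility removes maternity admissions and stays under 24 h.
Matching is **greedy 1:1** in chronological order of first culture:
controls must share the ward at culture time within ±24 h (±96 h for
critical care) and have length of stay within ±24 h (±48 h critical
care); ties break on smallest LOS difference then earliest admission;
each control is used once. Greedy matching mirrors feasible manual
practice and is deterministic; it is not claimed optimal. Cohort
sampling keeps all critical-care pairs and randomly samples ward pairs,
preserving pair integrity.

## Problem sizes and numerical choices

The recovery experiments use 20,000-admission cohorts (a size at which
three Monte-Carlo standard errors resolve the smallest target rates,
~0.04) and run in well under a minute; oracle checks use exhaustive
permutation at n = 8 (2⁸ swaps) and 10⁴ stratified bootstrap resamples
at n = 200. Period edges are closed-open; the 30-day windows include
the +720 h timestamp; score band edges are tested at value ± ε.

## Known limitations

* The asymptotic DeLong p-value and an exact permutation p differ by
  up to a few hundredths at n = 8; the test asserts agreement to 0.05.
* The binary-indicator AUROC CI method is the DeLong variance; other
  choices (e.g. bootstrap) give slightly different intervals.
* AVPU = V is mapped to surrogate GCS 13 (1 CNS point); deployments
  preferring a different surrogate can override the module constant.
* The infection-code list is a reconstruction, not a validated
  standard.
* Score engines accept one vasopressor record per period; multi-drug
  regimens score by the single worst agent supplied.
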