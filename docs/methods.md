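# Methods

This note documents the models and procedures the package implements,
the defaults and why they were chosen, the numerical conventions, and
what the synthetic data can and cannot establish.

## Calendar and interval conventions

All dates are integer day offsets from 2000-01-01 and all intervals are
half-open `[start, end)`, which makes gap and overlap arithmetic exact:
the gap between a supply ending on day `e` and one starting on day `s`
is `s − e` days. Calendar phrases are converted once and used
everywhere: 1 month = 30.44 days, 1 year = 365.25 days, 6 months = 183
days, 3 months = 92 days.

## Cohort construction

The index date is the patient's **first** prescription of any study
class (ACEi, ARB, CCB, TZD, BB) inside the study window (2006-01-01 to
2014-12-31 by default). New-user status requires that no prior supply
interval ends within `washout_days` (183; sensitivity 365) before the
index: a patient whose first in-window prescription violates the
washout is excluded outright rather than re-screened at later dates.
This convention makes the washout-365 cohort a strict subset of the
washout-183 cohort, which the sensitivity grid relies on.

Eligibility further requires, in cascade order: 1-2 classes started on
the index day; ≥ 365 days of registration before the index; evidence of
hypertension — a diagnosis code at or before the index *or* at least
two elevated readings (SBP ≥ 140 and/or DBP ≥ 90 mmHg) on distinct
dates in the prior year ("repeated" is operationalized as ≥ 2, the
minimum count the word supports); an elevated reading within 92 days up
to and including the index day, the most recent of which defines
baseline BP; no secondary hypertension or heart failure ever; no
stroke/MI in the prior year (TIA exclusion available behind a config
flag, off by default). Exclusion counts are sequential, so the
attrition report telescopes exactly.

Hypertension grade is the maximum of the systolic band (140-159 /
160-179 / ≥ 180) and the diastolic band (90-99 / 100-109 / ≥ 110).

Baseline covariates cover demographics and lifestyle, baseline BP and
grade, months since first hypertension diagnosis, medical-history
indicators with recency strata (ever / within 1 year), prior
antihypertensive use before the washout (any, months since the last
supply end, number of distinct classes), comedication indicators,
utilization (distinct primary-care contact dates and hospitalization
days in the prior year) and prior follow-up duration. Missingness is
always an explicit category or indicator. Laboratory values are not
modelled because the record streams carry no laboratory results.

## Exposure algebra

Per class, supplies merge into an episode when they overlap or when the
gap is **strictly** below `discontinuation_gap_days` (60; sensitivity
90): a gap of exactly 60 days separates episodes. The episode ends at
the last covered supply end — the gap allowance merges, it never
extends exposure.

Episodes of different classes overlapping ≥ `min_concomitant_overlap_days`
(30; sensitivity 60) form multi-class regimen spells. Shorter overlaps
are class switches; that rule leaves three cases genuinely open,
resolved here and enforced identically in the day-grid oracle:

* **Hand-off** (incoming class starts later, outgoing ends earlier):
  the outgoing episode is truncated at the incoming start, keeping
  exposure continuous through the switch.
* **Nested short episode** (a brief episode wholly inside another
  class's episode): dropped — the class count never rises during a
  sub-threshold overlap.
* **Same-day starts** (the two classes of a duo initiation): both kept
  regardless of overlap length; the index regimen is given by cohort
  entry, and a duo whose second class lapses early shows up as a
  switch to monotherapy, not as a mono initiation.

When several sub-threshold overlaps coexist, they are resolved one at a
time, earliest first, ordered by (incoming start, outgoing start,
incoming class, outgoing class).

The first boundary where the **count** of concomitant classes changes
ends as-treated time: increases are dated at the incoming spell start,
decreases at the outgoing spell end (the last supply end, per the
configurable convention); a duo dropping to one class is
`switch_to_monotherapy`, a drop to zero is `full_discontinuation`.
Same-count membership changes are class switches and do not end
exposure. Gaps between spells of different classes shorter than the
discontinuation threshold are bridged (a mono-to-mono transition across
a 50-day gap is a switch); a gap ≥ the threshold is full
discontinuation. A terminal gap counts as discontinuation only when at
least `discontinuation_gap_days` of registration remain after the last
supply end — otherwise discontinuation is unobservable and the regimen
is deemed ongoing to the administrative end.

Follow-up runs from the index to the minimum of the as-treated end
(as-treated mode only), registration end, death, and the coverage hard
end (2016-02-29). An outcome on the day of a regimen change counts as
an event, not a censoring.

## Propensity score, matching, balance

The PS is a maximum-likelihood logistic regression of two-drug
initiation on all baseline covariates (categoricals expanded with
explicit missing levels; constant columns dropped; collinearity
reported; perfect separation raised as an error naming the offending
covariates). The caliper is 0.2 × SD (ddof = 1) of logit(PS) computed
on the **pooled** cohort — the reference population had to be chosen;
pooled is the symmetric option.

Greedy 1:2 matching without replacement runs as two sequential 1:1
passes. Treated subjects are ordered by descending logit (hardest to
match first), ties broken by a seeded shuffle; each takes the nearest
unused control within the caliper, equal distances resolved toward the
lower logit. A treated subject failing any pass is dropped and its
controls return to the pool immediately. The result is deterministic
given the seed.

Balance uses the weighted absolute standardized difference: continuous
`|m_t − m_c| / sqrt((v_t + v_c)/2)`, binary
`|p_t − p_c| / sqrt((p_t(1−p_t) + p_c(1−p_c))/2)`, with matched
controls weighted 1/ratio and weighted variances computed with the
frequency-weight convention `Σw(x−m)² / (Σw − 1)`. Zero variance in
both groups gives ASD 0; in one group only, the pooled formula applies
and the covariate is flagged. Covariates with post-match ASD > 0.1
enter the outcome model as main effects (double adjustment).

## Outcomes and estimation

BP control is the first reading strictly after the index with
SBP < 140 **and** DBP < 90, at or before the follow-up end. MACE is the
earliest of nonfatal MI, nonfatal stroke and cardiovascular death; an
MI/stroke is fatal iff death occurs within 30 days **inclusive** of the
event date, in which case it contributes as CV death at the death date
when the cause is cardiovascular (and the death falls inside
follow-up), and as no MACE otherwise. Person-time for each endpoint is
censored independently of the other endpoint.

Incidence-rate intervals use the exact Poisson chi-square form
(`lower = χ²(0.025, 2k)/2`, `upper = χ²(0.975, 2k+2)/2`); a normal
approximation is available above a 100-event cutoff but exact is the
default at every count.

Cox models use the Efron tie approximation and a robust sandwich
variance clustered on the matched-set identifier (not the patient), on
the time scale of days since index with no delayed entry — except for
the time-varying BP-control covariate for MACE, where each patient's
follow-up is split at the first control date into delayed-entry rows
with a 0→1 indicator; the split conserves person-time exactly. Arms
with zero events yield a flagged non-estimable result instead of an
error. Subgroup analyses (grade 1, grade 2-3, ACEi+CCB vs ACEi or CCB
alone) re-fit the PS and re-match within the subgroup.

## Synthetic EHR generator

The generator emulates, with known parameters: five drug classes;
confounding by indication; refill behaviour with gaps, discontinuation
and regimen changes; pre- and post-index BP trajectories; and event
hazards with configurable true effects. Two modes exist so exposure
construction and estimation are testable independently: the full-EHR
mode emits raw record streams, the direct-survival benchmark emits
covariates, treatment and event/censoring times drawn exactly from the
proportional-hazards truth.

**Covariates and confounding.** Baseline covariates (age, sex, BMI,
smoking, deprivation, ethnicity, comorbidity history, hypertension
duration and grade, prior antihypertensive use, utilization) feed three
linear predictors with fixed weights: treatment assignment, BP-control
hazard and MACE hazard, all scaled by `confounding_strength` (default
1). Assignment weights reproduce the qualitative baseline contrasts of
two-drug initiators (younger, more often male, heavier, more severe,
longer-diagnosed, far more prior use stopped more recently, fewer GP
visits). Outcome weights are kept modest so the marginal and
conditional hazard ratios nearly coincide (the HR is non-collapsible;
with these weights the gap is within the Monte-Carlo tolerance of the
recovery experiments). The assignment intercept is calibrated by root
finding so the marginal two-drug share equals `duo_target_fraction`
(default 0.06). Confounding is injected only through these shared
covariates, so PS adjustment can remove it completely; an optional
unmeasured-confounder term (default 0) exists for robustness
demonstrations.

**True effects.** Defaults: conditional HR 1.17 for BP control and 1.0
for MACE. Event times are exponential given covariates, with the
BP-control baseline 0.075/month and MACE component rates (MI 0.00045,
stroke 0.00045, CV death 0.0003 per month) chosen so incidence sits at
a realistic scale of a few events per 100 patient-months (BP control)
and ~10 per 1000 patient-years (MACE). After the first regimen change
the hazard contrast between arms is removed by default
(`equalize_post_change`), which is both realistic (the exposure
contrast ends with the regimen) and the mechanism behind the
ITT-attenuation property.

**Regimen dynamics.** The time to the first count-changing transition
is Weibull with shape 0.45 (heavy early change, long tail) and scale
set so the median equals ln 2 / total rate; per-month transition
hazards default to add 0.035, remove 0.04, discontinue 0.045, plus
class switches at 0.02 which never change the count. Discontinuers may
restart later (p = 0.3). Change times are floored at 2 days so no
change can redefine the index regimen. These values were fixed once
against the qualitative anchors of the domain — roughly three-quarters
of initiators changing regimen, median exposure of a few months with a
long tail — and left alone; the realized values are reported by the
acceptance script, not asserted by tests.

**Records.** Supplies default to 28/56/84 days (0.7/0.2/0.1) with
small refill jitter and occasional long gaps (4% at 61-120 days), so
genuine episode splits occur. Visits follow a Poisson process at
`visit_rate` = 8/year; readings before the latent control time are
elevated, after it controlled, so the observed control time is the
first visit after the latent one — the interval-censored detection
real BP data exhibit. Prior antihypertensive use is emitted strictly
before the study window (chains ending in-window would redefine the
first in-window prescription and hence the index); the months-since
covariate is recomputed from the records actually emitted, and prior
use that registration cannot capture is zeroed so the assignment model
only ever uses extractable information. Prevalent users are planted as
refill chains crossing the window boundary, which the washout then
excludes; other eligibility-noise fractions (short history, missing
recent BP, secondary hypertension, heart failure, triple-class index)
exercise each cascade step. The visit-frequency and refill-gap
distributions are free parameters with no external anchor; they are
config fields documented here.

**What passing tests do and do not show.** The generator's confounding
is measured, linear on the logit/log scale, and shared between models;
real confounding is neither guaranteed measured nor linear. Recovery of
the true HR here therefore validates the *machinery* (cascade, episode
algebra, matching, variance), not the causal validity of any real-world
estimate. Coding realism (READ/ICD-10), dosage and titration,
practice-level clustering and laboratory values are out of scope. In
the full-EHR pipeline the matched estimate is additionally attenuated
a few percent toward the null relative to the generating conditional
HR by interval-censored event detection at visits and by the use of
extracted proxies (e.g. visit counts) for the latent covariates — an
intended piece of realism worth remembering when reading single-run
numbers.

## Problem sizes and experiment design

The estimator-recovery experiments use the direct benchmark at
n = 20 000 per replicate — 50 replicates (seeds 0-49) for the effect
(true HR 1.20) and the null (type-I error at nominal 0.05), 10
replicates (seeds 0-9) for balance restoration. The episode oracle
comparison covers 1 000 random prescription histories against a
day-grid brute force. The acceptance script runs the full pipeline at
n = 20 000 and the benchmark at 10 replicates. Sensitivity and ITT
properties are audited on 5 000-8 000-patient cohorts. These sizes give
Monte-Carlo error comfortably inside the stated tolerances while
keeping the whole suite in single-digit minutes on one CPU.

## Known limitations

* The washout design admits restarting users by construction (as in
  the source design); prior-use covariates quantify this rather than
  eliminate it, and the 1-year-washout variant tightens it.
* Greedy matching is order-dependent; the documented order (descending
  logit, seeded ties) is a convention, not an optimum. Optimal/full
  matching and IPTW are out of scope.
* MACE is rare at the default scale, so single-run MACE hazard ratios
  are noisy and may be non-estimable in small cohorts; the pipeline
  flags rather than fails.
* The day-grid oracle shares the package's *semantic decisions* (it
  must, to be comparable); it independently re-derives the arithmetic,
  not the conventions.
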