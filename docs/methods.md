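# Methods

## Ascertainment model

The unit of analysis is a participant followed over approximately annual
visits, dementia-free (NC or MCI) at baseline. At each visit the NPI-Q
records informant-rated severities 0–3 for 12 symptom domains; severity 0 is
taken as symptom absence, and a separate presence flag (carried by some
NPI-Q exports) is not used. Ten items map onto five MBI domains (the
neurovegetative items — nighttime behaviors, appetite/eating — are excluded
by the MBI criteria) and the global severity score 0–30 is their sum.

A visit with any of the ten mapped items missing is *unscorable*: the score
is reported unavailable rather than imputing zeros, mirroring the cohort
practice of excluding participants with missing NPI-Q data. Unscorable
follow-up visits inherit the most recent scorable status
(last observation carried forward) and leave both numerator and denominator
of the persistence fraction.

Classification is the three-way rule: global score 0 → No NPS; score ≥ 1
with psychiatric history and/or impersistent symptoms → non-MBI NPS;
score ≥ 1, persistent, no psychiatric history → MBI. Persistence is
symptom presence in **strictly** more than two-thirds of the participant's
scorable dementia-free visits (exactly 2/3 is impersistent; the comparison
is done in integer arithmetic, `3*n_present > 2*n_visits`, so the boundary
is exact). By default persistence is computed retrospectively over the full
dementia-free series and applied to every visit; a prospective
(visits-so-far) mode is available for sensitivity analyses. Psychiatric
history is a baseline-fixed flag (union of the recorded conditions), not
time-varying.

Inclusion filters retain participants who are dementia-free and aged ≥ 50
at baseline, have a scorable baseline NPI-Q, pass scan quality control, and
have a known APOE4 allele count; each excluded participant is logged with
the first matching rule, in that order.

The incident-decline outcome is the first visit with a changed diagnosis
(NC baseline: MCI or dementia; MCI baseline: dementia), located at the
visit date — no interval-censoring midpoint imputation. Participants
without a qualifying transition are censored at their last visit (death is
not modelled as a competing event; follow-up simply ends). A single-visit
participant is censored at time 0 and flagged.

## Statistical models

**Imaging models.** Per cognitive stratum, OLS of each normative Z score
(bilateral hippocampal volume, entorhinal volume, AD meta-ROI mean cortical
thickness) on two NPS-group indicators (No NPS reference) plus years of
education, race (indicator set, White reference), clinic-to-scan gap in
days, and APOE4 allele count entered as a linear 0/1/2 term. Complete-case
analysis with dropped rows counted; normal-theory standard errors and 95%
CIs; no multiple-testing adjustment across the six stratum × ROI models
(single-threshold reporting; a documented caveat). Designs with an empty
exposure reference level, a single exposure level, a zero-variance outcome,
or rank deficiency raise explicit errors naming the term.

**Survival.** Visit histories are expanded into counting-process rows —
half-open `(start, stop]` intervals of constant NPS status, one row per
maximal run, the event attached to the final row only; interval lengths sum
to follow-up time. Kaplan–Meier curves are estimated per group (median =
smallest time with survival ≤ 0.5, undefined when not reached). The Cox
model is maximized over the counting-process rows with the risk set at
event time *t* comprising rows with `start < t <= stop`; ties are handled
by the Efron approximation; the timescale is years on study (baseline age
is a covariate). The fully adjusted model uses age, sex, education, race,
APOE4, clinic-to-scan gap and the three baseline imaging Z scores. Race
levels held by fewer than max(5, 2%) of participants are pooled into a
single indicator (folded into the reference when the pooled cell itself has
fewer than 5 participants): near-empty cells otherwise produce monotone
partial likelihoods. A monotone likelihood (complete separation) is raised
as an explicit error rather than returned as a silently divergent estimate.
Indicator columns of absent exposure levels (and any constant column) are
dropped before fitting.

Schoenfeld residuals are computed at each event time (observed covariate
minus the risk-set mean weighted by `exp(X beta)`); the
proportional-hazards check is the Pearson correlation of each covariate's
residuals with event time. Martingale residuals per subject use the Breslow
baseline cumulative hazard. Diagnostics require at least 3 events and never
trigger refitting.

## Synthetic cohort generator

The generator emulates the joint structure the analysis consumes. Defaults
are the observed cohort values; everything is overridable via `SimConfig`.

| parameter | default | provenance |
|---|---|---|
| NPS prevalences (No NPS / non-MBI / MBI) | 0.669 / 0.215 / 0.115 | observed cohort (stratum-specific 0.769/0.182/0.049 NC, 0.406/0.303/0.291 MCI in `recovery.STRATUM_PREVALENCE`) |
| MCI fraction at baseline | 0.275 | observed cohort |
| psychiatric-history prevalence | 0.324 | observed cohort; among non-MBI NPS, 59.9% carry history |
| age at baseline | N(68.3, 10) NC, N(73.6, 8) MCI, truncated ≥ 50 | observed cohort |
| education, sex, race, APOE4 | stratum-specific observed frequencies | observed cohort |
| imaging shifts per stratum × ROI | e.g. NC meta-ROI (−0.12, −0.50) | observed coefficient table |
| residual SD of Z scores | 1.0 | normative Z-scoring |
| covariate effects on Z | +0.02/edu-year, −0.10/APOE4 allele, −0.0002/gap-day | invented, small and plausible |
| baseline hazards | NC −ln(1−0.209)/10 ≈ 0.0234/y; MCI ln 2/7.98 ≈ 0.0869/y | solved from the observed No-NPS event fraction (NC) and median (MCI) |
| log hazard ratios (non-MBI, MBI) | NC ln 1.54, ln 2.83; MCI ln 1.63, ln 3.11 | observed adjusted HRs |
| visit schedule | annual; planned visits/person uniform on [4, 11] | invented (follow-up 3–10 years) |
| No-NPS conversion probability | 0.02/visit | invented, exercises the time-varying exposure |
| clinic-to-scan gap | Uniform(0, 120) days | invented |

Symptom trajectories encode the generating group: MBI and
history-attributable non-MBI participants are symptomatic at every visit;
impersistent non-MBI participants are symptomatic at every third visit from
baseline; No-NPS participants may convert to the same intermittent pattern.
Symptomatic visits endorse 1–3 mapped items at severity 1–3; the
neurovegetative items vary independently of group (they must never affect
any result). These patterns are deliberately chosen to be
**truncation-invariant**: for (almost) any point at which an event ends
follow-up, the three-way class of every observed visit is the same as on
the full planned series, so the status that drove the simulated hazard is
the status the analysis recovers.

Progression is piecewise-exponential: on each inter-visit interval the
hazard is `baseline_rate * exp(log HR of the current NPS status)`, with the
status taken from the same classification the analysis applies. Event times
are drawn by interval-wise inversion of the cumulative hazard and are
continuous; the diagnosis visit is placed at the event time (in the NC
stratum it is an MCI visit, still dementia-free and NPI-Q-assessed, so it
legitimately enters the persistence denominator; in the MCI stratum it is a
dementia visit without further NPI-Q use). Identical seed and config give
bit-identical cohorts, and the CSV fixture round-trips losslessly
(`float_precision="round_trip"` on read).

**What the generator does not emulate:** within-person severity dynamics
beyond presence/absence, site/scanner effects, death and other competing
risks, longitudinal imaging, item-level symptom correlation structure, and
misdiagnosis. Passing recovery tests therefore demonstrate the correctness
of the ascertainment and estimation machinery under the stated generative
model — not robustness to these real-data complications.

## Recovery experiments and known limitations

`mbikit.recovery` replicates the full simulate → classify → expand → fit
chain. Problem sizes: Cox recovery uses single-stratum cohorts of n = 2000
with 40 replicates per stratum; linear recovery n = 900 with 50 replicates;
the KM median n = 500 with 20 replicates under 10% independent
Uniform(0, c_max) censoring with c_max solved so the expected censored
fraction is 10%.

One bias is inherent and documented rather than patched: an MCI participant
with impersistent symptoms who progresses to dementia before the second
visit has a single dementia-free visit, and the persistence rule (fraction
1/1 > 2/3) classifies them MBI. Because such participants are selected by
having early events, their short event-terminated exposure inflates the MBI
hazard-ratio estimate in the MCI stratum by about +7% at the default
parameters (measured over replicated runs). The rule itself forces this on
any data with this visit structure; the NC stratum is unaffected because
the incident-MCI visit remains dementia-free and scorable. The same
mechanism slightly attenuates the MCI non-MBI hazard ratio.

Other numerical choices: `lifelines.CoxTimeVaryingFitter` performs the
partial-likelihood maximization (Newton-type with step-halving) and
`lifelines.KaplanMeierFitter` the product-limit estimation;
`statsmodels` formula OLS fits the imaging models. The Cox convergence
warning for non-unique maxima is promoted to an error. Kaplan–Meier curves
are exported as per-group step-function TSVs rather than rendered plots.
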