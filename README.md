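# mbikit

Ascertainment of **mild behavioral impairment (MBI)** from longitudinal
NPI-Q assessments, with the downstream analyses that distinguish MBI from
other neuropsychiatric symptoms (NPS): stratified linear models of
structural-imaging Z scores and time-dependent-exposure survival models of
incident cognitive decline.

The package is aimed at biostatisticians and dementia researchers who work
with memory-clinic cohorts (dementia-free older adults with normal cognition
(NC) or mild cognitive impairment (MCI), followed approximately annually).
Because the cohort that motivated this pipeline is access-restricted, the
package ships a first-class synthetic-cohort generator that reproduces the
statistical structure of such data — including planted effect sizes — so
every stage is testable and the whole analysis is reproducible end to end
without any data download.

## The algorithm

**Scoring.** Each visit's 12 NPI-Q item severities (0–3) map onto five MBI
domains; the two neurovegetative items (nighttime behaviors,
appetite/eating) are excluded:

| MBI domain | NPI-Q items | range |
|---|---|---|
| decreased motivation | apathy | 0–3 |
| affective dysregulation | depression, anxiety, elation | 0–9 |
| impulse dyscontrol | agitation, irritability, aberrant motor | 0–9 |
| social inappropriateness | disinhibition | 0–3 |
| abnormal perception / thought content | delusions, hallucinations | 0–6 |

The global MBI severity score (0–30) is the sum of the domain scores.

**Classification.** Each visit receives one of three NPS states from the
global score *g*, the participant's psychiatric history *h*, and symptom
persistence *p* (presence in strictly more than 2/3 of dementia-free
visits):

```
g = 0                  ->  No NPS
g >= 1 and (h or !p)   ->  non-MBI NPS     (transient, or attributable to
                                            a psychiatric condition)
g >= 1 and !h and p    ->  MBI             (later-life emergent, persistent)
```

**Models.** Within each cognitive stratum, ordinary least squares regresses
each normative imaging Z score (bilateral hippocampal volume, entorhinal
volume, AD meta-ROI mean cortical thickness) on the NPS group (No NPS
reference) adjusting for education, race, clinic-to-scan gap and APOE4
allele count. Incident cognitive decline (NC → MCI/dementia; MCI →
dementia) is analysed by Kaplan–Meier estimation and by Cox regression over
counting-process intervals `(start, stop]` in which the NPS state is a
**time-dependent exposure** (carried forward between assessments), with
Efron tie handling and Schoenfeld/Martingale residual diagnostics.

## Worked example

```python
import numpy as np
import mbikit as mk

cohort, truth = mk.simulate_cohort(mk.SimConfig(n_participants=800, seed=42))
retained, excluded = mk.apply_inclusion_filters(cohort)
frame = mk.build_analysis_frame(retained)

res = mk.fit_biomarker_model(frame, "metaroi", "nc")
t = res["mbi"]
print(f"NC meta-ROI, MBI vs No NPS: beta = {t.estimate:.2f} "
      f"[{t.ci_low:.2f}, {t.ci_high:.2f}], p = {t.p_value:.3g}, n = {res.n_used}")
```

```
NC meta-ROI, MBI vs No NPS: beta = -0.45 [-0.70, -0.21], p = 0.000349, n = 592
```

The generator planted a −0.50 SD meta-ROI deficit for MBI in NC; the fitted
coefficient estimates it with its sampling noise. The survival side, on the
MCI stratum of the same run:

```python
from mbikit.classify import classify_history, derive_outcome
from mbikit.survival import expand_counting_process, fit_cox_td, km_estimate

sub = frame[frame["stratum"] == "mci"]
for c in sorted(km_estimate(sub["event_time"], sub["event"], sub["nps_status"]),
                key=lambda c: c.group):
    med = "not reached" if c.median is None else f"{c.median:.2f} y"
    print(f"KM median time to dementia [{c.group}]: {med} (n={c.n})")

by_id = {p.participant_id: p for p in retained}
rows = []
for pid in sub["participant_id"]:
    p = by_id[pid]
    rows.extend(expand_counting_process(p, classify_history(p), derive_outcome(p)))
fit = fit_cox_td(rows, stratum="mci")
for term in ("non_mbi_nps", "mbi"):
    t = fit[term]
    print(f"MCI aHR {term}: {np.exp(t.estimate):.2f} "
          f"[{np.exp(t.ci_low):.2f}, {np.exp(t.ci_high):.2f}], p = {t.p_value:.2g}")
```

```
KM median time to dementia [mbi]: 2.82 y (n=22)
KM median time to dementia [no_nps]: 6.22 y (n=135)
KM median time to dementia [non_mbi_nps]: 5.47 y (n=51)
MCI aHR non_mbi_nps: 1.04 [0.64, 1.71], p = 0.86
MCI aHR mbi: 2.11 [1.24, 3.60], p = 0.0061
```

MBI participants reach dementia fastest and carry the highest adjusted
hazard, non-MBI NPS are intermediate — the ordering the classification is
designed to expose. (At n=800 the per-run confidence intervals are wide;
the recovery experiments below average over replicates.)

The same analysis runs from the shell:

```bash
mbikit simulate -n 800 --seed 42 --out cohort.csv
mbikit classify  --input cohort.csv --out classified.csv
mbikit run-all   --seed 42 --outdir report/
```

`run-all` writes a report bundle: coefficient tables
(`biomarker_models.tsv`, `hazard_ratios.tsv`), per-group KM step functions
(`km_curves.tsv`), the exclusion log, a run log, and a `manifest.json` with
the seed and config hash; identical seed and config reproduce the bundle
byte for byte.

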