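"""Synthetic longitudinal cohort generator.

Emulates the statistical structure of a memory-clinic research cohort
followed approximately annually: per-visit NPI-Q item severities whose
longitudinal pattern encodes a generating NPS group (No NPS, non-MBI NPS,
MBI), baseline demographics and APOE4 genotype, normatively standardized
structural-imaging Z scores with planted group shifts, and visit-interval
progression to MCI/dementia under a piecewise-exponential hazard whose
multiplier tracks the participant's *current* NPS status (a time-varying
exposure).

The generator first lays out the planned visit series and symptom patterns,
classifies every planned visit with the same three-way rule the analysis
uses, then simulates the latent progression time by interval-wise inversion
sampling with the hazard constant between consecutive visits.  An event
truncates the series and appends a diagnosis visit at the latent event time.
Identical seeds produce bit-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .classify import (
    CognitiveStatus,
    Covariates,
    ImagingZ,
    NPSStatus,
    ParticipantHistory,
    VisitRecord,
    classify_history,
)
from .npiq import MAPPED_ITEMS, NEUROVEGETATIVE_ITEMS, NPIQ_ITEMS, NPIQRecord

ROIS = ("hippocampus", "entorhinal", "metaroi")

# Group-mean Z-score shifts (non-MBI NPS, MBI) relative to No NPS,
# per stratum and region.
_DEFAULT_SHIFTS = {
    "nc": {
        "hippocampus": (-0.24, -0.38),
        "entorhinal": (-0.06, -0.08),
        "metaroi": (-0.12, -0.50),
    },
    "mci": {
        "hippocampus": (-0.28, -0.40),
        "entorhinal": (-0.17, -0.37),
        "metaroi": (-0.04, -0.39),
    },
}

# Log hazard multipliers (non-MBI NPS, MBI) vs No NPS for incident decline.
_DEFAULT_LOG_HR = {
    "nc": (math.log(1.54), math.log(2.83)),
    "mci": (math.log(1.63), math.log(3.11)),
}

# Baseline (No NPS) hazards per year.  NC: ~20.9% of No-NPS participants
# decline within a decade => rate -ln(1-0.209)/10.  MCI: No-NPS median time
# to dementia ~7.98 years => rate ln(2)/7.98.
_DEFAULT_BASE_HAZARD = {"nc": -math.log(1 - 0.209) / 10.0, "mci": math.log(2) / 7.98}

_RACES = ("White", "Asian", "Black", "Hispanic", "Indigenous", "Other")
_RACE_PROBS = (0.844, 0.016, 0.126, 0.001, 0.012, 0.001)
_APOE4_PROBS = {"nc": (0.646, 0.319, 0.035), "mci": (0.503, 0.380, 0.117)}
_AGE_DIST = {"nc": (68.3, 10.0), "mci": (73.6, 8.0)}
_EDU_DIST = {"nc": (15.9, 5.0), "mci": (15.6, 7.2)}
_FEMALE_PROB = {"nc": 0.652, "mci": 0.474}


class SimConfigError(ValueError):
    """The simulation configuration is inconsistent or unsatisfiable."""


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Prevalences, covariate distributions, imaging shifts and hazard
    multipliers default to the values observed in the cohort the generator
    emulates; all are overridable.
    """

    n_participants: int = 1273
    fraction_mci: float = 0.275
    #: (No NPS, non-MBI NPS, MBI) generating prevalences; must sum to 1.
    nps_prevalence: tuple[float, float, float] = (0.669, 0.215, 0.115)
    psychiatric_history_prevalence: float = 0.324
    #: Among non-MBI NPS participants, fraction whose symptoms are explained
    #: by psychiatric history (the rest are impersistent).
    nonmbi_history_fraction: float = 0.599
    #: Planned annual visits per participant, drawn uniformly from
    #: [min_visits, max_visits] (baseline included).
    min_visits: int = 4
    max_visits: int = 11
    #: Per-stratum, per-ROI (non-MBI, MBI) mean Z-score shifts vs No NPS.
    imaging_shifts: dict = field(default_factory=lambda: {
        s: dict(r) for s, r in _DEFAULT_SHIFTS.items()
    })
    #: Planted covariate effects on every imaging Z score.
    education_effect: float = 0.02  # per year of education (centered at 16)
    apoe4_effect: float = -0.10  # per allele
    scan_gap_effect: float = -0.0002  # per day between clinic and scan
    residual_sd: float = 1.0
    #: Per-stratum baseline (No NPS) hazard of incident decline, per year.
    baseline_hazard: dict = field(default_factory=lambda: dict(_DEFAULT_BASE_HAZARD))
    #: Per-stratum (non-MBI, MBI) log hazard ratios vs No NPS.
    log_hr: dict = field(default_factory=lambda: dict(_DEFAULT_LOG_HR))
    #: Per-visit probability that a No-NPS participant becomes (and stays)
    #: symptomatic, exercising the time-varying exposure machinery.
    transition_prob: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise SimConfigError("n_participants must be >= 1")
        if not 0 <= self.fraction_mci <= 1:
            raise SimConfigError("fraction_mci must be in [0, 1]")
        p = self.nps_prevalence
        if len(p) != 3 or any(not 0 <= x <= 1 for x in p):
            raise SimConfigError("nps_prevalence entries must be in [0, 1]")
        # printed prevalences may carry rounding error; renormalized at draw time
        if abs(sum(p) - 1.0) > 5e-3:
            raise SimConfigError(f"nps_prevalence must sum to 1, got {sum(p)}")
        if not 0 <= self.psychiatric_history_prevalence <= 1:
            raise SimConfigError("psychiatric_history_prevalence must be in [0, 1]")
        if not 2 <= self.min_visits <= self.max_visits:
            raise SimConfigError("need 2 <= min_visits <= max_visits")
        if p[2] > 0 and self.max_visits < 2:
            raise SimConfigError("MBI prevalence > 0 requires follow-up visits")
        for s in ("nc", "mci"):
            if self.baseline_hazard[s] <= 0:
                raise SimConfigError(f"baseline hazard for {s} must be > 0")
        if self.residual_sd < 0:
            raise SimConfigError("residual_sd must be >= 0")


@dataclass
class SimTruth:
    """Generating labels and planted parameter values for a simulated cohort."""

    group_labels: dict[str, NPSStatus]
    strata: dict[str, str]  # participant id -> "nc" | "mci"
    config: SimConfig


def _no_nps_history_prob(cfg: SimConfig) -> float:
    """Psychiatric-history probability for No-NPS participants, solved so the
    cohort-wide prevalence matches its target (MBI participants never carry a
    history; non-MBI carry one at the configured fraction)."""
    p_no, p_non, _ = cfg.nps_prevalence
    if p_no == 0:
        return 0.0
    p = (cfg.psychiatric_history_prevalence - p_non * cfg.nonmbi_history_fraction) / p_no
    return min(max(p, 0.0), 1.0)


def _draw_npiq(rng: np.random.Generator, symptomatic: bool) -> NPIQRecord:
    """One visit's NPI-Q items.  Symptomatic visits endorse 1-3 mapped items
    at severity 1-3; neurovegetative items vary independently of NPS group."""
    sev = {item: 0 for item in NPIQ_ITEMS}
    if symptomatic:
        k = int(rng.integers(1, 4))
        for item in rng.choice(len(MAPPED_ITEMS), size=k, replace=False):
            sev[MAPPED_ITEMS[item]] = int(rng.integers(1, 4))
    for item in NEUROVEGETATIVE_ITEMS:
        sev[item] = int(rng.choice(4, p=[0.7, 0.15, 0.1, 0.05]))
    return NPIQRecord(**sev)


def _symptom_pattern(
    rng: np.random.Generator, group: NPSStatus, history: bool, n_visits: int,
    transition_prob: float,
) -> list[bool]:
    """Which planned visits are symptomatic (global score >= 1).

    MBI and history-attributable non-MBI participants are symptomatic at every
    visit; impersistent non-MBI participants are symptomatic at every third
    visit starting from baseline (fraction <= 1/2 for any series of >= 2
    visits, hence never persistent); No-NPS participants start asymptomatic
    but may convert, with a small per-visit probability, to intermittent
    symptoms (every third visit from conversion).  Intermittent patterns keep
    the three-way classification invariant to where follow-up ends, so the
    status driving the simulated hazard is the status the analysis recovers.
    """
    if group is NPSStatus.MBI:
        return [True] * n_visits
    if group is NPSStatus.NON_MBI_NPS:
        if history:
            return [True] * n_visits
        return [j % 3 == 0 for j in range(n_visits)]
    pattern = [False] * n_visits
    for j in range(1, n_visits):
        if rng.random() < transition_prob:
            pattern[j:] = [(i - j) % 3 == 0 for i in range(j, n_visits)]
            break
    return pattern


def _draw_covariates(rng: np.random.Generator, stratum: str) -> Covariates:
    mu, sd = _AGE_DIST[stratum]
    age = float(rng.normal(mu, sd))
    while age < 50:
        age = float(rng.normal(mu, sd))
    mu_e, sd_e = _EDU_DIST[stratum]
    edu = max(0.0, float(rng.normal(mu_e, sd_e)))
    return Covariates(
        age_baseline=age,
        sex="female" if rng.random() < _FEMALE_PROB[stratum] else "male",
        education_years=edu,
        race=_RACES[int(rng.choice(len(_RACES), p=_RACE_PROBS))],
        apoe4_count=int(rng.choice(3, p=_APOE4_PROBS[stratum])),
        scan_gap_days=float(rng.uniform(0, 120)),
    )


def _event_time(
    rng: np.random.Generator,
    statuses: list[Optional[NPSStatus]],
    times: list[float],
    base_rate: float,
    log_hr: tuple[float, float],
) -> Optional[float]:
    """Latent progression time by interval-wise inversion of the cumulative
    hazard, constant between consecutive visits; None if censored at the
    last planned visit."""
    mult = {
        NPSStatus.NO_NPS: 1.0,
        NPSStatus.NON_MBI_NPS: math.exp(log_hr[0]),
        NPSStatus.MBI: math.exp(log_hr[1]),
    }
    target = rng.exponential(1.0)
    acc = 0.0
    for j in range(len(times) - 1):
        rate = base_rate * mult[statuses[j] or NPSStatus.NO_NPS]
        width = times[j + 1] - times[j]
        if acc + rate * width >= target:
            return times[j] + (target - acc) / rate
        acc += rate * width
    return None


def simulate_cohort(config: SimConfig) -> tuple[list[ParticipantHistory], SimTruth]:
    """Draw a full synthetic cohort; identical config and seed reproduce it."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    p_hist_nonps = _no_nps_history_prob(config)
    groups = (NPSStatus.NO_NPS, NPSStatus.NON_MBI_NPS, NPSStatus.MBI)
    prev = np.asarray(config.nps_prevalence, dtype=float)
    prev = prev / prev.sum()

    cohort: list[ParticipantHistory] = []
    labels: dict[str, NPSStatus] = {}
    strata: dict[str, str] = {}
    for i in range(config.n_participants):
        pid = f"P{i:05d}"
        stratum = "mci" if rng.random() < config.fraction_mci else "nc"
        base_status = CognitiveStatus.MCI if stratum == "mci" else CognitiveStatus.NC
        group = groups[int(rng.choice(3, p=prev))]
        if group is NPSStatus.MBI:
            history = False
        elif group is NPSStatus.NON_MBI_NPS:
            history = bool(rng.random() < config.nonmbi_history_fraction)
        else:
            history = bool(rng.random() < p_hist_nonps)

        cov = _draw_covariates(rng, stratum)
        n_visits = int(rng.integers(config.min_visits, config.max_visits + 1))
        times = [float(t) for t in range(n_visits)]
        symptomatic = _symptom_pattern(
            rng, group, history, n_visits, config.transition_prob
        )
        visits = [
            VisitRecord(t, base_status, npiq=_draw_npiq(rng, s))
            for t, s in zip(times, symptomatic)
        ]
        planned = ParticipantHistory(pid, history, cov, visits)
        statuses = classify_history(planned, "retrospective")

        te = _event_time(
            rng, statuses, times, config.baseline_hazard[stratum],
            config.log_hr[stratum],
        )
        if te is not None:
            kept = [v for v in visits if v.visit_time < te]
            if stratum == "mci":
                # dementia diagnosis visit: NPI-Q plays no further role
                event_visit = VisitRecord(te, CognitiveStatus.DEMENTIA, npiq=None)
            else:
                # incident-MCI visit is still dementia-free and assessed; its
                # symptom state continues the pattern of the visit it replaces
                j_next = len(kept)  # index of the first planned visit at/after te
                event_visit = VisitRecord(
                    te, CognitiveStatus.MCI,
                    npiq=_draw_npiq(rng, symptomatic[j_next]),
                )
            kept.append(event_visit)
            planned = ParticipantHistory(pid, history, cov, kept)

        planned.visits[0].imaging = _draw_imaging(rng, config, stratum, group, cov)
        cohort.append(planned)
        labels[pid] = group
        strata[pid] = stratum
    return cohort, SimTruth(labels, strata, config)


def _draw_imaging(
    rng: np.random.Generator, cfg: SimConfig, stratum: str, group: NPSStatus,
    cov: Covariates,
) -> ImagingZ:
    covariate_part = (
        cfg.education_effect * (cov.education_years - 16.0)
        + cfg.apoe4_effect * cov.apoe4_count
        + cfg.scan_gap_effect * cov.scan_gap_days
    )
    z = {}
    for roi in ROIS:
        non, mbi = cfg.imaging_shifts[stratum][roi]
        shift = {NPSStatus.NO_NPS: 0.0, NPSStatus.NON_MBI_NPS: non,
                 NPSStatus.MBI: mbi}[group]
        z[roi] = shift + covariate_part + float(rng.normal(0.0, cfg.residual_sd))
    return ImagingZ(z["hippocampus"], z["entorhinal"], z["metaroi"])


def write_fixture(
    cohort: list[ParticipantHistory], path, truth: Optional[SimTruth] = None
) -> None:
    """Write the cohort in the long-format CSV dialect the pipeline reads;
    optionally write the generating truth as a sidecar JSON next to it."""
    from . import io as _io  # local import: io depends on classify, not on us

    _io.write_visit_table(cohort, path)
    if truth is not None:
        import json
        from pathlib import Path

        sidecar = Path(path).with_suffix(".truth.json")
        payload = {
            "group_labels": {k: v.value for k, v in truth.group_labels.items()},
            "strata": truth.strata,
            "config": {
                k: v for k, v in asdict(truth.config).items()
            },
        }
        sidecar.write_text(json.dumps(payload, indent=1, sort_keys=True))
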