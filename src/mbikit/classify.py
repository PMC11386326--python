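"""Inclusion filtering, symptom persistence, and three-way NPS classification.

Each visit of a dementia-free participant is assigned one of three
neuropsychiatric-symptom (NPS) states:

* ``NO_NPS``      — global MBI severity score 0;
* ``NON_MBI_NPS`` — score >= 1, but with a psychiatric history and/or
                    impersistent symptoms;
* ``MBI``         — score >= 1, persistent, and not attributable to a
                    psychiatric condition (de novo later-life emergence).

Persistence is symptom presence in strictly more than two-thirds of a
participant's dementia-free visits; a fraction of exactly 2/3 is
impersistent.  By default persistence is evaluated retrospectively over the
full dementia-free visit series and applied to every visit; a prospective
(visits-so-far) mode is available for sensitivity analyses.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .npiq import MBIDomainScores, NPIQRecord, score_mbi


class CognitiveStatus(enum.Enum):
    NC = "nc"
    MCI = "mci"
    DEMENTIA = "dementia"


class NPSStatus(enum.Enum):
    NO_NPS = "no_nps"
    NON_MBI_NPS = "non_mbi_nps"
    MBI = "mbi"


class PersistenceUndefinedError(ValueError):
    """No scorable dementia-free visit; the persistence fraction is undefined."""


class EmptyCohortError(ValueError):
    """Every participant was excluded by the inclusion filters."""


@dataclass(frozen=True)
class Covariates:
    """Baseline covariates used for adjustment in all models."""

    age_baseline: float
    sex: str  # "female" | "male"
    education_years: float
    race: str  # White / Asian / Black / Hispanic / Indigenous / Other
    apoe4_count: Optional[int]  # 0, 1, 2 or None when genotype is missing
    scan_gap_days: float = 0.0  # time between clinical and scanning visits

    def __post_init__(self) -> None:
        if self.apoe4_count is not None and self.apoe4_count not in (0, 1, 2):
            raise ValueError(f"apoe4_count must be 0, 1 or 2; got {self.apoe4_count}")


@dataclass(frozen=True)
class ImagingZ:
    """Normatively standardized structural measures (Z scores, bilateral means)."""

    hippocampus: float
    entorhinal: float
    metaroi_thickness: float


@dataclass
class VisitRecord:
    visit_time: float  # years since baseline
    cognitive_status: CognitiveStatus
    npiq: Optional[NPIQRecord] = None
    imaging: Optional[ImagingZ] = None

    @property
    def dementia_free(self) -> bool:
        return self.cognitive_status is not CognitiveStatus.DEMENTIA

    def mbi_scores(self) -> Optional[MBIDomainScores]:
        """MBI scores for this visit, or None when the NPI-Q is unscorable."""
        if self.npiq is None or not self.npiq.scorable:
            return None
        return score_mbi(self.npiq)

    def global_score(self) -> Optional[int]:
        s = self.mbi_scores()
        return None if s is None else s.global_score


@dataclass
class ParticipantHistory:
    participant_id: str
    psychiatric_history: bool
    covariates: Covariates
    visits: list[VisitRecord] = field(default_factory=list)
    qc_pass: bool = True

    def __post_init__(self) -> None:
        if not self.visits:
            raise ValueError(f"participant {self.participant_id}: no visits")
        times = [v.visit_time for v in self.visits]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(
                f"participant {self.participant_id}: visit times not strictly increasing"
            )

    @property
    def baseline(self) -> VisitRecord:
        return self.visits[0]

    def dementia_free_visits(self) -> list[VisitRecord]:
        return [v for v in self.visits if v.dementia_free]


# ---------------------------------------------------------------------------
# Inclusion filtering

#: (rule order, reason label, predicate returning True when EXCLUDED)
_EXCLUSION_RULES = (
    (1, "baseline not dementia-free",
     lambda p: p.baseline.cognitive_status is CognitiveStatus.DEMENTIA),
    (2, "age under 50 at baseline",
     lambda p: p.covariates.age_baseline < 50),
    (3, "missing NPI-Q",
     lambda p: p.baseline.npiq is None or not p.baseline.npiq.scorable),
    (4, "failed scan quality control",
     lambda p: not p.qc_pass),
    (5, "missing APOE4",
     lambda p: p.covariates.apoe4_count is None),
)


@dataclass(frozen=True)
class Exclusion:
    participant_id: str
    reason: str
    rule_order: int


def apply_inclusion_filters(
    cohort: Sequence[ParticipantHistory],
) -> tuple[list[ParticipantHistory], list[Exclusion]]:
    """Retain eligible participants; log one (first-matching) reason per exclusion.

    Eligibility: dementia-free and aged >= 50 at baseline, scorable baseline
    NPI-Q, passing scan QC, and known APOE4 allele count.
    """
    retained: list[ParticipantHistory] = []
    log: list[Exclusion] = []
    for p in cohort:
        for order, reason, excluded in _EXCLUSION_RULES:
            if excluded(p):
                log.append(Exclusion(p.participant_id, reason, order))
                break
        else:
            retained.append(p)
    if cohort and not retained:
        raise EmptyCohortError("no participants remain after inclusion filtering")
    return retained, log


# ---------------------------------------------------------------------------
# Persistence and visit-level classification


def compute_persistence(
    history: ParticipantHistory, upto_time: Optional[float] = None
) -> tuple[float, bool]:
    """Fraction of scorable dementia-free visits with any symptom, and whether
    it strictly exceeds 2/3.

    Visits with missing NPI-Q are excluded from numerator and denominator.
    ``upto_time`` restricts the window to visits at or before that time
    (prospective mode); by default all dementia-free visits count.
    """
    scores = [
        g
        for v in history.dementia_free_visits()
        if (upto_time is None or v.visit_time <= upto_time)
        and (g := v.global_score()) is not None
    ]
    if not scores:
        raise PersistenceUndefinedError(
            f"participant {history.participant_id}: persistence undefined "
            "(no scorable dementia-free visit)"
        )
    n_present = sum(1 for g in scores if g >= 1)
    # strict "> 2/3" comparison kept exact in integer arithmetic
    return n_present / len(scores), 3 * n_present > 2 * len(scores)


def classify_visit(
    global_score: int, psychiatric_history: bool, persistent: bool
) -> NPSStatus:
    """Three-way NPS rule for a single scored visit."""
    if global_score == 0:
        return NPSStatus.NO_NPS
    if psychiatric_history or not persistent:
        return NPSStatus.NON_MBI_NPS
    return NPSStatus.MBI


def classify_history(
    history: ParticipantHistory, persistence_mode: str = "retrospective"
) -> list[Optional[NPSStatus]]:
    """Per-visit NPS status with last-observation-carried-forward.

    A visit with an unscorable NPI-Q inherits the status of the most recent
    scorable visit (None before any scorable visit).  In retrospective mode a
    single persistence flag, computed over the entire dementia-free series,
    applies to all visits; in prospective mode persistence is recomputed per
    visit over visits up to and including it.
    """
    if persistence_mode not in ("retrospective", "prospective"):
        raise ValueError(f"unknown persistence mode {persistence_mode!r}")
    if persistence_mode == "retrospective":
        _, persistent_all = compute_persistence(history)

    statuses: list[Optional[NPSStatus]] = []
    current: Optional[NPSStatus] = None
    for v in history.visits:
        g = v.global_score()
        if g is not None:
            if persistence_mode == "retrospective":
                persistent = persistent_all
            else:
                try:
                    _, persistent = compute_persistence(history, upto_time=v.visit_time)
                except PersistenceUndefinedError:
                    persistent = False
            current = classify_visit(g, history.psychiatric_history, persistent)
        statuses.append(current)
    return statuses


def baseline_status(
    history: ParticipantHistory, persistence_mode: str = "retrospective"
) -> Optional[NPSStatus]:
    """NPS group at the baseline visit (the cross-sectional exposure)."""
    return classify_history(history, persistence_mode)[0]


# ---------------------------------------------------------------------------
# Outcome derivation


@dataclass(frozen=True)
class Outcome:
    event: bool
    event_time: float  # years since baseline
    label: str  # "mci_or_dementia" (NC baseline) | "dementia" (MCI baseline)
    no_followup: bool = False


def derive_outcome(history: ParticipantHistory) -> Outcome:
    """Incident cognitive decline: NC -> (MCI or dementia); MCI -> dementia.

    The event is located at the visit date of the first changed diagnosis;
    otherwise the participant is censored at the last visit.  A single-visit
    participant is censored at time 0 and flagged as having no follow-up.
    """
    base = history.baseline.cognitive_status
    if base is CognitiveStatus.DEMENTIA:
        raise ValueError(
            f"participant {history.participant_id}: baseline already dementia"
        )
    if base is CognitiveStatus.NC:
        label = "mci_or_dementia"
        hit = (CognitiveStatus.MCI, CognitiveStatus.DEMENTIA)
    else:
        label = "dementia"
        hit = (CognitiveStatus.DEMENTIA,)

    if len(history.visits) == 1:
        return Outcome(False, 0.0, label, no_followup=True)
    for v in history.visits[1:]:
        if v.cognitive_status in hit:
            return Outcome(True, v.visit_time - history.baseline.visit_time, label)
    return Outcome(
        False, history.visits[-1].visit_time - history.baseline.visit_time, label
    )
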