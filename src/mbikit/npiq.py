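"""NPI-Q item severities and their mapping onto MBI domain scores.

The Neuropsychiatric Inventory Questionnaire (NPI-Q) is an informant-rated
instrument with 12 symptom domains, each scored 0-3 for severity over the
past month (0 = absent).  Mild behavioral impairment (MBI) domain scores are
derived from ten of the twelve items; the two neurovegetative items
(nighttime behaviors, appetite/eating) are excluded by the MBI criteria:

* decreased motivation (0-3): apathy
* affective dysregulation (0-9): depression/dysphoria + anxiety + elation/euphoria
* impulse dyscontrol (0-9): agitation + irritability + aberrant motor behavior
* social inappropriateness (0-3): disinhibition
* abnormal perception or thought content (0-6): delusions + hallucinations

The global MBI severity score (0-30) is the sum of the five domain scores.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional

NPIQ_ITEMS = (
    "delusions",
    "hallucinations",
    "agitation",
    "depression_dysphoria",
    "anxiety",
    "elation_euphoria",
    "apathy",
    "disinhibition",
    "irritability",
    "aberrant_motor",
    "nighttime_behaviors",
    "appetite_eating",
)

#: Items excluded from MBI scoring (neurovegetative symptoms).
NEUROVEGETATIVE_ITEMS = ("nighttime_behaviors", "appetite_eating")

#: MBI domain -> contributing NPI-Q items.
MBI_DOMAIN_MAP = {
    "decreased_motivation": ("apathy",),
    "affective_dysregulation": ("depression_dysphoria", "anxiety", "elation_euphoria"),
    "impulse_dyscontrol": ("agitation", "irritability", "aberrant_motor"),
    "social_inappropriateness": ("disinhibition",),
    "abnormal_perception": ("delusions", "hallucinations"),
}

#: The ten items that feed MBI scoring, in canonical order.
MAPPED_ITEMS = tuple(i for items in MBI_DOMAIN_MAP.values() for i in items)


class NPIQValidationError(ValueError):
    """An NPI-Q severity is non-integer or outside {0,1,2,3}."""


class MissingItemError(ValueError):
    """A mapped NPI-Q item required for MBI scoring is missing.

    Missingness propagates to exclusion of the visit from scoring rather than
    being imputed as zero.
    """


@dataclass(frozen=True)
class NPIQRecord:
    """One visit's NPI-Q item severities.

    Each field is an integer severity in {0, 1, 2, 3}, or ``None`` when the
    item was not assessed.  Severity 0 means the symptom is absent.
    """

    delusions: Optional[int] = None
    hallucinations: Optional[int] = None
    agitation: Optional[int] = None
    depression_dysphoria: Optional[int] = None
    anxiety: Optional[int] = None
    elation_euphoria: Optional[int] = None
    apathy: Optional[int] = None
    disinhibition: Optional[int] = None
    irritability: Optional[int] = None
    aberrant_motor: Optional[int] = None
    nighttime_behaviors: Optional[int] = None
    appetite_eating: Optional[int] = None

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None:
                continue
            if isinstance(v, bool) or not isinstance(v, int):
                raise NPIQValidationError(
                    f"NPI-Q item {f.name!r}: severity must be an integer 0-3, got {v!r}"
                )
            if not 0 <= v <= 3:
                raise NPIQValidationError(
                    f"NPI-Q item {f.name!r}: severity {v} outside {{0,1,2,3}}"
                )

    def missing_mapped_items(self) -> tuple[str, ...]:
        """Names of MBI-mapped items that are missing at this visit."""
        return tuple(i for i in MAPPED_ITEMS if getattr(self, i) is None)

    @property
    def scorable(self) -> bool:
        """True when all ten MBI-mapped items are non-missing."""
        return not self.missing_mapped_items()


@dataclass(frozen=True)
class MBIDomainScores:
    """MBI domain scores plus the global severity score for one visit."""

    decreased_motivation: int
    affective_dysregulation: int
    impulse_dyscontrol: int
    social_inappropriateness: int
    abnormal_perception: int
    global_score: int

    _RANGES = {
        "decreased_motivation": 3,
        "affective_dysregulation": 9,
        "impulse_dyscontrol": 9,
        "social_inappropriateness": 3,
        "abnormal_perception": 6,
        "global_score": 30,
    }

    def __post_init__(self) -> None:
        for name, hi in self._RANGES.items():
            v = getattr(self, name)
            if not isinstance(v, int) or not 0 <= v <= hi:
                raise ValueError(f"{name} = {v!r} outside its range 0-{hi}")
        domain_sum = (
            self.decreased_motivation
            + self.affective_dysregulation
            + self.impulse_dyscontrol
            + self.social_inappropriateness
            + self.abnormal_perception
        )
        if self.global_score != domain_sum:
            raise ValueError(
                f"global_score {self.global_score} != sum of domains {domain_sum}"
            )


def score_mbi(npiq: NPIQRecord) -> MBIDomainScores:
    """Compute MBI domain scores and global severity from an NPI-Q record.

    Raises
    ------
    MissingItemError
        If any of the ten mapped items is missing; the visit is unscorable.
    """
    missing = npiq.missing_mapped_items()
    if missing:
        raise MissingItemError(
            "cannot score MBI: missing NPI-Q item(s) " + ", ".join(missing)
        )
    domains = {
        domain: sum(getattr(npiq, item) for item in items)
        for domain, items in MBI_DOMAIN_MAP.items()
    }
    return MBIDomainScores(global_score=sum(domains.values()), **domains)


def nps_present(scores: MBIDomainScores) -> bool:
    """Whether any neuropsychiatric symptom is present (global score >= 1)."""
    return scores.global_score >= 1
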