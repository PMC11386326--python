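import pytest

from mbikit.classify import (
    CognitiveStatus,
    Covariates,
    ParticipantHistory,
    VisitRecord,
)
from mbikit.npiq import NPIQRecord


def npiq(**items) -> NPIQRecord:
    """NPI-Q record with every item 0 except the given overrides."""
    sev = {item: 0 for item in NPIQRecord.__dataclass_fields__}
    sev.update(items)
    return NPIQRecord(**sev)


def npiq_with_score(score: int) -> NPIQRecord:
    """Record whose global MBI score equals ``score`` (0-9), spread over items."""
    assert 0 <= score <= 9
    parts = {}
    for item in ("apathy", "depression_dysphoria", "irritability"):
        take = min(3, score)
        parts[item] = take
        score -= take
    return npiq(**parts)


def make_covariates(age=70.0, apoe4=1, **kw) -> Covariates:
    defaults = dict(
        age_baseline=age, sex="female", education_years=16.0,
        race="White", apoe4_count=apoe4, scan_gap_days=30.0,
    )
    defaults.update(kw)
    return Covariates(**defaults)


def make_history(
    scores,
    *,
    pid="P1",
    history=False,
    statuses=None,
    times=None,
    qc=True,
    age=70.0,
    apoe4=1,
):
    """Participant with one visit per entry of ``scores``.

    ``scores[i]`` is the visit's global MBI score (int) or None for a missing
    NPI-Q.  ``statuses`` optionally gives per-visit cognitive status codes
    ("nc"/"mci"/"dementia"); default all NC.
    """
    n = len(scores)
    times = times if times is not None else list(range(n))
    statuses = statuses if statuses is not None else ["nc"] * n
    visits = [
        VisitRecord(
            visit_time=float(t),
            cognitive_status=CognitiveStatus(s),
            npiq=None if g is None else npiq_with_score(g),
        )
        for t, s, g in zip(times, statuses, scores)
    ]
    return ParticipantHistory(
        participant_id=pid,
        psychiatric_history=history,
        covariates=make_covariates(age=age, apoe4=apoe4),
        visits=visits,
        qc_pass=qc,
    )


@pytest.fixture
def eligible_participant():
    return make_history([1, 1, 0])
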