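"""Reading and writing the long-format per-visit cohort table.

One CSV row per participant-visit.  Columns:

``participant_id, visit_time, cognitive_status, psychiatric_history,
qc_pass, age_baseline, sex, education_years, race, apoe4_count,
scan_gap_days, npiq_<item> (x12), z_hippocampus, z_entorhinal, z_metaroi``

``cognitive_status`` is one of ``nc``/``mci``/``dementia``.  NPI-Q item
columns hold integer severities 0-3 and are left empty when the item is
missing; imaging Z columns are typically present at baseline only.
Participant-level fields (history, QC, covariates) are repeated on every row
of the participant and must be constant within participant.
"""

from __future__ import annotations

import math
from typing import Sequence

import pandas as pd

from .classify import (
    CognitiveStatus,
    Covariates,
    ImagingZ,
    ParticipantHistory,
    VisitRecord,
)
from .npiq import NPIQ_ITEMS, NPIQRecord

NPIQ_COLUMNS = tuple(f"npiq_{item}" for item in NPIQ_ITEMS)
Z_COLUMNS = ("z_hippocampus", "z_entorhinal", "z_metaroi")
COLUMNS = (
    "participant_id", "visit_time", "cognitive_status", "psychiatric_history",
    "qc_pass", "age_baseline", "sex", "education_years", "race", "apoe4_count",
    "scan_gap_days", *NPIQ_COLUMNS, *Z_COLUMNS,
)


class SchemaError(ValueError):
    """The visit table violates the documented schema."""


def write_visit_table(cohort: Sequence[ParticipantHistory], path) -> None:
    rows = []
    for p in cohort:
        for v in p.visits:
            row = {
                "participant_id": p.participant_id,
                "visit_time": v.visit_time,
                "cognitive_status": v.cognitive_status.value,
                "psychiatric_history": int(p.psychiatric_history),
                "qc_pass": int(p.qc_pass),
                "age_baseline": p.covariates.age_baseline,
                "sex": p.covariates.sex,
                "education_years": p.covariates.education_years,
                "race": p.covariates.race,
                "apoe4_count": p.covariates.apoe4_count,
                "scan_gap_days": p.covariates.scan_gap_days,
            }
            for col, item in zip(NPIQ_COLUMNS, NPIQ_ITEMS):
                row[col] = None if v.npiq is None else getattr(v.npiq, item)
            row["z_hippocampus"] = None if v.imaging is None else v.imaging.hippocampus
            row["z_entorhinal"] = None if v.imaging is None else v.imaging.entorhinal
            row["z_metaroi"] = None if v.imaging is None else v.imaging.metaroi_thickness
            rows.append(row)
    frame = pd.DataFrame(rows, columns=list(COLUMNS))
    frame.to_csv(path, index=False, lineterminator="\n")


def _opt_int(value):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return int(value)


def _opt_float(value):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def read_visit_table(path) -> list[ParticipantHistory]:
    """Parse and validate the long-format visit table.

    Raises :class:`SchemaError` on missing columns, duplicated
    (participant, visit_time) rows, non-monotone visit times, unknown
    cognitive-status codes, or participant-level fields varying within a
    participant.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"visit table missing columns: {', '.join(missing)}")
    if frame.empty:
        raise SchemaError("visit table contains no rows")

    dupes = frame.duplicated(subset=["participant_id", "visit_time"])
    if dupes.any():
        pid = frame.loc[dupes, "participant_id"].iloc[0]
        raise SchemaError(f"duplicate (participant, visit_time) row for {pid!r}")
    bad_status = set(frame["cognitive_status"]) - {s.value for s in CognitiveStatus}
    if bad_status:
        raise SchemaError(f"unknown cognitive status code(s): {sorted(bad_status)}")

    cohort: list[ParticipantHistory] = []
    for pid, grp in frame.groupby("participant_id", sort=False):
        times = grp["visit_time"].to_numpy()
        if not (times[1:] > times[:-1]).all():
            raise SchemaError(f"visit times not strictly increasing for {pid!r}")
        for col in ("psychiatric_history", "qc_pass", "age_baseline", "sex",
                    "education_years", "race", "apoe4_count", "scan_gap_days"):
            if grp[col].nunique(dropna=False) > 1:
                raise SchemaError(f"participant-level column {col!r} varies for {pid!r}")
        first = grp.iloc[0]
        cov = Covariates(
            age_baseline=float(first["age_baseline"]),
            sex=str(first["sex"]),
            education_years=float(first["education_years"]),
            race=str(first["race"]),
            apoe4_count=_opt_int(first["apoe4_count"]),
            scan_gap_days=float(first["scan_gap_days"]),
        )
        visits = []
        for _, r in grp.iterrows():
            sev = {item: _opt_int(r[col]) for col, item in zip(NPIQ_COLUMNS, NPIQ_ITEMS)}
            npiq = None if all(v is None for v in sev.values()) else NPIQRecord(**sev)
            zs = [_opt_float(r[c]) for c in Z_COLUMNS]
            imaging = None if any(z is None for z in zs) else ImagingZ(*zs)
            visits.append(
                VisitRecord(
                    visit_time=float(r["visit_time"]),
                    cognitive_status=CognitiveStatus(r["cognitive_status"]),
                    npiq=npiq,
                    imaging=imaging,
                )
            )
        cohort.append(
            ParticipantHistory(
                participant_id=str(pid),
                psychiatric_history=bool(first["psychiatric_history"]),
                covariates=cov,
                visits=visits,
                qc_pass=bool(first["qc_pass"]),
            )
        )
    return cohort
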