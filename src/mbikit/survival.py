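"""Time-to-event analysis with NPS status as a time-varying exposure.

Visit histories are expanded into counting-process intervals — half-open
``(start, stop]`` segments on which the participant's NPS status is constant
(last observation carried forward), with the event attached to the final
interval only.  Kaplan–Meier curves summarize group-wise survival
non-parametrically; adjusted hazard ratios come from a Cox proportional
hazards model maximized over the counting-process rows (Efron tie
handling), and Schoenfeld / Martingale residuals provide the standard
proportional-hazards and linearity diagnostics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxTimeVaryingFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .classify import Covariates, ImagingZ, NPSStatus, Outcome, ParticipantHistory
from .results import ModelResult, TermEstimate

#: covariates of the fully adjusted hazard model (demographics, genotype,
#: clinic-to-scan gap, and the three baseline structural measures)
DEFAULT_COX_COVARIATES = (
    "age_baseline", "sex", "education_years", "race", "apoe4_count",
    "scan_gap_days", "z_hippocampus", "z_entorhinal", "z_metaroi",
)


@dataclass(frozen=True)
class CountingProcessRow:
    participant_id: str
    start: float
    stop: float
    event: bool
    status: NPSStatus
    covariates: Covariates
    imaging: Optional[ImagingZ] = None

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise ValueError(
                f"{self.participant_id}: interval ({self.start}, {self.stop}] empty"
            )


def expand_counting_process(
    history: ParticipantHistory,
    statuses: Sequence[Optional[NPSStatus]],
    outcome: Outcome,
) -> list[CountingProcessRow]:
    """One row per maximal run of constant NPS status during follow-up.

    ``statuses`` aligns with ``history.visits`` (``classify_history`` output).
    Interval times are years since baseline; the union of intervals spans
    (0, follow-up end] and the event flag sits on the final row only.
    """
    if len(statuses) != len(history.visits):
        raise ValueError("statuses must align with history.visits")
    follow_up = outcome.event_time
    if follow_up <= 0:
        warnings.warn(
            f"participant {history.participant_id}: zero-length follow-up",
            stacklevel=2,
        )
        return []
    if statuses[0] is None:
        raise ValueError(
            f"participant {history.participant_id}: baseline NPS status unavailable"
        )
    t0 = history.baseline.visit_time
    imaging = history.baseline.imaging
    rows: list[CountingProcessRow] = []
    seg_start = 0.0
    current = statuses[0]
    for visit, status in zip(history.visits[1:], statuses[1:]):
        t = visit.visit_time - t0
        if t >= follow_up:
            break
        if status is not None and status is not current:
            rows.append(
                CountingProcessRow(
                    history.participant_id, seg_start, t, False, current,
                    history.covariates, imaging,
                )
            )
            seg_start, current = t, status
    rows.append(
        CountingProcessRow(
            history.participant_id, seg_start, follow_up, outcome.event, current,
            history.covariates, imaging,
        )
    )
    return rows


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class SurvivalCurve:
    group: str
    times: np.ndarray  # distinct observed event times
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # number at risk just before each event time
    median: Optional[float]  # smallest t with S(t) <= 0.5; None if never
    n: int

    def step_function(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        ).assign(group=self.group)


def km_estimate(
    times: Sequence[float],
    events: Sequence[bool],
    group_labels: Sequence[str],
) -> list[SurvivalCurve]:
    """Product-limit estimator per group, with median survival time."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    labels = np.asarray(group_labels)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    curves = []
    for group in pd.unique(labels):
        mask = labels == group
        if not mask.any():
            raise ValueError(f"group {group!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        tab = kmf.event_table
        ev = tab[tab["observed"] > 0]
        median = float(kmf.median_survival_time_)
        curves.append(
            SurvivalCurve(
                group=str(group),
                times=ev.index.to_numpy(dtype=float),
                survival=kmf.survival_function_.loc[ev.index, "KM_estimate"].to_numpy(),
                at_risk=ev["at_risk"].to_numpy(),
                median=None if math.isinf(median) else median,
                n=int(mask.sum()),
            )
        )
    return curves


# ---------------------------------------------------------------------------
# Cox regression over counting-process rows


def counting_process_frame(
    rows: Sequence[CountingProcessRow],
    covariates: Sequence[str] = DEFAULT_COX_COVARIATES,
    rare_level_fraction: float = 0.02,
) -> pd.DataFrame:
    """Numeric design frame for the time-varying Cox fit.

    The three-level exposure enters as two indicators (``non_mbi_nps``,
    ``mbi``; No NPS reference); sex becomes a female indicator and race an
    indicator set with White as reference.  Race levels held by fewer than
    ``rare_level_fraction`` of participants are pooled into one indicator to
    avoid monotone partial likelihoods from near-empty cells.
    """
    n_participants = len({r.participant_id for r in rows})
    level_counts: dict[str, set] = {}
    for r in rows:
        level_counts.setdefault(r.covariates.race, set()).add(r.participant_id)
    floor = max(5, rare_level_fraction * n_participants)
    rare = {
        lvl for lvl, pids in level_counts.items()
        if lvl != "White" and len(pids) < floor
    }
    # a pooled cell that is itself near-empty folds into the reference
    pooled_label = (
        "Pooled"
        if sum(len(level_counts[lvl]) for lvl in rare) >= 5
        else "White"
    )

    def race_of(r: CountingProcessRow) -> str:
        return pooled_label if r.covariates.race in rare else r.covariates.race

    recs = []
    race_levels = sorted({race_of(r) for r in rows} - {"White"})
    for r in rows:
        rec = {
            "pid": r.participant_id,
            "start": r.start,
            "stop": r.stop,
            "event": int(r.event),
            "non_mbi_nps": int(r.status is NPSStatus.NON_MBI_NPS),
            "mbi": int(r.status is NPSStatus.MBI),
        }
        for cov in covariates:
            if cov == "sex":
                rec["sex_female"] = int(r.covariates.sex == "female")
            elif cov == "race":
                for lvl in race_levels:
                    rec[f"race_{lvl}"] = int(race_of(r) == lvl)
            elif cov.startswith("z_"):
                z = r.imaging
                val = {
                    "z_hippocampus": z.hippocampus if z else None,
                    "z_entorhinal": z.entorhinal if z else None,
                    "z_metaroi": z.metaroi_thickness if z else None,
                }[cov]
                rec[cov] = val
            else:
                rec[cov] = getattr(r.covariates, cov)
        recs.append(rec)
    return pd.DataFrame(recs)


def fit_cox_td(
    rows: Sequence[CountingProcessRow],
    covariates: Sequence[str] = DEFAULT_COX_COVARIATES,
    stratum: str = "",
) -> ModelResult:
    """Cox partial-likelihood fit with time-dependent NPS exposure.

    Risk set at an event time t comprises all rows with start < t <= stop;
    ties are handled by the Efron approximation.  Returns log hazard ratios
    with normal-theory standard errors, 95% CIs and Wald p-values.
    """
    frame = counting_process_frame(rows, covariates)
    if frame["event"].sum() == 0:
        raise ValueError("no events in the counting-process rows; cannot fit")
    n_before = len(frame)
    frame = frame.dropna()
    if len(frame) < n_before:
        warnings.warn(
            f"dropped {n_before - len(frame)} rows with missing covariates",
            stacklevel=2,
        )
    # constant columns (e.g. the indicator of an absent exposure level) carry
    # no information and make the Hessian singular
    constant = [
        c for c in frame.columns
        if c not in ("pid", "start", "stop", "event") and frame[c].nunique() == 1
    ]
    if constant:
        frame = frame.drop(columns=constant)
    ctv = CoxTimeVaryingFitter(penalizer=0.0)
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            ctv.fit(
                frame, id_col="pid", event_col="event",
                start_col="start", stop_col="stop",
            )
    except ConvergenceError as exc:
        raise ValueError(
            "Cox fit did not converge (possible monotone likelihood / complete "
            f"separation): {exc}"
        ) from exc
    for w in caught:
        if "norm(delta)" in str(w.message) or "non-unique" in str(w.message):
            raise ValueError(
                "Cox partial likelihood appears monotone (complete separation "
                f"in some covariate): {w.message}"
            )

    summary = ctv.summary
    terms = [
        TermEstimate(
            name=str(name),
            estimate=float(row["coef"]),
            se=float(row["se(coef)"]),
            ci_low=float(row["coef lower 95%"]),
            ci_high=float(row["coef upper 95%"]),
            p_value=float(row["p"]),
        )
        for name, row in summary.iterrows()
    ]
    return ModelResult(
        terms=terms,
        stratum=stratum,
        outcome="incident_decline",
        n_used=frame["pid"].nunique(),
        n_dropped=n_before - len(frame),
        design=frame,
    )


def hazard_ratio_report(result: ModelResult) -> pd.DataFrame:
    """Exponentiate the coefficient table into adjusted hazard ratios."""
    frame = result.to_frame()
    frame["aHR"] = np.exp(frame["estimate"])
    frame["aHR_ci_low"] = np.exp(frame["ci_low"])
    frame["aHR_ci_high"] = np.exp(frame["ci_high"])
    return frame


# ---------------------------------------------------------------------------
# Proportional-hazards and linearity diagnostics


@dataclass
class PHDiagnostics:
    #: per-covariate Pearson correlation of Schoenfeld residuals with event time
    ph_table: pd.DataFrame  # columns: covariate, rho, p
    #: Schoenfeld residual matrix, one row per event (indexed by event time)
    schoenfeld: pd.DataFrame
    #: Martingale residual per participant (for linearity inspection)
    martingale: pd.Series


def ph_diagnostics(result: ModelResult) -> PHDiagnostics:
    """Schoenfeld residuals at each event time plus a correlation-with-time
    test per covariate, and Breslow-baseline Martingale residuals per subject.

    Requires the design frame stored by :func:`fit_cox_td`.  No refitting is
    performed; with fewer than 3 events the diagnostics are undefined.
    """
    frame = result.design
    if frame is None:
        raise ValueError("result carries no design frame; fit with fit_cox_td")
    covs = [c for c in frame.columns if c not in ("pid", "start", "stop", "event")]
    X = frame[covs].to_numpy(dtype=float)
    beta = np.array([result[c].estimate for c in covs])
    w = np.exp(X @ beta)
    start = frame["start"].to_numpy(dtype=float)
    stop = frame["stop"].to_numpy(dtype=float)
    event = frame["event"].to_numpy(dtype=bool)

    ev_idx = np.flatnonzero(event)
    if ev_idx.size < 3:
        raise ValueError("fewer than 3 events: residual diagnostics undefined")

    resids = np.empty((ev_idx.size, len(covs)))
    ev_times = stop[ev_idx]
    order = np.argsort(ev_times)
    ev_idx, ev_times = ev_idx[order], ev_times[order]
    for k, (i, t) in enumerate(zip(ev_idx, ev_times)):
        at_risk = (start < t) & (t <= stop)
        wsum = w[at_risk].sum()
        resids[k] = X[i] - (w[at_risk] @ X[at_risk]) / wsum

    rows = []
    for j, cov in enumerate(covs):
        col = resids[:, j]
        if np.allclose(col, col[0]):
            rho, p = float("nan"), float("nan")
        else:
            rho, p = stats.pearsonr(ev_times, col)
        rows.append({"covariate": cov, "rho": float(rho), "p": float(p)})

    # Breslow baseline increments at distinct event times
    uniq_times, counts = np.unique(ev_times, return_counts=True)
    dlambda = np.empty_like(uniq_times)
    for k, t in enumerate(uniq_times):
        at_risk = (start < t) & (t <= stop)
        dlambda[k] = counts[k] / w[at_risk].sum()
    cumhaz = np.zeros(len(frame))
    for t, dl in zip(uniq_times, dlambda):
        in_interval = (start < t) & (t <= stop)
        cumhaz[in_interval] += dl
    cumhaz *= w
    per_subject = pd.DataFrame(
        {"pid": frame["pid"], "event": event.astype(int), "cumhaz": cumhaz}
    ).groupby("pid", sort=False).sum()
    martingale = per_subject["event"] - per_subject["cumhaz"]
    martingale.name = "martingale"

    return PHDiagnostics(
        ph_table=pd.DataFrame(rows),
        schoenfeld=pd.DataFrame(resids, index=pd.Index(ev_times, name="time"),
                                columns=covs),
        martingale=martingale,
    )
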