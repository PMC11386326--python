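"""End-to-end orchestration: filter -> score -> classify -> model -> report.

A run consumes either a long-format visit table or a simulation
configuration, applies the inclusion filters, derives per-visit NPS status
and the incident-decline outcome, fits the stratified imaging models and the
time-dependent survival models, and writes a reproducible report bundle:
coefficient tables, hazard-ratio tables, Kaplan–Meier step functions, the
exclusion log, a run log, and a JSON manifest (seed, config hash, versions)
sufficient to re-run the bundle bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .classify import (
    CognitiveStatus,
    ParticipantHistory,
    apply_inclusion_filters,
    classify_history,
    derive_outcome,
)
from .io import read_visit_table, write_visit_table
from .linear import OUTCOME_COLUMNS, fit_biomarker_model, table_like_report
from .results import ModelResult
from .simulate import SimConfig, simulate_cohort
from .survival import (
    DEFAULT_COX_COVARIATES,
    expand_counting_process,
    fit_cox_td,
    hazard_ratio_report,
    km_estimate,
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and partial outputs remain."""


@dataclass
class RunConfig:
    outdir: str
    input_path: Optional[str] = None
    sim: Optional[SimConfig] = None
    seed: int = 0
    stratum: str = "both"  # nc | mci | both
    persistence_mode: str = "retrospective"
    significance_threshold: float = 0.05
    cox_covariates: tuple = DEFAULT_COX_COVARIATES

    def validate(self) -> None:
        if (self.input_path is None) == (self.sim is None):
            raise ValueError("exactly one of input_path or sim must be given")
        if not 0 < self.significance_threshold < 1:
            raise ValueError("significance threshold must be in (0, 1)")
        if self.stratum not in ("nc", "mci", "both"):
            raise ValueError(f"unknown stratum {self.stratum!r}")


@dataclass
class ReportBundle:
    outdir: Path
    analysis_frame: pd.DataFrame
    linear_results: list[ModelResult]
    cox_results: dict[str, ModelResult]
    km_medians: dict[str, dict[str, Optional[float]]]
    log: list[str] = field(default_factory=list)


def build_analysis_frame(
    cohort: list[ParticipantHistory], persistence_mode: str = "retrospective"
) -> pd.DataFrame:
    """Per-participant baseline frame: stratum, baseline NPS group, covariates,
    imaging Z scores, and the derived incident-decline outcome."""
    rows = []
    for p in cohort:
        statuses = classify_history(p, persistence_mode)
        outcome = derive_outcome(p)
        cov = p.covariates
        z = p.baseline.imaging
        rows.append(
            {
                "participant_id": p.participant_id,
                "stratum": "mci"
                if p.baseline.cognitive_status is CognitiveStatus.MCI
                else "nc",
                "nps_status": statuses[0].value if statuses[0] else None,
                "psychiatric_history": p.psychiatric_history,
                "age_baseline": cov.age_baseline,
                "sex": cov.sex,
                "education_years": cov.education_years,
                "race": cov.race,
                "apoe4_count": cov.apoe4_count,
                "scan_gap_days": cov.scan_gap_days,
                "z_hippocampus": z.hippocampus if z else None,
                "z_entorhinal": z.entorhinal if z else None,
                "z_metaroi": z.metaroi_thickness if z else None,
                "event": outcome.event,
                "event_time": outcome.event_time,
                "no_followup": outcome.no_followup,
            }
        )
    return pd.DataFrame(rows)


def classified_visit_table(
    cohort: list[ParticipantHistory], persistence_mode: str = "retrospective"
) -> pd.DataFrame:
    """The long-format visit table with an appended ``nps_status`` column."""
    import io as _stdio

    buf = _stdio.StringIO()
    write_visit_table(cohort, buf)
    buf.seek(0)
    frame = pd.read_csv(buf, float_precision="round_trip")
    status_col = []
    for p in cohort:
        for s in classify_history(p, persistence_mode):
            status_col.append(s.value if s else None)
    frame["nps_status"] = status_col
    return frame


def _stage(name):
    def decorator(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return decorator


@_stage("load")
def _load_cohort(config: RunConfig) -> list[ParticipantHistory]:
    if config.input_path is not None:
        return read_visit_table(config.input_path)
    sim = dataclasses.replace(config.sim, seed=config.seed)
    cohort, _ = simulate_cohort(sim)
    return cohort


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis and write the report bundle to ``outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def note(msg: str) -> None:
        log.append(msg)
        print(msg, file=sys.stderr)

    cohort = _load_cohort(config)
    note(f"loaded {len(cohort)} participants")

    retained, exclusions = _stage("filter")(apply_inclusion_filters)(cohort)
    pd.DataFrame(
        [
            {"participant_id": e.participant_id, "reason": e.reason,
             "rule_order": e.rule_order}
            for e in exclusions
        ],
        columns=["participant_id", "reason", "rule_order"],
    ).to_csv(outdir / "exclusions.tsv", sep="\t", index=False)
    note(f"retained {len(retained)}, excluded {len(exclusions)}")

    frame = _stage("classify")(build_analysis_frame)(retained, config.persistence_mode)
    classified = _stage("classify")(classified_visit_table)(
        retained, config.persistence_mode
    )
    classified.to_csv(outdir / "classified_visits.csv", index=False)
    unscorable = int(frame["nps_status"].isna().sum())
    if unscorable:
        note(f"{unscorable} participants with unscorable baseline left unclassified")

    strata = ("nc", "mci") if config.stratum == "both" else (config.stratum,)

    linear_results: list[ModelResult] = []
    for stratum in strata:
        sub_n = int((frame["stratum"] == stratum).sum())
        if sub_n == 0:
            note(f"linear models for stratum {stratum!r} skipped: no participants")
            continue
        for outcome in OUTCOME_COLUMNS:
            res = _stage("associate")(fit_biomarker_model)(frame, outcome, stratum)
            linear_results.append(res)
            note(f"linear {stratum}/{outcome}: n={res.n_used}")
    if linear_results:
        table_like_report(linear_results).to_csv(
            outdir / "biomarker_models.tsv", sep="\t", index=False
        )

    cox_results: dict[str, ModelResult] = {}
    km_medians: dict[str, dict[str, Optional[float]]] = {}
    km_frames = []
    for stratum in strata:
        sub = frame[(frame["stratum"] == stratum) & frame["nps_status"].notna()]
        sub = sub[sub["event_time"] > 0]
        if sub.empty or sub["event"].sum() == 0:
            note(f"survival for stratum {stratum!r} skipped: no usable follow-up")
            continue
        curves = _stage("survive")(km_estimate)(
            sub["event_time"], sub["event"], sub["nps_status"]
        )
        km_medians[stratum] = {c.group: c.median for c in curves}
        for c in curves:
            km_frames.append(c.step_function().assign(stratum=stratum))

        rows = []
        by_id = {p.participant_id: p for p in retained}
        for pid in sub["participant_id"]:
            p = by_id[pid]
            rows.extend(
                expand_counting_process(
                    p, classify_history(p, config.persistence_mode), derive_outcome(p)
                )
            )
        res = _stage("survive")(fit_cox_td)(rows, config.cox_covariates, stratum)
        cox_results[stratum] = res
        note(f"cox {stratum}: n={res.n_used}, events={int(sub['event'].sum())}")
    if km_frames:
        pd.concat(km_frames).to_csv(outdir / "km_curves.tsv", sep="\t", index=False)
    if cox_results:
        pd.concat(
            [hazard_ratio_report(r) for r in cox_results.values()]
        ).to_csv(outdir / "hazard_ratios.tsv", sep="\t", index=False)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "config_sha256": _config_hash(config),
        "n_input": len(cohort),
        "n_retained": len(retained),
        "n_excluded": len(exclusions),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    return ReportBundle(outdir, frame, linear_results, cox_results, km_medians, log)


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d.pop("outdir")  # environmental, not part of the analysis definition
    d["cox_covariates"] = list(d["cox_covariates"])
    return d


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(_config_dict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()
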