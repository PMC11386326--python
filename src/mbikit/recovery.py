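"""Planted-parameter recovery experiments.

The pipeline cannot be validated against the restricted source cohort, so
its correctness argument is recovery: simulate cohorts whose generating
parameters equal the reported effect sizes, run the full ascertainment and
modelling chain, and compare the estimates with the planted values.  These
helpers define the stratum-specific study conditions (baseline NPS-group
prevalences per cognitive stratum) and run the replicated experiments.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import classify_history, derive_outcome
from .linear import fit_biomarker_model
from .pipeline import build_analysis_frame
from .simulate import SimConfig, simulate_cohort
from .survival import (
    DEFAULT_COX_COVARIATES,
    expand_counting_process,
    fit_cox_td,
    km_estimate,
)

#: Baseline (No NPS, non-MBI NPS, MBI) prevalences within each cognitive
#: stratum of the emulated cohort.
STRATUM_PREVALENCE = {
    "nc": (0.769, 0.182, 0.049),
    "mci": (0.406, 0.303, 0.291),
}


def stratum_config(stratum: str, n: int, seed: int, **overrides) -> SimConfig:
    """Single-stratum simulation with that stratum's observed NPS mix."""
    cfg = SimConfig(
        n_participants=n,
        fraction_mci=1.0 if stratum == "mci" else 0.0,
        nps_prevalence=STRATUM_PREVALENCE[stratum],
        seed=seed,
    )
    return dataclasses.replace(cfg, **overrides) if overrides else cfg


def cox_hr_recovery(
    stratum: str,
    n: int,
    seeds: Sequence[int],
    covariates: Sequence[str] = DEFAULT_COX_COVARIATES,
) -> pd.DataFrame:
    """Per-replicate exponentiated Cox coefficients for both NPS exposures.

    Each replicate simulates a fresh single-stratum cohort, classifies every
    visit, expands to counting-process rows and fits the adjusted
    time-dependent Cox model.  Columns: seed, hr_non_mbi, hr_mbi, n_events.
    """
    records = []
    for seed in seeds:
        cohort, _ = simulate_cohort(stratum_config(stratum, n, seed))
        rows = []
        n_events = 0
        for p in cohort:
            outcome = derive_outcome(p)
            n_events += outcome.event
            rows.extend(
                expand_counting_process(p, classify_history(p), outcome)
            )
        res = fit_cox_td(rows, covariates, stratum)
        records.append(
            {
                "seed": seed,
                "hr_non_mbi": float(np.exp(res["non_mbi_nps"].estimate)),
                "hr_mbi": float(np.exp(res["mbi"].estimate)),
                "n_events": int(n_events),
            }
        )
    return pd.DataFrame(records)


def linear_shift_recovery(
    n: int,
    seeds: Sequence[int],
    stratum: str = "nc",
    outcomes: Sequence[str] = ("metaroi", "hippocampus"),
) -> pd.DataFrame:
    """Per-replicate MBI coefficients from the stratified imaging models.

    One simulated cohort per seed; each requested outcome is fitted on the
    same cohort.  Columns: seed, outcome, mbi_coef, non_mbi_coef.
    """
    records = []
    for seed in seeds:
        cohort, _ = simulate_cohort(stratum_config(stratum, n, seed))
        frame = build_analysis_frame(cohort)
        for outcome in outcomes:
            res = fit_biomarker_model(frame, outcome, stratum)
            records.append(
                {
                    "seed": seed,
                    "outcome": outcome,
                    "mbi_coef": res["mbi"].estimate,
                    "non_mbi_coef": res["non_mbi_nps"].estimate,
                }
            )
    return pd.DataFrame(records)


def km_median_recovery(
    true_median: float,
    n: int,
    seeds: Sequence[int],
    censor_fraction: float = 0.1,
) -> list[Optional[float]]:
    """KM median from exponential samples with the given generating median.

    Event times are exponential with rate ln(2)/true_median.  Censoring
    times are Uniform(0, c_max), drawn independently of the event times,
    with c_max solved so the expected censored fraction equals
    ``censor_fraction``; each subject's observed time is the earlier of the
    two.
    """
    from scipy.optimize import brentq

    medians: list[Optional[float]] = []
    rate = np.log(2) / true_median
    if censor_fraction > 0:
        # P(C < T) = (1 - exp(-x)) / x for x = rate * c_max
        x = brentq(
            lambda v: (1 - np.exp(-v)) / v - censor_fraction, 1e-6, 1e4
        )
        c_max = x / rate
    for seed in seeds:
        rng = np.random.default_rng(seed)
        t = rng.exponential(1.0 / rate, size=n)
        if censor_fraction > 0:
            c = rng.uniform(0.0, c_max, size=n)
            obs = np.minimum(t, c)
            events = t <= c
        else:
            obs, events = t, np.ones(n, dtype=bool)
        curve = km_estimate(obs, events, ["all"] * n)[0]
        medians.append(curve.median)
    return medians
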