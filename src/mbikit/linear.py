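"""Stratified multivariable linear models of imaging Z scores on NPS group.

Within each cognitive stratum (NC, MCI), each normatively standardized
structural measure is regressed by ordinary least squares on the three-level
NPS group (No NPS reference, entered as two indicators) adjusting for years
of education, race/ethnicity (White reference), the clinic-to-scan time gap,
and the APOE4 allele count (a linear 0/1/2 term).  Coefficients are on the
Z-score scale: a coefficient of -0.5 for MBI means MBI participants average
half a normative standard deviation lower than No-NPS participants with the
same covariates.  Complete-case analysis; normal-theory standard errors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .results import ModelResult, TermEstimate

#: outcome key -> column in the analysis frame
OUTCOME_COLUMNS = {
    "hippocampus": "z_hippocampus",
    "entorhinal": "z_entorhinal",
    "metaroi": "z_metaroi",
}

_MODEL_VARS = ("nps_status", "education_years", "race", "scan_gap_days", "apoe4_count")

#: readable names for the patsy design terms
_TERM_NAMES = {
    "C(nps_status, Treatment('no_nps'))[T.non_mbi_nps]": "non_mbi_nps",
    "C(nps_status, Treatment('no_nps'))[T.mbi]": "mbi",
}


class RankDeficientDesignError(ValueError):
    """A model term has no variation (e.g. an empty factor level)."""


def fit_biomarker_model(data: pd.DataFrame, outcome: str, stratum: str) -> ModelResult:
    """OLS of one imaging Z score on NPS group plus covariates, one stratum.

    ``data`` is a per-participant baseline frame with columns ``nps_status``
    (values no_nps / non_mbi_nps / mbi), the covariates, ``stratum`` and the
    three ``z_*`` outcomes.  Rows outside ``stratum`` or with any missing
    model variable are dropped (and counted).
    """
    if outcome not in OUTCOME_COLUMNS:
        raise KeyError(f"unknown outcome {outcome!r}; expected one of "
                       f"{sorted(OUTCOME_COLUMNS)}")
    ycol = OUTCOME_COLUMNS[outcome]
    sub = data[data["stratum"] == stratum] if "stratum" in data.columns else data
    n_stratum = len(sub)
    cols = [ycol, *_MODEL_VARS]
    sub = sub.dropna(subset=cols)
    n_dropped = n_stratum - len(sub)

    n_params = 2 + 1 + (sub["race"].nunique() - 1) + 2 + 1  # nps + edu + race + gap/apoe + icpt
    if len(sub) < n_params + 2:
        raise ValueError(
            f"stratum {stratum!r}: only {len(sub)} complete cases for "
            f"{n_params} parameters"
        )
    if np.isclose(sub[ycol].var(ddof=0), 0.0):
        raise ValueError(f"outcome {outcome!r} has zero variance in stratum {stratum!r}")
    if "no_nps" not in set(sub["nps_status"]):
        raise RankDeficientDesignError(
            f"term 'nps_status': reference level 'no_nps' empty in stratum {stratum!r}"
        )
    if sub["nps_status"].nunique() < 2:
        raise RankDeficientDesignError(
            f"term 'nps_status': only one level observed in stratum {stratum!r}"
        )

    formula = (
        f"{ycol} ~ C(nps_status, Treatment('no_nps')) + education_years"
        " + C(race, Treatment('White')) + scan_gap_days + apoe4_count"
    )
    try:
        fit = smf.ols(formula, data=sub).fit()
    except Exception as exc:  # pragma: no cover - patsy-level failures
        raise RankDeficientDesignError(str(exc)) from exc
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise RankDeficientDesignError(
            f"design matrix rank-deficient in stratum {stratum!r}"
        )

    ci = fit.conf_int(alpha=0.05)
    terms = []
    for raw in fit.params.index:
        name = _TERM_NAMES.get(raw, raw)
        terms.append(
            TermEstimate(
                name=name,
                estimate=float(fit.params[raw]),
                se=float(fit.bse[raw]),
                ci_low=float(ci.loc[raw, 0]),
                ci_high=float(ci.loc[raw, 1]),
                p_value=float(fit.pvalues[raw]),
            )
        )
    return ModelResult(
        terms=terms, stratum=stratum, outcome=outcome,
        n_used=len(sub), n_dropped=n_dropped,
    )


def table_like_report(results: list[ModelResult]) -> pd.DataFrame:
    """Stack per-stratum, per-outcome NPS-group coefficients into one table
    (outcome x exposure rows with beta, 95% CI and p)."""
    rows = []
    for res in results:
        for term in ("non_mbi_nps", "mbi"):
            try:
                t = res[term]
            except KeyError:  # exposure level absent from this stratum
                continue
            rows.append(
                {
                    "stratum": res.stratum,
                    "outcome": res.outcome,
                    "exposure": term,
                    "beta": t.estimate,
                    "ci_low": t.ci_low,
                    "ci_high": t.ci_high,
                    "p": t.p_value,
                    "n": res.n_used,
                }
            )
    return pd.DataFrame(rows)
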