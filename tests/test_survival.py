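"""Counting-process expansion, Kaplan-Meier, time-varying Cox, diagnostics."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from mbikit.classify import NPSStatus, Outcome
from mbikit.survival import (
    CountingProcessRow,
    expand_counting_process,
    fit_cox_td,
    km_estimate,
    ph_diagnostics,
)
from conftest import make_covariates, make_history


def cp_row(pid, start, stop, event, status, **cov):
    return CountingProcessRow(
        pid, start, stop, event, status, make_covariates(**cov)
    )


def binary_rows(times, events, x):
    """Time-fixed binary exposure encoded as MBI vs No NPS."""
    return [
        cp_row(f"S{i}", 0.0, t, bool(e),
               NPSStatus.MBI if xi else NPSStatus.NO_NPS)
        for i, (t, e, xi) in enumerate(zip(times, events, x))
    ]


class TestExpansion:
    def test_status_change_splits_intervals(self):
        h = make_history([0, 1], statuses=["nc", "nc"])
        statuses = [NPSStatus.NO_NPS, NPSStatus.MBI]
        out = Outcome(event=True, event_time=2.5, label="mci_or_dementia")
        rows = expand_counting_process(h, statuses, out)
        assert [(r.start, r.stop, r.status, r.event) for r in rows] == [
            (0.0, 1.0, NPSStatus.NO_NPS, False),
            (1.0, 2.5, NPSStatus.MBI, True),
        ]

    def test_constant_status_single_row(self):
        h = make_history([1, 1, 1, 1])
        statuses = [NPSStatus.NON_MBI_NPS] * 4
        out = Outcome(event=False, event_time=3.0, label="mci_or_dementia")
        rows = expand_counting_process(h, statuses, out)
        assert len(rows) == 1
        assert (rows[0].start, rows[0].stop, rows[0].event) == (0.0, 3.0, False)

    def test_alternating_status_partitions_followup(self):
        h = make_history([1, 0, 1, 0])
        statuses = [NPSStatus.NON_MBI_NPS, NPSStatus.NO_NPS,
                    NPSStatus.NON_MBI_NPS, NPSStatus.NO_NPS]
        out = Outcome(event=True, event_time=3.5, label="mci_or_dementia")
        rows = expand_counting_process(h, statuses, out)
        assert len(rows) == 4
        assert sum(r.stop - r.start for r in rows) == pytest.approx(3.5)
        assert [r.event for r in rows] == [False, False, False, True]
        starts = [r.start for r in rows]
        stops = [r.stop for r in rows]
        assert starts[1:] == stops[:-1]  # contiguous

    def test_zero_length_followup_warns_and_returns_empty(self):
        h = make_history([0])
        out = Outcome(event=False, event_time=0.0, label="mci_or_dementia",
                      no_followup=True)
        with pytest.warns(UserWarning, match="zero-length"):
            assert expand_counting_process(h, [NPSStatus.NO_NPS], out) == []

    def test_status_changes_after_event_ignored(self):
        h = make_history([0, 1, 1])
        statuses = [NPSStatus.NO_NPS, NPSStatus.MBI, NPSStatus.NON_MBI_NPS]
        out = Outcome(event=True, event_time=1.5, label="mci_or_dementia")
        rows = expand_counting_process(h, statuses, out)
        assert rows[-1].stop == 1.5 and len(rows) == 2


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        curves = km_estimate([1, 2, 3, 4], [True] * 4, ["g"] * 4)
        c = curves[0]
        assert list(c.times) == [1, 2, 3, 4]
        assert list(c.survival) == pytest.approx([0.75, 0.5, 0.25, 0.0])
        assert list(c.at_risk) == [4, 3, 2, 1]
        assert c.median == pytest.approx(2.0)

    def test_all_censored_curve_flat_median_undefined(self):
        c = km_estimate([1, 2, 3], [False] * 3, ["g"] * 3)[0]
        assert len(c.times) == 0 and c.median is None

    def test_km_equals_one_minus_ecdf_without_censoring(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(2.0, size=50)
        c = km_estimate(t, [True] * 50, ["g"] * 50)[0]
        ecdf = np.searchsorted(np.sort(t), c.times, side="right") / 50
        assert c.survival == pytest.approx(1 - ecdf)

    def test_groups_estimated_separately(self):
        curves = km_estimate([1, 2, 1, 2], [True] * 4, ["a", "a", "b", "b"])
        assert {c.group for c in curves} == {"a", "b"}
        assert all(c.n == 2 for c in curves)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            km_estimate([-1.0], [True], ["g"])


def partial_loglik(beta, times, events, x):
    """Breslow partial log-likelihood for time-fixed data without ties."""
    ll = 0.0
    for i in np.flatnonzero(events):
        risk = times >= times[i]
        ll += beta * x[i] - np.log(np.exp(beta * np.asarray(x)[risk]).sum())
    return ll


class TestCox:
    def test_three_subject_toy_matches_brute_force(self):
        times = np.array([1.0, 2.0, 3.0])
        events = np.array([True, True, True])
        x = np.array([1, 0, 1])
        res = fit_cox_td(binary_rows(times, events, x), covariates=())
        grid = minimize_scalar(
            lambda b: -partial_loglik(b, times, events, x),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10},
        )
        assert res["mbi"].estimate == pytest.approx(grid.x, abs=1e-4)

    def test_estimates_invariant_to_time_scaling(self):
        rng = np.random.default_rng(11)
        n = 60
        x = rng.integers(0, 2, n)
        times = rng.exponential(1.0 / np.exp(0.7 * x))
        events = times < 2.0
        times = np.minimum(times, 2.0)
        a = fit_cox_td(binary_rows(times, events, x), covariates=())
        b = fit_cox_td(binary_rows(times * 3.7, events, x), covariates=())
        assert a["mbi"].estimate == pytest.approx(b["mbi"].estimate, rel=1e-6)

    def test_score_statistic_equals_logrank(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(5)
        n = 40
        x = np.r_[np.zeros(20), np.ones(20)].astype(int)
        times = rng.exponential(1.0, n)  # null: no group effect
        events = np.ones(n, dtype=bool)

        # score U(0) and information I(0) accumulated over the risk sets of
        # the counting-process expansion
        histories = [
            make_history([1 if xi else 0, 1 if xi else 0], pid=f"S{i}",
                         history=True)
            for i, xi in enumerate(x)
        ]
        rows = []
        for h, t, e, xi in zip(histories, times, events, x):
            status = NPSStatus.NON_MBI_NPS if xi else NPSStatus.NO_NPS
            rows.extend(
                expand_counting_process(
                    h, [status, status], Outcome(bool(e), float(t), "x")
                )
            )
        U = I = 0.0
        xs = {r.participant_id: x[int(r.participant_id[1:])] for r in rows}
        for r in rows:
            if not r.event:
                continue
            at_risk = [q for q in rows if q.start < r.stop <= q.stop]
            xr = np.array([xs[q.participant_id] for q in at_risk], dtype=float)
            U += xs[r.participant_id] - xr.mean()
            I += xr.var()
        lr = logrank_test(times[x == 0], times[x == 1],
                          events[x == 0], events[x == 1])
        assert U**2 / I == pytest.approx(lr.test_statistic, rel=1e-9)

    def test_no_events_rejected(self):
        rows = binary_rows([1.0, 2.0], [False, False], [0, 1])
        with pytest.raises(ValueError, match="no events"):
            fit_cox_td(rows, covariates=())

    def test_separation_flagged(self):
        # every exposed subject fails before any unexposed: monotone likelihood
        times = np.r_[np.linspace(0.1, 1, 10), np.linspace(5, 6, 10)]
        x = np.r_[np.ones(10), np.zeros(10)].astype(int)
        events = np.ones(20, dtype=bool)
        with pytest.raises(ValueError, match="converge|separation"):
            fit_cox_td(binary_rows(times, events, x), covariates=())


class TestPHDiagnostics:
    @staticmethod
    def _simple_fit(seed=7, n=80, beta=0.5, censor_at=3.0):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, n)
        t = rng.exponential(1.0 / (0.5 * np.exp(beta * x)))
        events = t < censor_at
        t = np.minimum(t, censor_at)
        return fit_cox_td(binary_rows(t, events, x), covariates=())

    def test_schoenfeld_residual_matches_hand_computation(self):
        res = self._simple_fit()
        diag = ph_diagnostics(res)
        beta = res["mbi"].estimate
        frame = res.design
        first = frame[frame["event"] == 1].nsmallest(1, "stop").iloc[0]
        t1 = first["stop"]
        risk = frame[(frame["start"] < t1) & (t1 <= frame["stop"])]
        w = np.exp(beta * risk["mbi"])
        expected = first["mbi"] - (w * risk["mbi"]).sum() / w.sum()
        assert diag.schoenfeld.iloc[0]["mbi"] == pytest.approx(expected, abs=1e-12)

    def test_martingale_residuals_sum_to_zero(self):
        diag = ph_diagnostics(self._simple_fit())
        assert diag.martingale.sum() == pytest.approx(0.0, abs=1e-8)
        # censored subjects without events have non-positive residuals >= -cumhaz
        assert diag.martingale.max() <= 1.0

    def test_reversing_effect_detected(self):
        # exposed hazard 3 before t=0.5 then 0.3; unexposed constant 1:
        # the Schoenfeld trend test must reject proportionality
        rng = np.random.default_rng(19)
        n = 1000
        x = np.tile([0, 1], n // 2)
        e_std = rng.exponential(1.0, n)
        t = np.where(
            x == 0,
            e_std,
            np.where(e_std < 1.5, e_std / 3.0, 0.5 + (e_std - 1.5) / 0.3),
        )
        events = t < 4.0
        t = np.minimum(t, 4.0)
        diag = ph_diagnostics(fit_cox_td(binary_rows(t, events, x), covariates=()))
        p = diag.ph_table.set_index("covariate").loc["mbi", "p"]
        assert p < 0.05

    def test_null_rejection_rate_near_nominal(self):
        rejections = 0
        n_rep = 150
        for seed in range(n_rep):
            diag = ph_diagnostics(self._simple_fit(seed=seed, n=60, beta=0.0))
            p = diag.ph_table.set_index("covariate").loc["mbi", "p"]
            rejections += p < 0.05
        rate = rejections / n_rep
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert rate < 0.05 + 3 * se

    def test_too_few_events_undefined(self):
        rows = binary_rows([1.0, 2.0, 3.0], [True, False, False], [0, 1, 0])
        res_ok = fit_cox_td(
            binary_rows([1, 2, 3, 4], [True, True, True, False], [0, 1, 0, 1]),
            covariates=(),
        )
        res_ok.design = res_ok.design[res_ok.design["event"].cumsum() <= 2]
        with pytest.raises(ValueError, match="fewer than 3 events"):
            ph_diagnostics(res_ok)
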