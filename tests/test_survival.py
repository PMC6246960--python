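"""Kaplan-Meier, log-rank, maxstat cut point, and Cox fitting."""

import itertools
import math

import numpy as np
import pytest

from ctdna_concord.ddpcr import CtDNAQuant
from ctdna_concord.errors import FitError, InputError
from ctdna_concord.survival import (
    DEFAULT_CUTPOINT_COPIES_PER_ML,
    HIGH,
    LOW,
    NOT_DETECTED,
    SurvivalRecord,
    _breslow_loglik,
    cox_univariate,
    km_estimate,
    logrank_test,
    maxstat_cutpoint,
    stratify,
    survival_report,
    two_group_logrank_z,
)


def rec(t, e, sid=None, group=None, val=None):
    return SurvivalRecord(
        sample_id=sid or f"s{t}_{e}", time_days=float(t), event=int(e),
        group=group, ctdna_copies_per_ml=val,
    )


class TestKaplanMeier:
    def test_all_censored_flat_curve(self):
        recs = [rec(t, 0, sid=f"c{t}") for t in (5, 10, 15)]
        curve = km_estimate(recs)
        assert len(curve.event_times) == 0
        assert curve.median_survival_days is None

    def test_three_events_product_limit(self):
        recs = [rec(1, 1, "a"), rec(2, 1, "b"), rec(3, 1, "c")]
        curve = km_estimate(recs)
        assert np.allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        assert curve.median_survival_days == 2

    def test_event_then_censor(self):
        recs = [rec(5, 1, "a"), rec(10, 0, "b")]
        curve = km_estimate(recs)
        assert np.allclose(curve.survival, [0.5])
        assert curve.median_survival_days == 5

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.exponential(100, size=80)
        recs = [rec(t, 1, f"s{i}") for i, t in enumerate(times)]
        curve = km_estimate(recs)
        for t, s in zip(curve.event_times, curve.survival):
            assert s == pytest.approx((times > t).mean(), abs=1e-12)

    def test_monotone_and_bounded(self, rng):
        times = rng.exponential(100, size=60)
        events = rng.random(60) < 0.6
        recs = [rec(t, int(e), f"s{i}") for i, (t, e) in enumerate(zip(times, events))]
        curve = km_estimate(recs)
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert np.all((curve.survival >= 0) & (curve.survival <= 1))

    def test_negative_time_rejected(self):
        with pytest.raises(InputError):
            km_estimate([rec(-1, 1)])


def naive_logrank_oracle(groups):
    """Observed-minus-expected log-rank chi-square, computed by direct
    enumeration over pooled event times (independent of the package and
    of lifelines)."""
    data = []
    labels = sorted(groups)
    for gi, g in enumerate(labels):
        for r in groups[g]:
            data.append((r.time_days, r.event, gi))
    k = len(labels)
    event_times = sorted({t for t, e, _ in data if e == 1})
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in event_times:
        at_risk = [(ti, ei, gi) for ti, ei, gi in data if ti >= t]
        n = len(at_risk)
        d = sum(1 for ti, ei, _ in at_risk if ti == t and ei == 1)
        for gi in range(k):
            n_g = sum(1 for *_, g in at_risk if g == gi)
            d_g = sum(1 for ti, ei, g in at_risk if ti == t and ei == 1 and g == gi)
            O[gi] += d_g
            E[gi] += d * n_g / n
        for gi in range(k):
            n_g = sum(1 for *_, g in at_risk if g == gi)
            for gj in range(k):
                n_j = sum(1 for *_, g in at_risk if g == gj)
                delta = 1.0 if gi == gj else 0.0
                if n > 1:
                    V[gi, gj] += d * (n_g / n) * (delta - n_j / n) * (n - d) / (n - 1)
    z = (O - E)[:-1]
    return float(z @ np.linalg.solve(V[:-1, :-1], z))


class TestLogrank:
    def test_identical_groups_give_zero(self):
        recs = [rec(t, 1, f"a{t}") for t in (1, 3, 7, 9)]
        dup = [rec(t, 1, f"b{t}") for t in (1, 3, 7, 9)]
        res = logrank_test({"g1": recs, "g2": dup})
        assert res.chi_square == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hand_computed_small_case(self):
        g1 = [rec(1, 1, "a1"), rec(4, 1, "a2"), rec(6, 0, "a3")]
        g2 = [rec(2, 1, "b1"), rec(5, 0, "b2"), rec(8, 1, "b3")]
        res = logrank_test({"g1": g1, "g2": g2})
        expect = naive_logrank_oracle({"g1": g1, "g2": g2})
        assert res.chi_square == pytest.approx(expect, rel=1e-9)
        assert res.df == 1

    def test_three_group_statistic_matches_oracle(self, rng):
        groups = {}
        for g, lam in (("a", 0.01), ("b", 0.02), ("c", 0.04)):
            groups[g] = [
                rec(t, int(rng.random() < 0.8), f"{g}{i}")
                for i, t in enumerate(rng.exponential(1 / lam, size=15))
            ]
        res = logrank_test(groups)
        assert res.chi_square == pytest.approx(naive_logrank_oracle(groups), rel=1e-6)
        assert res.df == 2

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            logrank_test({"a": [rec(1, 1)], "b": []})

    def test_standardized_z_consistent_with_chi_square(self, rng):
        t = rng.exponential(50, 60)
        e = (rng.random(60) < 0.7).astype(int)
        g = rng.random(60) < 0.5
        recs1 = [rec(ti, ei, f"a{i}") for i, (ti, ei) in enumerate(zip(t[g], e[g]))]
        recs2 = [rec(ti, ei, f"b{i}") for i, (ti, ei) in enumerate(zip(t[~g], e[~g]))]
        z = two_group_logrank_z(t, e, g)
        chi2 = logrank_test({"1": recs1, "2": recs2}).chi_square
        assert z * z == pytest.approx(chi2, rel=1e-9)


def brute_force_maxstat(recs, min_frac):
    """Exhaustive candidate scan with an independent statistic path."""
    vals = np.array([r.ctdna_copies_per_ml for r in recs])
    t = np.array([r.time_days for r in recs])
    e = np.array([r.event for r in recs])
    uniq = np.unique(vals)
    n = len(recs)
    best = (None, -1.0)
    n_cand = 0
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        mid = (lo + hi) / 2
        n_low = (vals <= mid).sum()
        if n_low < min_frac * n or n - n_low < min_frac * n:
            continue
        n_cand += 1
        z = abs(two_group_logrank_z(t, e, vals > mid))
        if z > best[1]:
            best = (mid, z)
    return best[0], best[1], n_cand


class TestMaxstat:
    def _random_records(self, rng, n=40):
        vals = rng.uniform(0, 400, n)
        lam = np.where(vals > 180, 0.01, 0.002)
        t = rng.exponential(1 / lam)
        e = (rng.random(n) < 0.8).astype(int)
        return [rec(ti, ei, f"s{i}", val=v) for i, (ti, ei, v) in enumerate(zip(t, e, vals))]

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(5):
            recs = self._random_records(rng)
            res = maxstat_cutpoint(recs, 0.1)
            cut, stat, n_cand = brute_force_maxstat(recs, 0.1)
            assert res.cutpoint == pytest.approx(cut)
            assert res.max_standardized_statistic == pytest.approx(stat, rel=1e-9)
            assert res.candidates_evaluated == n_cand

    def test_cutpoint_is_midpoint_and_groups_respect_fraction(self, rng):
        recs = self._random_records(rng, n=50)
        res = maxstat_cutpoint(recs, 0.2)
        vals = np.array(sorted({r.ctdna_copies_per_ml for r in recs}))
        mids = (vals[:-1] + vals[1:]) / 2
        assert np.min(np.abs(mids - res.cutpoint)) < 1e-9
        n_low = sum(r.ctdna_copies_per_ml <= res.cutpoint for r in recs)
        assert min(n_low, len(recs) - n_low) >= 0.2 * len(recs)

    def test_rank_invariance_under_monotone_transform(self, rng):
        recs = self._random_records(rng)
        res = maxstat_cutpoint(recs, 0.1)
        transformed = [
            rec(r.time_days, r.event, r.sample_id, val=math.log1p(r.ctdna_copies_per_ml))
            for r in recs
        ]
        res_t = maxstat_cutpoint(transformed, 0.1)
        assert res_t.max_standardized_statistic == pytest.approx(
            res.max_standardized_statistic, rel=1e-9
        )
        # the selected split induces the same partition of samples
        low_a = {r.sample_id for r in recs if r.ctdna_copies_per_ml <= res.cutpoint}
        low_b = {r.sample_id for r in transformed if r.ctdna_copies_per_ml <= res_t.cutpoint}
        assert low_a == low_b

    def test_identical_survival_flags_unreliable(self):
        # every subject fails at the same time: no rank information
        recs = [rec(10, 1, f"s{i}", val=float(i)) for i in range(20)]
        res = maxstat_cutpoint(recs, 0.1)
        assert res.max_standardized_statistic == pytest.approx(0.0, abs=1e-12)
        assert not res.reliable

    def test_identical_values_rejected(self):
        recs = [rec(i + 1, 1, f"s{i}", val=5.0) for i in range(20)]
        with pytest.raises(InputError):
            maxstat_cutpoint(recs)


class TestStratify:
    def _q(self, sid, copies, detected=True):
        return CtDNAQuant(sid, mut_copies_per_ml_plasma=copies, detected=detected, maf_pct=1.0)

    def test_three_way_assignment(self):
        quants = {
            "nd": self._q("nd", 0.0, detected=False),
            "hi": self._q("hi", 6947.82),
            "lo": self._q("lo", 12.0),
        }
        groups = stratify(quants, DEFAULT_CUTPOINT_COPIES_PER_ML)
        assert groups == {"nd": NOT_DETECTED, "hi": HIGH, "lo": LOW}

    def test_boundary_value_is_low(self):
        quants = {"s": self._q("s", DEFAULT_CUTPOINT_COPIES_PER_ML)}
        assert stratify(quants)["s"] == LOW

    def test_bad_cutpoint(self):
        with pytest.raises(InputError):
            stratify({}, 0.0)


def brute_force_breslow_loglik(beta, recs, groups_order):
    """Direct-sum Breslow partial likelihood (independent enumeration)."""
    out = 0.0
    events = [r for r in recs if r.event == 1]
    for r in events:
        xi = np.array([1.0 if r.group == g else 0.0 for g in groups_order])
        risk = [s for s in recs if s.time_days >= r.time_days]
        denom = sum(
            math.exp(
                sum(
                    b
                    for b, g in zip(beta, groups_order)
                    if s.group == g
                )
            )
            for s in risk
        )
        out += float(xi @ beta) - math.log(denom)
    return out


class TestCox:
    def test_identical_groups_hr_one(self):
        base = [(3, 1), (5, 0), (8, 1), (11, 1), (13, 0)]
        recs = [rec(t, e, f"a{i}", group="high") for i, (t, e) in enumerate(base)]
        recs += [rec(t, e, f"b{i}", group="low") for i, (t, e) in enumerate(base)]
        res = cox_univariate(recs, reference="high")
        assert res.hazard_ratios["low"] == pytest.approx(1.0, abs=1e-6)

    def test_partial_likelihood_matches_enumeration_small_n(self, rng):
        recs = []
        for i in range(8):
            recs.append(
                rec(
                    float(rng.exponential(10)),
                    int(rng.random() < 0.8),
                    f"s{i}",
                    group="high" if i % 2 else "low",
                )
            )
        res = cox_univariate(recs, reference="high")
        beta_hat = np.array([math.log(res.hazard_ratios["low"])])
        expect = brute_force_breslow_loglik(beta_hat, recs, ["low"])
        assert res.log_partial_likelihood == pytest.approx(expect, rel=1e-8)
        # the fit maximizes the enumerated likelihood over a grid
        grid = beta_hat[0] + np.linspace(-1, 1, 41)
        lls = [brute_force_breslow_loglik(np.array([b]), recs, ["low"]) for b in grid]
        assert max(lls) <= expect + 1e-7

    def test_matches_lifelines_on_tie_free_data(self, rng):
        # with no ties, Breslow, Efron and the exact likelihood coincide
        import pandas as pd
        from lifelines import CoxPHFitter

        t = rng.exponential(10, 60)
        e = (rng.random(60) < 0.75).astype(int)
        g = rng.random(60) < 0.5
        recs = [
            rec(ti, ei, f"s{i}", group="high" if gi else "low")
            for i, (ti, ei, gi) in enumerate(zip(t, e, g))
        ]
        res = cox_univariate(recs, reference="low")
        df = pd.DataFrame({"T": t, "E": e, "x": g.astype(int)})
        cph = CoxPHFitter().fit(df, "T", "E")
        # agreement to the solvers' convergence tolerances
        assert res.hazard_ratios["high"] == pytest.approx(
            float(np.exp(cph.params_.iloc[0])), rel=1e-3
        )
        lo, hi = res.ci95["high"]
        ci = np.exp(cph.confidence_intervals_.values[0])
        assert lo == pytest.approx(ci[0], rel=1e-3) and hi == pytest.approx(ci[1], rel=1e-3)

    def test_no_events_rejected(self):
        recs = [rec(5, 0, f"s{i}", group="high" if i % 2 else "low") for i in range(6)]
        with pytest.raises(FitError):
            cox_univariate(recs)

    def test_group_without_events_flagged(self):
        recs = [rec(t, 1, f"a{t}", group="high") for t in (2, 4, 6, 8)]
        recs += [rec(t, 0, f"b{t}", group="low") for t in (3, 5, 7, 9)]
        res = cox_univariate(recs, reference="high")
        assert not res.converged and "no events" in res.diagnostics

    def test_log_hr_bias_small_on_proportional_hazards_data(self, rng):
        # parameter recovery: true HR 0.5 at n=1000/group
        n = 1000
        t_high = rng.exponential(1 / 0.01, n)
        t_low = rng.exponential(1 / 0.005, n)
        recs = [rec(t, 1, f"h{i}", group="high") for i, t in enumerate(t_high)]
        recs += [rec(t, 1, f"l{i}", group="low") for i, t in enumerate(t_low)]
        res = cox_univariate(recs, reference="high")
        assert abs(math.log(res.hazard_ratios["low"]) - math.log(0.5)) < 0.15


class TestSurvivalReport:
    def _quants(self):
        return {
            "h1": CtDNAQuant("h1", mut_copies_per_ml_plasma=500, detected=True),
            "h2": CtDNAQuant("h2", mut_copies_per_ml_plasma=900, detected=True),
            "h3": CtDNAQuant("h3", mut_copies_per_ml_plasma=400, detected=True),
            "l1": CtDNAQuant("l1", mut_copies_per_ml_plasma=50, detected=True),
            "l2": CtDNAQuant("l2", mut_copies_per_ml_plasma=20, detected=True),
            "l3": CtDNAQuant("l3", mut_copies_per_ml_plasma=90, detected=True),
            "n1": CtDNAQuant("n1", detected=False),
            "n2": CtDNAQuant("n2", detected=False),
            "n3": CtDNAQuant("n3", detected=False),
        }

    def _records(self):
        # medians: high 120, low 300, not_detected 400 (= 280 over high)
        times = {
            "h1": 100, "h2": 120, "h3": 140,
            "l1": 280, "l2": 300, "l3": 320,
            "n1": 380, "n2": 400, "n3": 420,
        }
        return [rec(t, 1, sid) for sid, t in times.items()]

    def test_median_differences_reported(self):
        report = survival_report(self._records(), self._quants(), cutpoint=210.53)
        assert report.medians[HIGH] == 120
        assert report.median_differences_vs[(NOT_DETECTED, HIGH)] == 280
        assert "280 days" in report.to_text()

    def test_single_group_no_tests(self):
        quants = {k: v for k, v in self._quants().items() if k.startswith("h")}
        records = [r for r in self._records() if r.sample_id.startswith("h")]
        report = survival_report(records, quants, cutpoint=210.53)
        assert report.global_logrank is None and report.pairwise_logrank == {}
        assert report.cox is None

    def test_numeric_content_invariant_to_record_order(self):
        a = survival_report(self._records(), self._quants(), cutpoint=210.53)
        recs = list(reversed(self._records()))
        b = survival_report(recs, self._quants(), cutpoint=210.53)
        assert a.medians == b.medians
        assert a.global_logrank.chi_square == pytest.approx(b.global_logrank.chi_square)
        assert a.cox.hazard_ratios["low"] == pytest.approx(b.cox.hazard_ratios["low"])
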