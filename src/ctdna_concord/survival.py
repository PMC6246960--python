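"""Baseline-ctDNA survival stratification.

Each patient's ctDNA level is summarized by the mutation with the
highest mutant allele frequency. Patients with no detectable tumor
mutation in plasma form the ``not_detected`` group; the detected
patients are split into ``high`` and ``low`` at a cut point on
copies/mL plasma found by maximally selected rank statistics: every
admissible split of the sorted ctDNA values is scored by the
standardized two-group log-rank statistic and the split with the
largest absolute value wins. Group differences are assessed with
Kaplan-Meier curves, log-rank tests, and a univariate Cox proportional
hazards model (Breslow tie handling) with the high-ctDNA group as
reference, so hazard ratios below 1 for the low and not-detected
groups indicate better prognosis.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .ddpcr import CtDNAQuant
from .errors import FitError, InputError

HIGH, LOW, NOT_DETECTED = "high", "low", "not_detected"

#: The operative cut point on copies/mL plasma used by the study design
#: this package emulates; :func:`maxstat_cutpoint` recomputes one for
#: any dataset.
DEFAULT_CUTPOINT_COPIES_PER_ML = 210.53

DAYS_PER_MONTH = 30.44  # calendar-average convention


@dataclass
class SurvivalRecord:
    """Time-to-event follow-up for one patient."""

    sample_id: str
    time_days: float
    event: int  # 1 = death, 0 = censored
    ctdna_copies_per_ml: float | None = None  # None = not detected
    group: str | None = None

    def __post_init__(self) -> None:
        if self.time_days < 0:
            raise InputError(f"{self.sample_id}: negative follow-up time")
        if self.event not in (0, 1):
            raise InputError(f"{self.sample_id}: event must be 0 or 1")


@dataclass
class KMCurve:
    """Product-limit survival estimate."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    median_survival_days: float | None


@dataclass
class LogrankResult:
    chi_square: float
    df: int
    p_value: float


@dataclass
class CutpointResult:
    cutpoint: float
    max_standardized_statistic: float
    candidates_evaluated: int
    min_group_fraction: float
    reliable: bool = True


@dataclass
class CoxResult:
    hazard_ratios: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    log_partial_likelihood: float
    reference: str
    converged: bool = True
    diagnostics: str = ""


def _as_arrays(records: list[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    if not records:
        raise InputError("no survival records")
    t = np.array([r.time_days for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=int)
    if not np.all(np.isfinite(t)):
        raise InputError("non-finite follow-up time")
    return t, e


def km_estimate(records: list[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier product-limit estimate.

    ``S(t) = prod_{t_i <= t} (1 - d_i / n_i)`` over distinct event
    times. The median is the earliest time at which S drops to 0.5 or
    below; ``None`` if S never reaches 0.5.
    """
    t, e = _as_arrays(records)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[ev.index, "KM_estimate"].to_numpy()
    median = kmf.median_survival_time_
    return KMCurve(
        event_times=times,
        survival=surv,
        at_risk=ev["at_risk"].to_numpy(dtype=int),
        n_events=ev["observed"].to_numpy(dtype=int),
        median_survival_days=None if math.isinf(median) else float(median),
    )


def logrank_test(groups: dict[str, list[SurvivalRecord]]) -> LogrankResult:
    """k-group log-rank test over pooled event times."""
    if len(groups) < 2:
        raise InputError("log-rank test needs at least two groups")
    empty = [g for g, recs in groups.items() if not recs]
    if empty:
        raise InputError(f"group(s) with zero subjects: {empty}")
    t, e, g = [], [], []
    for name, recs in groups.items():
        tt, ee = _as_arrays(recs)
        t.append(tt)
        e.append(ee)
        g.extend([name] * len(recs))
    res = multivariate_logrank_test(np.concatenate(t), g, np.concatenate(e))
    return LogrankResult(
        chi_square=float(res.test_statistic),
        df=len(groups) - 1,
        p_value=float(res.p_value),
    )


def two_group_logrank_z(
    time: np.ndarray, event: np.ndarray, in_group1: np.ndarray
) -> float:
    """Standardized (signed) two-group log-rank statistic.

    ``Z = (O1 - E1) / sqrt(V)`` with the usual hypergeometric variance at
    each distinct event time; positive when group 1 experiences more
    events than expected. Returns 0 when the variance is 0 (no
    information to compare).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    g1 = np.asarray(in_group1, dtype=bool)
    order = np.argsort(time, kind="stable")
    time, event, g1 = time[order], event[order], g1[order]
    n = len(time)

    ev = event == 1
    event_times = np.unique(time[ev])
    if len(event_times) == 0:
        return 0.0
    # at-risk counts by binary search on the sorted times
    left = np.searchsorted(time, event_times, side="left")
    cum_g1 = np.concatenate([[0], np.cumsum(g1)])
    n_at = n - left
    n1_at = cum_g1[n] - cum_g1[left]
    # event counts per distinct event time
    idx = np.searchsorted(event_times, time[ev])
    d = np.bincount(idx, minlength=len(event_times))
    d1 = np.bincount(idx, weights=g1[ev].astype(float), minlength=len(event_times))
    p1 = n1_at / n_at
    o_minus_e = float(np.sum(d1 - d * p1))
    with np.errstate(divide="ignore", invalid="ignore"):
        v = d * p1 * (1 - p1) * (n_at - d) / (n_at - 1)
    var = float(np.sum(np.where(n_at > 1, v, 0.0)))
    if var <= 0:
        return 0.0
    return o_minus_e / math.sqrt(var)


def maxstat_cutpoint(
    records: list[SurvivalRecord], min_group_fraction: float = 0.1
) -> CutpointResult:
    """Maximally selected log-rank cut point on ctDNA copies/mL.

    Candidate cut points are midpoints between adjacent sorted unique
    values, restricted so that each side keeps at least
    ``min_group_fraction`` of the subjects. The statistic depends on
    the values only through their ranks, so it is invariant under any
    strictly monotone transformation. No multiple-testing correction is
    applied to the selected maximum: the result is for group selection,
    not inference.
    """
    vals = np.array([r.ctdna_copies_per_ml for r in records], dtype=float)
    if len(records) < 10:
        raise InputError("cut-point search needs at least 10 records with values")
    if np.any(~np.isfinite(vals)):
        raise InputError("all records must carry a ctDNA value")
    uniq = np.unique(vals)
    if len(uniq) < 2:
        raise InputError("all ctDNA values identical: no candidate cut points")
    t, e = _as_arrays(records)

    n = len(vals)
    min_n = min_group_fraction * n
    candidates = []
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        mid = (lo + hi) / 2.0
        n_low = int((vals <= mid).sum())
        if n_low >= min_n and (n - n_low) >= min_n:
            candidates.append(mid)
    if not candidates:
        raise InputError(
            "no candidate split leaves both groups above the minimum fraction"
        )
    best_mid, best_abs = candidates[0], -1.0
    for mid in candidates:
        z = two_group_logrank_z(t, e, vals > mid)
        if abs(z) > best_abs:
            best_abs, best_mid = abs(z), mid
    return CutpointResult(
        cutpoint=float(best_mid),
        max_standardized_statistic=float(best_abs),
        candidates_evaluated=len(candidates),
        min_group_fraction=min_group_fraction,
        reliable=best_abs > 1e-8,
    )


def stratify(
    quants: dict[str, CtDNAQuant],
    cutpoint: float = DEFAULT_CUTPOINT_COPIES_PER_ML,
) -> dict[str, str]:
    """Assign each sample to high / low / not_detected.

    ``not_detected`` when no tumor mutation was detected in plasma;
    otherwise ``high`` when copies/mL exceeds the cut point (strict >)
    and ``low`` at or below it.
    """
    if cutpoint <= 0:
        raise InputError("cutpoint must be positive")
    groups = {}
    for sid, q in quants.items():
        if not q.detected:
            groups[sid] = NOT_DETECTED
        elif q.mut_copies_per_ml_plasma > cutpoint:
            groups[sid] = HIGH
        else:
            groups[sid] = LOW
    return groups


def cox_univariate(
    records: list[SurvivalRecord],
    reference: str = HIGH,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> CoxResult:
    """Univariate Cox proportional-hazards fit on the group factor.

    Maximizes the Breslow partial likelihood by Newton iteration with
    step halving, to gradient norm below ``tol``. Hazard ratios are
    reported against the reference group with Wald 95% confidence
    intervals on the log scale. A group with no events gives a monotone
    partial likelihood; the fit is then flagged as non-converged.
    """
    groups = sorted({r.group for r in records if r.group is not None})
    if any(r.group is None for r in records):
        raise InputError("all records must carry a group label")
    if reference not in groups:
        raise InputError(f"reference group {reference!r} absent from data")
    if len(groups) < 2:
        raise InputError("need at least two groups")
    t, e = _as_arrays(records)
    if e.sum() == 0:
        raise FitError("no events: partial likelihood is flat")

    others = [g for g in groups if g != reference]
    glab = np.array([r.group for r in records])
    X = np.column_stack([(glab == g).astype(float) for g in others])

    diagnostics = ""
    for g in groups:
        if e[glab == g].sum() == 0:
            diagnostics = f"monotone likelihood: group {g!r} has no events"

    beta = np.zeros(len(others))
    loglik, grad, hess = _breslow_loglik(beta, t, e, X)
    converged = False
    for _ in range(max_iter):
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        # Newton ascent with step halving
        new_beta = beta - step
        new = _breslow_loglik(new_beta, t, e, X)
        halvings = 0
        while new[0] < loglik and halvings < 20:
            step /= 2.0
            new_beta = beta - step
            new = _breslow_loglik(new_beta, t, e, X)
            halvings += 1
        beta = new_beta
        loglik, grad, hess = new
    else:
        converged = np.linalg.norm(grad) < tol

    cov = np.linalg.inv(-hess) if np.all(np.isfinite(hess)) else np.full_like(hess, np.nan)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    zcrit = stats.norm.ppf(0.975)
    hrs = {g: float(np.exp(b)) for g, b in zip(others, beta)}
    with np.errstate(over="ignore"):
        cis = {
            g: (float(np.exp(b - zcrit * s)), float(np.exp(b + zcrit * s)))
            for g, b, s in zip(others, beta, se)
        }
    if diagnostics:
        converged = False
    return CoxResult(
        hazard_ratios=hrs,
        ci95=cis,
        log_partial_likelihood=float(loglik),
        reference=reference,
        converged=converged,
        diagnostics=diagnostics,
    )


def _breslow_loglik(
    beta: np.ndarray, t: np.ndarray, e: np.ndarray, X: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Breslow log partial likelihood with gradient and Hessian.

    Ties at an event time share the same risk set; the risk-set term is
    counted once per event (d_i multiplicity).
    """
    order = np.argsort(t, kind="stable")
    t, e, X = t[order], e[order], X[order]
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)

    ev = e == 1
    event_times = np.unique(t[ev])
    left = np.searchsorted(t, event_times, side="left")
    m = len(event_times)

    # suffix sums over the (time-sorted) risk sets
    suf_w = np.concatenate([np.cumsum(w[::-1])[::-1], [0.0]])
    suf_xw = np.zeros((n + 1, p))
    suf_xw[:n] = np.cumsum((X * w[:, None])[::-1], axis=0)[::-1]
    xxw_terms = X[:, :, None] * X[:, None, :] * w[:, None, None]
    suf_xxw = np.zeros((n + 1, p, p))
    suf_xxw[:n] = np.cumsum(xxw_terms[::-1], axis=0)[::-1]

    W = suf_w[left]  # (m,)
    mu = suf_xw[left] / W[:, None]  # (m, p)
    xxw = suf_xxw[left] / W[:, None, None]  # (m, p, p)

    idx = np.searchsorted(event_times, t[ev])
    d = np.bincount(idx, minlength=m).astype(float)
    s = np.zeros((m, p))
    np.add.at(s, idx, X[ev])

    loglik = float(eta[ev].sum() - np.sum(d * np.log(W)))
    grad = s.sum(axis=0) - (d[:, None] * mu).sum(axis=0)
    hess = -np.einsum("i,ijk->jk", d, xxw - mu[:, :, None] * mu[:, None, :])
    return loglik, grad, hess


@dataclass
class SurvivalReport:
    """Three-group survival comparison bundle."""

    groups: dict[str, str]
    curves: dict[str, KMCurve]
    medians: dict[str, float | None]
    global_logrank: LogrankResult | None
    pairwise_logrank: dict[tuple[str, str], float]
    median_differences_vs: dict[tuple[str, str], float | None]
    cox: CoxResult | None
    cutpoint: float

    def to_text(self) -> str:
        lines = [
            "Baseline-ctDNA survival stratification",
            f"  cut point: {self.cutpoint:g} copies/mL plasma (high > cut point >= low)",
            "",
            "  group          n     events  median survival (days)",
        ]
        for g, curve in self.curves.items():
            n = sum(1 for s in self.groups.values() if s == g)
            med = self.medians[g]
            med_s = f"{med:.0f}" if med is not None else "not reached"
            lines.append(f"  {g:<14} {n:<5} {int(curve.n_events.sum()):<7} {med_s}")
        lines.append("")
        for (a, b), diff in self.median_differences_vs.items():
            if diff is not None:
                lines.append(f"  median survival advantage, {a} vs {b}: {diff:.0f} days")
        if self.global_logrank is not None:
            lr = self.global_logrank
            lines.append(
                f"  global log-rank: chi2 = {lr.chi_square:.4g} ({lr.df} df), p = {lr.p_value:.3g}"
            )
        for (a, b), p in self.pairwise_logrank.items():
            lines.append(f"  log-rank {a} vs {b}: p = {p:.3g}")
        if self.cox is not None:
            lines.append(f"  Cox PH (reference = {self.cox.reference}):")
            for g, hr in self.cox.hazard_ratios.items():
                lo, hi = self.cox.ci95[g]
                lines.append(f"    HR[{g}] = {hr:.4f} (95% CI {lo:.4f}-{hi:.4f})")
        return "\n".join(lines)


def survival_report(
    records: list[SurvivalRecord],
    quants: dict[str, CtDNAQuant],
    cutpoint: float = DEFAULT_CUTPOINT_COPIES_PER_ML,
    reference: str = HIGH,
) -> SurvivalReport:
    """Full three-group analysis: KM curves, log-rank tests, Cox HRs."""
    groups = stratify(quants, cutpoint)
    recs = []
    for r in records:
        if r.sample_id in groups:
            r.group = groups[r.sample_id]
            recs.append(r)
    if not recs:
        raise InputError("no survival record matches a quantified sample")

    by_group: dict[str, list[SurvivalRecord]] = {}
    for r in recs:
        by_group.setdefault(r.group, []).append(r)
    order = [g for g in (HIGH, LOW, NOT_DETECTED) if g in by_group]

    curves = {g: km_estimate(by_group[g]) for g in order}
    medians = {g: curves[g].median_survival_days for g in order}
    global_lr = logrank_test(by_group) if len(order) >= 2 else None
    pairwise = {}
    for a, b in itertools.combinations(order, 2):
        pairwise[(a, b)] = logrank_test({a: by_group[a], b: by_group[b]}).p_value

    diffs: dict[tuple[str, str], float | None] = {}
    if reference in medians and medians[reference] is not None:
        for g in order:
            if g == reference:
                continue
            diffs[(g, reference)] = (
                medians[g] - medians[reference] if medians[g] is not None else None
            )

    cox = None
    if len(order) >= 2 and reference in by_group:
        try:
            cox = cox_univariate(recs, reference=reference)
        except FitError as exc:
            warnings.warn(f"Cox fit skipped: {exc}", stacklevel=2)

    return SurvivalReport(
        groups={r.sample_id: r.group for r in recs},
        curves=curves,
        medians=medians,
        global_logrank=global_lr,
        pairwise_logrank=pairwise,
        median_differences_vs=diffs,
        cox=cox,
        cutpoint=cutpoint,
    )
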