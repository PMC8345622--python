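"""Signature survival evaluation.

A Cox proportional-hazards fit on panel-gene expression turns a signature
into a per-sample risk score (the linear predictor); splitting the cohort
at the median risk defines low-/high-risk strata whose Kaplan-Meier curves
are compared with the two-group log-rank test.  This is the standard
procedure for asking whether a response signature also carries prognostic
information in an independent survival cohort.

The Cox partial likelihood is maximised by Newton-Raphson with
step-halving; tied event times use the Breslow approximation by default
(Efron available via ``ties=``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import ExpressionCohort, SurvivalCohort

LOW_RISK = "low_risk"
HIGH_RISK = "high_risk"


@dataclass
class CoxFit:
    coefficients: np.ndarray
    log_likelihood: float
    converged: bool
    risk_scores: np.ndarray
    n_iterations: int = 0
    score_norm: float = float("nan")


@dataclass
class KMCurve:
    """Product-limit survival estimate at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        s = 1.0
        for et, sv in zip(self.event_times, self.survival):
            if et <= t:
                s = sv
            else:
                break
        return s


@dataclass
class LogRankResult:
    chi_sq: float
    df: int
    p_value: float


def _partial_loglik(beta, X, time, event, ties="breslow"):
    """Breslow/Efron partial log-likelihood, score vector and information."""
    eta = X @ beta
    w = np.exp(eta)
    order = np.argsort(-time, kind="mergesort")  # decreasing time
    Xo, to, eo, wo = X[order], time[order], event[order], w[order]
    n, p = X.shape
    # cumulative risk-set sums as time decreases
    cw = np.cumsum(wo)
    cwx = np.cumsum(wo[:, None] * Xo, axis=0)
    cwxx = np.cumsum(wo[:, None, None] * (Xo[:, :, None] * Xo[:, None, :]), axis=0)

    ll, score, info = 0.0, np.zeros(p), np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and to[j] == to[i]:
            j += 1
        idx = np.arange(i, j)
        deaths = idx[eo[idx] == 1]
        d = len(deaths)
        if d > 0:
            S0 = cw[j - 1]
            S1 = cwx[j - 1]
            S2 = cwxx[j - 1]
            xd = Xo[deaths]
            if ties == "breslow" or d == 1:
                ll += float(np.sum(xd @ beta)) - d * np.log(S0)
                xbar = S1 / S0
                score += xd.sum(axis=0) - d * xbar
                info += d * (S2 / S0 - np.outer(xbar, xbar))
            elif ties == "efron":
                wd = wo[deaths]
                s0d = wd.sum()
                s1d = (wd[:, None] * xd).sum(axis=0)
                s2d = (wd[:, None, None] * (xd[:, :, None] * xd[:, None, :])).sum(axis=0)
                ll += float(np.sum(xd @ beta))
                for l in range(d):
                    f = l / d
                    S0l = S0 - f * s0d
                    S1l = S1 - f * s1d
                    S2l = S2 - f * s2d
                    ll -= np.log(S0l)
                    xbar = S1l / S0l
                    score += xd.sum(axis=0) / d - xbar
                    info += S2l / S0l - np.outer(xbar, xbar)
            else:
                raise ValueError(f"unknown tie method {ties!r}")
        i = j
    return ll, score, info


def fit_cox(cohort: SurvivalCohort, ties: str = "breslow", max_iter: int = 50,
            tol: float = 1e-8) -> CoxFit:
    """Newton-Raphson maximisation of the Cox partial likelihood.

    Convergence when the score (gradient) norm drops below `tol`; the
    Newton step is halved until the partial log-likelihood does not
    decrease.  Monotone-likelihood divergence (perfectly separating
    covariates) surfaces as ``converged=False``.
    """
    if cohort.covariates is None:
        raise ValueError("cohort carries no covariates")
    if int(cohort.event.sum()) < 1:
        raise ValueError("need at least one event")
    X = cohort.covariates
    beta = np.zeros(X.shape[1])
    ll, score, info = _partial_loglik(beta, X, cohort.time, cohort.event, ties)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as err:
            raise ValueError("collinear covariates: singular information matrix") from err
        # step-halving keeps the partial log-likelihood non-decreasing
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, score_new, info_new = _partial_loglik(cand, X, cohort.time,
                                                          cohort.event, ties)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta, ll, score, info = cand, ll_new, score_new, info_new
    else:
        it = max_iter
    if np.max(np.abs(score)) < tol:
        converged = True
    return CoxFit(beta, float(ll), converged, X @ beta, it,
                  float(np.max(np.abs(score))))


def median_split(fit: CoxFit) -> np.ndarray:
    """Dichotomise risk scores at the median (ties at the median go low).

    With an even number of unique scores this produces two equal groups;
    an all-identical score vector yields a degenerate all-low split, left
    to the caller to flag.
    """
    scores = np.asarray(fit.risk_scores, dtype=float)
    med = float(np.median(scores))
    return np.where(scores <= med, LOW_RISK, HIGH_RISK)


def km_estimate(times: np.ndarray, events: np.ndarray) -> KMCurve:
    """Product-limit (Kaplan-Meier) estimate of the survival function."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("empty survival data")
    if np.any(times < 0):
        raise ValueError("negative times")
    event_times = np.unique(times[events == 1])
    surv, at_risk = [], []
    s = 1.0
    for t in event_times:
        n_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d / n_risk
        surv.append(s)
        at_risk.append(n_risk)
    return KMCurve(event_times, np.asarray(surv), np.asarray(at_risk, dtype=int))


def logrank_test(group_a: SurvivalCohort, group_b: SurvivalCohort) -> LogRankResult:
    """Two-group log-rank test (hypergeometric variance at each event time)."""
    if group_a.n_samples == 0 or group_b.n_samples == 0:
        raise ValueError("both groups must be non-empty")
    times = np.concatenate([group_a.time, group_b.time])
    events = np.concatenate([group_a.event, group_b.event])
    grp = np.concatenate([np.zeros(group_a.n_samples), np.ones(group_b.n_samples)])
    if int(events.sum()) < 1:
        raise ValueError("no events in either group")
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int(np.sum(at_risk & (grp == 0)))
        died = (times == t) & (events == 1)
        d = int(died.sum())
        d1 = int(np.sum(died & (grp == 0)))
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return LogRankResult(0.0, 1, 1.0)
    chi = o_minus_e ** 2 / var
    return LogRankResult(float(chi), 1, float(stats.chi2.sf(chi, 1)))


@dataclass
class SignatureSurvivalReport:
    fit: CoxFit
    strata: np.ndarray
    km_curves: dict[str, KMCurve]
    logrank: LogRankResult | None
    status: str = "ok"
    degenerate_split: bool = False


def evaluate_signature(expr: ExpressionCohort, surv: SurvivalCohort,
                       genes: list[str], standardize: bool = True,
                       ties: str = "breslow") -> SignatureSurvivalReport:
    """Full signature survival evaluation in one call.

    Fits a Cox model on the panel genes' expression (z-scored per gene by
    default), splits the cohort at the median risk score, estimates a
    Kaplan-Meier curve per stratum and compares the strata with the
    log-rank test.  A degenerate split (all samples on one side, e.g. a
    constant panel) is flagged and the log-rank test is skipped.
    """
    if expr.sample_ids != surv.sample_ids:
        raise ValueError("expression and survival cohorts are not aligned")
    X = expr.features(genes)
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    cov = SurvivalCohort(surv.sample_ids, surv.time, surv.event, X, list(genes))
    fit = fit_cox(cov, ties=ties)
    strata = median_split(fit)
    curves = {}
    for name in (LOW_RISK, HIGH_RISK):
        mask = strata == name
        if np.any(mask):
            curves[name] = km_estimate(surv.time[mask], surv.event[mask])
    if len(curves) < 2:
        return SignatureSurvivalReport(fit, strata, curves, None,
                                       status="degenerate_split",
                                       degenerate_split=True)
    lr = logrank_test(cov.subset(strata == LOW_RISK), cov.subset(strata == HIGH_RISK))
    return SignatureSurvivalReport(fit, strata, curves, lr)
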