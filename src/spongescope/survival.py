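"""Survival-analysis primitives implemented from their defining formulas.

Kaplan-Meier product-limit estimation, the k-group log-rank test, Cox
proportional-hazards fitting by Newton-Raphson on the partial likelihood
(Breslow or Efron handling of tied event times), and median-split group
construction. These are deliberately self-contained: downstream modules
evaluate the partial log-likelihood of *fixed* coefficients on held-out
samples, which off-the-shelf fitters do not expose cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalCohort",
    "KMCurve",
    "CoxFit",
    "LogrankResult",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "cox_partial_loglik",
    "median_split",
    "CoxEngine",
]


@dataclass
class SurvivalCohort:
    """Follow-up data plus an expression matrix (samples x genes)."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    expression: pd.DataFrame

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = len(self.sample_ids)
        if not (len(self.time) == len(self.event) == len(self.expression) == n):
            raise ValueError("inconsistent cohort lengths")
        if n == 0:
            raise ValueError("empty cohort")
        if np.any(~np.isfinite(self.time)) or np.any(self.time <= 0):
            raise ValueError("follow-up times must be finite and positive")
        if not set(np.unique(self.event)) <= {0, 1}:
            raise ValueError("event indicator must be 0 (censored) or 1 (event)")
        if not np.all(np.isfinite(self.expression.to_numpy())):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def genes(self) -> list[str]:
        return list(self.expression.columns)


@dataclass
class KMCurve:
    """Product-limit curve evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): step function, right-continuous, S=1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    @property
    def median(self) -> float | None:
        """Smallest event time with S(t) <= 0.5, or None if never reached."""
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.event_times[below[0]]) if below.size else None


@dataclass
class LogrankResult:
    chi_square: float
    df: int
    p_value: float


@dataclass
class CoxFit:
    coefficients: np.ndarray
    se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    log_partial_likelihood: float
    converged: bool
    n_iter: int

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)


def km_estimate(time: Sequence[float], event: Sequence[int]) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    S(t) = prod over distinct event times t_i <= t of (1 - d_i / n_i), where
    d_i is the number of events at t_i and n_i the number at risk (subjects
    with follow-up >= t_i; subjects censored at t_i remain in that risk set).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("empty cohort")
    event_times = np.unique(time[event == 1])
    surv, at_risk, n_events = [], [], []
    s = 1.0
    for t in event_times:
        n_i = int(np.sum(time >= t))
        d_i = int(np.sum((time == t) & (event == 1)))
        s *= 1.0 - d_i / n_i
        surv.append(s)
        at_risk.append(n_i)
        n_events.append(d_i)
    return KMCurve(
        event_times=event_times,
        survival=np.asarray(surv),
        at_risk=np.asarray(at_risk, dtype=int),
        n_events=np.asarray(n_events, dtype=int),
    )


def logrank_test(
    group_labels: Sequence,
    time: Sequence[float],
    event: Sequence[int],
) -> LogrankResult:
    """k-group log-rank test.

    At each distinct event time, the observed events per group are compared
    with their expectation under the hypergeometric null given the risk sets;
    the summed (O - E) vector over the first k-1 groups is normalised by its
    summed covariance, giving a chi-square statistic with k-1 df.
    """
    labels = np.asarray(group_labels)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.unique(labels)
    k = len(groups)
    if k < 2:
        raise ValueError("log-rank test needs at least two groups")
    for g in groups:
        if np.sum(labels == g) == 0:  # pragma: no cover - unique() precludes this
            raise ValueError(f"group {g!r} is empty")

    o_minus_e = np.zeros(k - 1)
    V = np.zeros((k - 1, k - 1))
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n_j = int(at_risk.sum())
        d_j = int(((time == t) & (event == 1)).sum())
        if n_j == 0:
            continue
        n_ij = np.array([int((at_risk & (labels == g)).sum()) for g in groups], dtype=float)
        d_ij = np.array(
            [int(((time == t) & (event == 1) & (labels == g)).sum()) for g in groups],
            dtype=float,
        )
        e_ij = d_j * n_ij / n_j
        o_minus_e += (d_ij - e_ij)[: k - 1]
        if n_j > 1:
            c = d_j * (n_j - d_j) / (n_j - 1)
            p = n_ij / n_j
            V += c * (np.diag(p[: k - 1]) - np.outer(p[: k - 1], p[: k - 1]))
    if np.allclose(V, 0):
        chi2 = 0.0
    else:
        chi2 = float(o_minus_e @ np.linalg.pinv(V) @ o_minus_e)
        chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, k - 1)) if chi2 > 0 else 1.0
    return LogrankResult(chi_square=chi2, df=k - 1, p_value=p)


class CoxEngine:
    """Pre-sorted Cox partial-likelihood machinery for one (time, event) design.

    Sorting and tie-group bookkeeping are done once so that many fits /
    log-likelihood evaluations with different covariate columns (as in
    repeated-holdout gene selection) reuse them.
    """

    def __init__(self, time: np.ndarray, event: np.ndarray, ties: str = "breslow"):
        if ties not in ("breslow", "efron"):
            raise ValueError("ties must be 'breslow' or 'efron'")
        self.ties = ties
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        self.order = np.argsort(time, kind="mergesort")
        self.time = time[self.order]
        self.event = event[self.order]
        self.n = len(time)
        self.n_events = int(event.sum())
        # indices (into sorted arrays) of events, grouped by tied event time
        ev_idx = np.nonzero(self.event == 1)[0]
        self.groups: list[np.ndarray] = []
        if ev_idx.size:
            ev_times = self.time[ev_idx]
            bounds = np.nonzero(np.diff(ev_times) > 0)[0] + 1
            self.groups = np.split(ev_idx, bounds)
        # first sorted index at risk for each group = index of first subject
        # with time >= group's event time
        self.risk_start = np.array(
            [np.searchsorted(self.time, self.time[g[0]], side="left") for g in self.groups],
            dtype=int,
        )
        self.group_sizes = np.array([len(g) for g in self.groups], dtype=float)
        self.event_rows = np.nonzero(self.event == 1)[0]

    def _suffix_sums(self, w: np.ndarray, X: np.ndarray):
        # reverse cumulative sums so S*(first index i) = sum over time >= t_i
        S0 = np.cumsum(w[::-1])[::-1]
        S1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
        xw = X[:, :, None] * X[:, None, :] * w[:, None, None]
        S2 = np.cumsum(xw[::-1], axis=0)[::-1]
        return S0, S1, S2

    def loglik(self, X: np.ndarray, beta: np.ndarray) -> float:
        """Partial log-likelihood of fixed coefficients (X in original order)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.ndim == 1:
            X = X[:, None]
        Xs = X[self.order]
        return self.loglik_presorted(Xs @ beta)

    def loglik_presorted(self, eta: np.ndarray) -> float:
        """Partial log-likelihood of a linear predictor already in sorted order."""
        eta = eta - eta.max()  # stabilise; partial lik is shift-invariant
        w = np.exp(eta)
        S0 = np.cumsum(w[::-1])[::-1]
        if self.ties == "breslow":
            return float(
                eta[self.event_rows].sum()
                - (self.group_sizes * np.log(S0[self.risk_start])).sum()
            )
        ll = float(eta[self.event_rows].sum())
        for g, r in zip(self.groups, self.risk_start):
            d = len(g)
            s0_tied = float(w[g].sum())
            for l in range(d):
                ll -= np.log(S0[r] - (l / d) * s0_tied)
        return float(ll)

    def loglik_grad_info(self, Xs: np.ndarray, beta: np.ndarray):
        """(loglik, gradient, information) for sorted covariates ``Xs``."""
        p = Xs.shape[1]
        eta = Xs @ beta
        shift = eta.max()
        w = np.exp(eta - shift)
        S0, S1, S2 = self._suffix_sums(w, Xs)
        if self.ties == "breslow":
            d = self.group_sizes
            r = self.risk_start
            s0 = S0[r]
            mu = S1[r] / s0[:, None]                      # (G, p)
            ll = float(eta[self.event_rows].sum() - (d * (np.log(s0) + shift)).sum())
            grad = Xs[self.event_rows].sum(axis=0) - (d[:, None] * mu).sum(axis=0)
            info = (
                d[:, None, None] * (S2[r] / s0[:, None, None] - mu[:, :, None] * mu[:, None, :])
            ).sum(axis=0)
            return ll, grad, info
        # efron
        ll = float(eta[self.event_rows].sum())
        grad = Xs[self.event_rows].sum(axis=0).astype(float)
        info = np.zeros((p, p))
        for g, r in zip(self.groups, self.risk_start):
            d = len(g)
            wg = w[g]
            s0t = float(wg.sum())
            s1t = (wg[:, None] * Xs[g]).sum(axis=0)
            s2t = (wg[:, None, None] * (Xs[g][:, :, None] * Xs[g][:, None, :])).sum(axis=0)
            for l in range(d):
                f = l / d
                s0 = S0[r] - f * s0t
                s1 = S1[r] - f * s1t
                s2 = S2[r] - f * s2t
                ll -= np.log(s0) + shift
                mu = s1 / s0
                grad -= mu
                info += s2 / s0 - np.outer(mu, mu)
        return float(ll), grad, info

    def fit(
        self,
        X: np.ndarray,
        max_iter: int = 50,
        tol: float = 1e-8,
        presorted: bool = False,
    ) -> CoxFit:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        Xs = X if presorted else X[self.order]
        p = Xs.shape[1]
        if self.n_events < 1:
            raise ValueError("no events in the data; Cox model undefined")
        beta = np.zeros(p)
        ll, grad, info = self.loglik_grad_info(Xs, beta)
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            if np.max(np.abs(grad)) < tol:
                converged = True
                break
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(info, grad, rcond=None)[0]
            # step halving if the likelihood does not improve
            factor = 1.0
            for _ in range(20):
                cand = beta + factor * step
                ll_new, grad_new, info_new = self.loglik_grad_info(Xs, cand)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                    break
                factor /= 2.0
            beta, ll, grad, info = cand, ll_new, grad_new, info_new
            if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 50:
                converged = False
                break
        else:
            n_iter = max_iter
        if np.max(np.abs(grad)) < tol and np.all(np.isfinite(beta)):
            converged = True
        with np.errstate(invalid="ignore"):
            try:
                cov = np.linalg.inv(info)
                se = np.sqrt(np.clip(np.diag(cov), 0, None))
            except np.linalg.LinAlgError:
                se = np.full(p, np.nan)
        z = stats.norm.ppf(0.975)
        return CoxFit(
            coefficients=beta,
            se=se,
            ci_lower=beta - z * se,
            ci_upper=beta + z * se,
            log_partial_likelihood=float(ll),
            converged=bool(converged),
            n_iter=n_iter,
        )


def cox_fit(
    covariates: np.ndarray,
    time: Sequence[float],
    event: Sequence[int],
    ties: str = "breslow",
    max_iter: int = 50,
    tol: float = 1e-8,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Maximises the partial likelihood (Breslow tie handling by default, Efron
    optional); returns coefficients, standard errors from the inverse observed
    information, Wald 95% CIs, and the maximised log partial likelihood.
    Constant covariate columns are rejected; non-convergence (including
    monotone likelihood / perfect separation) is flagged via ``converged``.
    """
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("constant covariate column")
    event = np.asarray(event, dtype=int)
    if int(event.sum()) < X.shape[1]:
        raise ValueError(
            f"{int(event.sum())} events for {X.shape[1]} covariates; model underdetermined"
        )
    return CoxEngine(np.asarray(time, dtype=float), event, ties).fit(
        X, max_iter=max_iter, tol=tol
    )


def cox_partial_loglik(
    covariates: np.ndarray,
    time: Sequence[float],
    event: Sequence[int],
    beta: np.ndarray,
    ties: str = "breslow",
) -> float:
    """Partial log-likelihood of fixed coefficients on the given data."""
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    eng = CoxEngine(np.asarray(time, dtype=float), np.asarray(event, dtype=int), ties)
    return eng.loglik(X, np.asarray(beta, dtype=float))


def median_split(values: Sequence[float], at_median: str = "low") -> tuple[np.ndarray, bool]:
    """Split samples at the median of ``values`` into 'low' / 'high' labels.

    Values strictly below the median are 'low', strictly above are 'high';
    values exactly at the median go to ``at_median`` ('low' by default).
    Returns ``(labels, degenerate)`` where ``degenerate`` is True when one
    group ends up empty (e.g. all values identical) — no test should be run
    on a degenerate split.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("median split needs at least two samples")
    if at_median not in ("low", "high"):
        raise ValueError("at_median must be 'low' or 'high'")
    med = float(np.median(v))
    labels = np.where(v < med, "low", np.where(v > med, "high", at_median))
    degenerate = (labels == "low").all() or (labels == "high").all()
    return labels, bool(degenerate)
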