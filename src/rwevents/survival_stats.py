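"""First-principles survival statistics.

Implements the product-limit (Kaplan-Meier) estimator, the K-group log-rank
test, Cox proportional-hazards regression by damped Newton maximization of
the partial likelihood (Breslow or Efron tie handling), and Fisher's exact
test via exact integer hypergeometric weights.

Conventions
-----------
* Censored observations tied with an event time count as at risk for that
  event time and are removed afterwards (censoring-after-events).
* The KM median is the smallest listed event time with survival <= 0.5 — the
  crossing convention, no interpolation.
* Cox ties default to Breslow; Efron is available because day-granularity
  real-world data produce ties.
* p-values are reported at full float precision; rounding is a presentation
  concern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .endpoints import SurvivalRecord


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival estimate over the distinct event times.

    ``survival[i] = prod_{j<=i} (1 - d_j / n_j)`` with ``d_j`` events among
    ``n_j`` at risk; ``greenwood_se`` is the Greenwood standard error.
    ``n_censored[i]`` counts censorings in ``[t_i, t_{i+1})`` (last interval
    open-ended); censorings before the first event time are in
    ``n_censored_before_first``.
    """

    event_times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    n_censored: np.ndarray
    survival: np.ndarray
    greenwood_se: np.ndarray
    median: Optional[float]
    censor_times: np.ndarray = field(default_factory=lambda: np.array([]))
    n_censored_before_first: int = 0
    label: str = ""

    def survival_at(self, t: float) -> float:
        """Right-continuous step-function value at time ``t``."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(records: Sequence[SurvivalRecord], label: str = "") -> KMCurve:
    """Kaplan-Meier product-limit estimate from survival records."""
    if not records:
        raise ValueError("km_estimate requires at least one record")
    times = np.asarray([r.time for r in records], dtype=float)
    events = np.asarray([r.event for r in records], dtype=int)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    n = len(times)

    ev_times = np.unique(times[events == 1])
    n_at_risk = np.empty(len(ev_times), dtype=int)
    n_events = np.empty(len(ev_times), dtype=int)
    for i, t in enumerate(ev_times):
        n_at_risk[i] = int(np.sum(times >= t))
        n_events[i] = int(np.sum((times == t) & (events == 1)))

    with np.errstate(divide="ignore", invalid="ignore"):
        frac = n_events / n_at_risk
        survival = np.cumprod(1.0 - frac)
        gw_terms = np.where(
            n_at_risk > n_events,
            n_events / (n_at_risk * (n_at_risk - n_events).astype(float)),
            np.nan,
        )
        greenwood_se = survival * np.sqrt(np.cumsum(gw_terms))

    cens_times = times[events == 0]
    edges = np.concatenate([ev_times, [np.inf]])
    n_censored = np.array(
        [
            int(np.sum((cens_times >= edges[i]) & (cens_times < edges[i + 1])))
            for i in range(len(ev_times))
        ],
        dtype=int,
    )
    before_first = int(np.sum(cens_times < ev_times[0])) if len(ev_times) else len(cens_times)

    median = None
    crossing = np.nonzero(survival <= 0.5)[0]
    if len(crossing):
        median = float(ev_times[crossing[0]])

    return KMCurve(
        event_times=ev_times,
        n_at_risk=n_at_risk,
        n_events=n_events,
        n_censored=n_censored,
        survival=survival,
        greenwood_se=greenwood_se,
        median=median,
        censor_times=np.sort(cens_times),
        n_censored_before_first=before_first,
        label=label,
    )


def km_by_group(records: Sequence[SurvivalRecord]) -> dict[str, KMCurve]:
    """One KM curve per group label."""
    groups: dict[str, list[SurvivalRecord]] = {}
    for r in records:
        groups.setdefault(r.group, []).append(r)
    return {g: km_estimate(rs, label=g) for g, rs in sorted(groups.items())}


def km_plot_data(curves: Sequence[KMCurve]) -> pd.DataFrame:
    """Plot-ready step-function table.

    Rows of kind ``step`` trace the right-continuous survival step function
    (starting at (0, 1)); rows of kind ``censor`` mark censoring ticks at the
    current survival level.  The step rows reconstruct every curve value
    exactly.
    """
    rows = []
    for curve in curves:
        lab = curve.label
        rows.append({"group": lab, "kind": "step", "time": 0.0, "survival": 1.0})
        prev = 1.0
        for t, s in zip(curve.event_times, curve.survival):
            rows.append({"group": lab, "kind": "step", "time": float(t), "survival": prev})
            rows.append({"group": lab, "kind": "step", "time": float(t), "survival": float(s)})
            prev = float(s)
        for t in curve.censor_times:
            rows.append({
                "group": lab, "kind": "censor", "time": float(t),
                "survival": curve.survival_at(float(t)),
            })
    return pd.DataFrame(rows, columns=["group", "kind", "time", "survival"])


def km_table(curves: Sequence[KMCurve]) -> pd.DataFrame:
    """Per-event-time KM table (time, n_risk, n_event, n_censor, survival,
    se, group) across curves."""
    rows = []
    for c in curves:
        for i, t in enumerate(c.event_times):
            rows.append({
                "time": float(t),
                "n_risk": int(c.n_at_risk[i]),
                "n_event": int(c.n_events[i]),
                "n_censor": int(c.n_censored[i]),
                "survival": float(c.survival[i]),
                "se": float(c.greenwood_se[i]),
                "group": c.label,
            })
    return pd.DataFrame(
        rows, columns=["time", "n_risk", "n_event", "n_censor", "survival", "se", "group"]
    )


# ---------------------------------------------------------------------------
# log-rank test
# ---------------------------------------------------------------------------

@dataclass
class LogRankResult:
    statistic: float
    df: int
    p_value: float
    observed: dict[str, float]
    expected: dict[str, float]


def logrank_test(
    records: Sequence[SurvivalRecord],
    by_group: Optional[Mapping[str, str]] = None,
) -> LogRankResult:
    """K-group log-rank test.

    Groups come from each record's ``group`` field unless *by_group* maps
    patient ids to labels.  The statistic is the standard quadratic form
    (O-E)' V^{-1} (O-E) over pooled event times, with the hypergeometric
    variance, referred to chi-square with ``groups - 1`` degrees of freedom.
    """
    labels = []
    for r in records:
        g = by_group.get(r.patient_id) if by_group is not None else r.group
        if g is None:
            raise ValueError(f"no group for patient {r.patient_id}")
        labels.append(g)
    group_names = sorted(set(labels))
    k = len(group_names)
    if k < 2:
        raise ValueError("logrank_test requires at least two groups")
    g_index = {g: i for i, g in enumerate(group_names)}

    times = np.asarray([r.time for r in records], dtype=float)
    events = np.asarray([r.event for r in records], dtype=int)
    gidx = np.asarray([g_index[g] for g in labels], dtype=int)
    for g in range(k):
        if not np.any(gidx == g):
            raise ValueError(f"group {group_names[g]!r} has no records")
    if events.sum() == 0:
        raise ValueError("logrank_test requires at least one event")

    observed = np.zeros(k)
    expected = np.zeros(k)
    V = np.zeros((k, k))
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n_t = int(at_risk.sum())
        d_t = int(((times == t) & (events == 1)).sum())
        n_g = np.array([int((at_risk & (gidx == g)).sum()) for g in range(k)], dtype=float)
        d_g = np.array(
            [int(((times == t) & (events == 1) & (gidx == g)).sum()) for g in range(k)],
            dtype=float,
        )
        observed += d_g
        expected += d_t * n_g / n_t
        if n_t > 1:
            c = d_t * (n_t - d_t) / (n_t - 1.0)
            p = n_g / n_t
            V += c * (np.diag(p) - np.outer(p, p))

    diff = (observed - expected)[: k - 1]
    Vsub = V[: k - 1, : k - 1]
    stat = float(diff @ np.linalg.pinv(Vsub) @ diff)
    df = k - 1
    return LogRankResult(
        statistic=stat,
        df=df,
        p_value=float(stats.chi2.sf(stat, df)),
        observed=dict(zip(group_names, observed)),
        expected=dict(zip(group_names, expected)),
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    hazard_ratios: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    log_partial_likelihood: float
    ties_method: str
    converged: bool
    n_iterations: int
    n: int
    n_events: int


class DegenerateInformationError(ValueError):
    """A covariate is constant over the subjects: no information to fit."""


def _cox_loglik_grad_hess(
    beta: np.ndarray,
    t: np.ndarray,
    d: np.ndarray,
    X: np.ndarray,
    ties_method: str,
):
    """Partial log-likelihood, gradient and (negative Hessian =) information
    at ``beta``.  Arrays must be sorted ascending by time."""
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    # reverse cumulative sums over the ascending order give risk-set sums
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
    wxx = w[:, None, None] * (X[:, :, None] * X[:, None, :])
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        tied = np.arange(i, j)[d[i:j] == 1]
        dt = len(tied)
        if dt > 0:
            s0, s1, s2 = S0[i], S1[i], S2[i]
            ll += float(eta[tied].sum())
            grad += X[tied].sum(axis=0)
            if ties_method == "breslow":
                ll -= dt * math.log(s0)
                mu = s1 / s0
                grad -= dt * mu
                info += dt * (s2 / s0 - np.outer(mu, mu))
            else:  # efron
                wD = w[tied]
                s0D = float(wD.sum())
                s1D = (wD[:, None] * X[tied]).sum(axis=0)
                s2D = (wD[:, None, None] * (X[tied][:, :, None] * X[tied][:, None, :])).sum(axis=0)
                for ell in range(dt):
                    c = ell / dt
                    s0l = s0 - c * s0D
                    s1l = s1 - c * s1D
                    s2l = s2 - c * s2D
                    ll -= math.log(s0l)
                    mu = s1l / s0l
                    grad -= mu
                    info += s2l / s0l - np.outer(mu, mu)
        i = j
    return ll, grad, info


def cox_partial_loglik(
    beta: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    X: np.ndarray,
    ties_method: str = "breslow",
) -> float:
    """Partial log-likelihood at ``beta`` (exposed for oracles and profiling)."""
    order = np.argsort(times, kind="stable")
    ll, _, _ = _cox_loglik_grad_hess(
        np.atleast_1d(np.asarray(beta, dtype=float)),
        times[order], events[order], np.atleast_2d(X)[order], ties_method,
    )
    return ll


def cox_ph(
    records: Sequence[SurvivalRecord],
    covariate_names: Sequence[str],
    ties_method: str = "breslow",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by damped Newton iteration.

    Covariates are read from each record's ``covariates`` mapping.  Starting
    from beta = 0, a Newton step is halved until the partial likelihood does
    not decrease; convergence when the max absolute gradient component drops
    below ``tol``.  Diverging estimates (|beta| > 50, e.g. complete
    separation) are flagged as non-converged rather than raised.
    """
    if ties_method not in ("breslow", "efron"):
        raise ValueError(f"unknown ties_method {ties_method!r}")
    names = list(covariate_names)
    times = np.asarray([r.time for r in records], dtype=float)
    events = np.asarray([r.event for r in records], dtype=int)
    X = np.asarray([[r.covariates[c] for c in names] for r in records], dtype=float)
    if events.sum() == 0:
        raise ValueError("cox_ph requires at least one event")
    for j, c in enumerate(names):
        if np.ptp(X[:, j]) == 0:
            raise DegenerateInformationError(f"covariate {c!r} is constant")

    order = np.argsort(times, kind="stable")
    t, d, Xs = times[order], events[order], X[order]
    p = len(names)
    beta = np.zeros(p)
    ll, grad, info = _cox_loglik_grad_hess(beta, t, d, Xs, ties_method)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            if it == 1:
                raise DegenerateInformationError(
                    "singular information matrix (collinear covariates?)"
                )
            converged = False  # information vanished along the way: divergence
            break
        # a flat (monotone) likelihood has a tiny gradient but a large Newton
        # step; require both small, so separation keeps diverging until the
        # |beta| bound flags it
        if np.max(np.abs(grad)) < tol and np.max(np.abs(step)) < 1e-6:
            converged = True
            break
        # damped Newton: halve the step until the likelihood does not drop
        # (margin relative to |ll| so float noise near the optimum does not
        # reject the full step)
        margin = 1e-9 * (abs(ll) + 1.0)
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, grad_new, info_new = _cox_loglik_grad_hess(cand, t, d, Xs, ties_method)
            if ll_new >= ll - margin:
                break
            scale /= 2.0
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        if np.max(np.abs(beta)) > 50:
            converged = False
            break

    cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    coefs = dict(zip(names, beta))
    ses = dict(zip(names, se))
    return CoxFit(
        coefficients=coefs,
        standard_errors=ses,
        hazard_ratios={c: math.exp(b) for c, b in coefs.items()},
        ci95={
            c: (coefs[c] - 1.96 * ses[c], coefs[c] + 1.96 * ses[c]) for c in names
        },
        log_partial_likelihood=ll,
        ties_method=ties_method,
        converged=converged,
        n_iterations=it,
        n=len(records),
        n_events=int(events.sum()),
    )


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

@dataclass
class FisherResult:
    odds_ratio: float
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]


def fisher_exact(table: Sequence[Sequence[int]]) -> FisherResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    With margins fixed, the two-sided p-value sums the hypergeometric
    probabilities of all tables no more probable than the observed one.  The
    comparison uses exact integer weights C(r1, x) * C(r2, c1 - x), so the
    result is exact rational arithmetic converted to float at the end.
    """
    (a, b), (c, d) = table
    cells = [a, b, c, d]
    if any(int(v) != v or v < 0 for v in cells):
        raise ValueError("table cells must be non-negative integers")
    a, b, c, d = (int(v) for v in cells)
    n = a + b + c + d
    if n == 0:
        raise ValueError("table grand total must be positive")
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    w_obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    num = 0
    den = 0
    for x in range(lo, hi + 1):
        w = math.comb(r1, x) * math.comb(r2, c1 - x)
        den += w
        if w <= w_obs:
            num += w
    p = float(Fraction(num, den))

    if b * c == 0:
        oddsr = math.inf if a * d > 0 else math.nan
    else:
        oddsr = (a * d) / (b * c)
    return FisherResult(odds_ratio=oddsr, p_value=p, table=((a, b), (c, d)))
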