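"""Survival-analysis core: Kaplan–Meier estimation, log-rank and trend tests,
stratified Cox proportional-hazards fitting, Harrell's concordance, restricted
mean survival time, and likelihood-based model comparison.

All estimators are written against plain numpy arrays so the layer stays pure:
it consumes in-memory vectors and emits small result objects that serialize to
JSON. Times are in months throughout; events are boolean indicators (True =
the event was observed, False = right-censored).

The Cox fitter maximises the stratified partial likelihood by Newton's method
with step-halving. Ties are handled by the Efron approximation by default
(Breslow selectable); both reduce to the exact partial likelihood on tie-free
data. Monotone partial likelihoods (e.g. a covariate level with zero events)
are detected by coefficient divergence and reported as an infinite hazard
ratio with an undefined p-value instead of raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "KMCurve",
    "TestResult",
    "CoxFit",
    "RMSTResult",
    "ConcordanceResult",
    "ImportanceResult",
    "km_estimate",
    "rate_at",
    "km_median",
    "logrank_test",
    "logrank_trend_test",
    "cox_fit",
    "wald_summary",
    "likelihood_ratio_test",
    "harrell_c",
    "rmst_compare",
    "chi2_importance",
]

Z95 = stats.norm.ppf(0.975)

# Newton solver controls for the partial-likelihood maximisation.
COX_GRADIENT_TOL = 1e-9
COX_MAX_ITER = 50
COX_DIVERGENCE_BOUND = 15.0  # |coef| beyond this flags a monotone likelihood


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass
class KMCurve:
    """Product-limit estimate of a survival function.

    ``event_times`` holds the distinct times at which at least one event
    occurred; the curve steps only there.  ``greenwood_cum`` is the running
    Greenwood sum ``sum d/(n(n-d))`` used for variances and log(-log)
    confidence bands.  ``max_observed`` is the largest observed time (event
    or censored), beyond which any evaluation is an extrapolation.
    """

    event_times: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray
    greenwood_cum: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    n_total: int
    max_observed: float

    def survival_at(self, t: float) -> float:
        """S(t); left step value between steps, 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class TestResult:
    statistic: float
    df: int
    p_value: float
    kind: str


@dataclass
class CoxFit:
    """A fitted (possibly stratified) proportional-hazards model."""

    coefficients: dict[str, float]
    covariance: np.ndarray
    loglik_null: float
    loglik_fitted: float
    strata_labels: list
    ties_method: str
    converged: bool
    n: int
    n_events: int
    infinite_terms: frozenset = field(default_factory=frozenset)
    n_iter: int = 0

    @property
    def term_names(self) -> list[str]:
        return list(self.coefficients)

    def coef_vector(self) -> np.ndarray:
        return np.array(list(self.coefficients.values()))


@dataclass
class RMSTResult:
    tau: float
    rmst_per_group: tuple[float, float]
    difference: float
    ci_95: tuple[float, float]
    p_value: float


@dataclass
class ConcordanceResult:
    c_index: float
    ci_95: tuple[float, float]
    n_comparable_pairs: int


@dataclass
class ImportanceResult:
    chi2: dict[str, float]
    proportion: dict[str, float]


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


def _as_surv_arrays(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValueError("times and events must be 1-d arrays of equal length")
    if t.size == 0:
        raise ValueError("empty input: at least one observation is required")
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise ValueError("times must be finite and > 0")
    return t, e


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier product-limit estimator with Greenwood variances."""
    t, e = _as_surv_arrays(times, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    n = t.size

    uniq, start = np.unique(t, return_index=True)
    # subjects at risk just before each unique time
    at_risk = n - start
    d = np.add.reduceat(e.astype(int), start)

    keep = d > 0
    ut, nr, de = uniq[keep], at_risk[keep], d[keep]
    with np.errstate(divide="ignore", invalid="ignore"):
        surv = np.cumprod(1.0 - de / nr)
        gw_terms = np.where(nr > de, de / (nr * (nr - de.astype(float))), np.inf)
    gw_cum = np.cumsum(gw_terms)
    finite = np.isfinite(gw_cum)
    gw_var = np.zeros_like(surv)
    gw_var[finite] = surv[finite] ** 2 * gw_cum[finite]
    return KMCurve(
        event_times=ut,
        survival=surv,
        greenwood_var=gw_var,
        greenwood_cum=gw_cum,
        n_at_risk=nr,
        n_events=de,
        n_total=n,
        max_observed=float(t.max()),
    )


def _loglog_ci(s: float, gw_cum: float) -> tuple[float, float]:
    """95% CI for S using the log(-log S) transform; bounded in [0, 1]."""
    if s >= 1.0:
        return (1.0, 1.0)
    if s <= 0.0 or not np.isfinite(gw_cum):
        return (0.0, 0.0) if s <= 0.0 else (0.0, 1.0)
    se = np.sqrt(gw_cum) / abs(np.log(s))
    lo = s ** np.exp(Z95 * se)
    hi = s ** np.exp(-Z95 * se)
    return (float(lo), float(hi))


def rate_at(curve: KMCurve, t: float) -> dict:
    """Survival rate at time ``t`` as a percent with log-log 95% CI.

    Between steps the left step value applies; querying beyond the last
    observed time returns the final value flagged ``extrapolated``.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    idx = np.searchsorted(curve.event_times, t, side="right") - 1
    if idx < 0:
        s, gw = 1.0, 0.0
    else:
        s, gw = float(curve.survival[idx]), float(curve.greenwood_cum[idx])
    lo, hi = _loglog_ci(s, gw)
    return {
        "rate": 100.0 * s,
        "ci_95": (100.0 * lo, 100.0 * hi),
        "extrapolated": bool(t > curve.max_observed),
    }


def km_median(curve: KMCurve) -> dict:
    """Median survival time with a Brookmeyer–Crowley-style log-log CI.

    The median is the first event time at which S drops to 0.5 or below;
    the CI endpoints are the first crossing times of the pointwise CI
    curves.  A bound is NaN when the corresponding curve never reaches 0.5.
    """

    def first_crossing(values: np.ndarray) -> float:
        below = np.nonzero(values <= 0.5)[0]
        return float(curve.event_times[below[0]]) if below.size else float("nan")

    ci = np.array([_loglog_ci(s, g) for s, g in zip(curve.survival, curve.greenwood_cum)])
    if ci.size == 0:
        return {"median": float("nan"), "ci_95": (float("nan"), float("nan"))}
    return {
        "median": first_crossing(curve.survival),
        "ci_95": (first_crossing(ci[:, 0]), first_crossing(ci[:, 1])),
    }


# ---------------------------------------------------------------------------
# log-rank family
# ---------------------------------------------------------------------------


def _logrank_moments(groups: Sequence[tuple]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observed, expected and covariance of per-group event counts."""
    k = len(groups)
    if k < 2:
        raise ValueError("at least two groups are required")
    parts = []
    for g, (t, e) in enumerate(groups):
        t, e = _as_surv_arrays(t, e)
        parts.append((t, e, np.full(t.size, g)))
    t = np.concatenate([p[0] for p in parts])
    e = np.concatenate([p[1] for p in parts])
    g = np.concatenate([p[2] for p in parts])

    obs = np.zeros(k)
    exp_ = np.zeros(k)
    cov = np.zeros((k, k))
    for tt in np.unique(t[e]):
        at_risk = t >= tt
        n_t = at_risk.sum()
        d_t = (e & (t == tt)).sum()
        n_g = np.bincount(g[at_risk], minlength=k).astype(float)
        d_g = np.bincount(g[e & (t == tt)], minlength=k).astype(float)
        obs += d_g
        exp_ += d_t * n_g / n_t
        if n_t > 1:
            f = d_t * (n_t - d_t) / (n_t - 1)
            cov += f * (np.diag(n_g) * n_t - np.outer(n_g, n_g)) / n_t**2
    return obs, exp_, cov


def logrank_test(groups: Sequence[tuple]) -> TestResult:
    """k-sample log-rank test; ``groups`` is a list of (times, events)."""
    obs, exp_, cov = _logrank_moments(groups)
    k = len(groups)
    u = (obs - exp_)[: k - 1]
    v = cov[: k - 1, : k - 1]
    stat = float(u @ np.linalg.pinv(v) @ u) if u.size else 0.0
    stat = max(stat, 0.0)
    df = k - 1
    return TestResult(stat, df, float(stats.chi2.sf(stat, df)), "logrank")


def logrank_trend_test(ordered_groups: Sequence[tuple]) -> TestResult:
    """Log-rank test for trend over ordered groups.

    Uses equally spaced integer scores 0, 1, 2, ... over the supplied group
    order; one degree of freedom.
    """
    if len(ordered_groups) < 3:
        raise ValueError("trend test requires >= 3 ordered groups; use logrank_test")
    obs, exp_, cov = _logrank_moments(ordered_groups)
    c = np.arange(len(ordered_groups), dtype=float)
    u = float(c @ (obs - exp_))
    v = float(c @ cov @ c)
    stat = u * u / v if v > 0 else 0.0
    return TestResult(stat, 1, float(stats.chi2.sf(stat, 1)), "trend")


# ---------------------------------------------------------------------------
# stratified Cox proportional hazards
# ---------------------------------------------------------------------------


def _cox_quantities(beta, X, times, events, strata, ties_method, loglik_only=False):
    """Stratified partial log-likelihood with gradient and information.

    Returns (loglik, gradient, information); the derivative slots are None
    when ``loglik_only`` is requested (used by step-halving).  The sums run
    over strata, each contributing its own risk sets; risk-set sums are
    reverse cumulative sums over time-sorted subjects.  Efron's correction
    downweights the tied death set within each tied event time; Breslow
    leaves the denominator whole.
    """
    p = X.shape[1]
    ll = 0.0
    grad = None if loglik_only else np.zeros(p)
    info = None if loglik_only else np.zeros((p, p))
    eta = X @ beta
    # guard against overflow during divergence; relative risks only matter
    eta = eta - eta.max() if eta.size else eta
    w = np.exp(eta)

    for s in np.unique(strata):
        m = strata == s
        order = np.argsort(times[m], kind="stable")
        ts = times[m][order]
        es = events[m][order]
        Xs = X[m][order]
        ws = w[m][order]
        etas = eta[m][order]

        # risk-set sums at each position: reverse cumulative sums
        rc0 = np.cumsum(ws[::-1])[::-1]
        if not loglik_only:
            rc1 = np.cumsum((ws[:, None] * Xs)[::-1], axis=0)[::-1]
            rc2 = np.cumsum(np.einsum("i,ij,ik->ijk", ws, Xs, Xs)[::-1],
                            axis=0)[::-1]

        uniq, start = np.unique(ts, return_index=True)
        bounds = np.append(start, ts.size)
        d_cnt = np.add.reduceat(es.astype(int), start)
        has_event = d_cnt > 0
        ll += float(etas[es].sum())
        if not loglik_only:
            grad += Xs[es].sum(axis=0)
        for k in np.nonzero(has_event)[0]:
            i0, i1 = bounds[k], bounds[k + 1]
            d = int(d_cnt[k])
            s0 = rc0[i0]
            if not loglik_only:
                s1, s2 = rc1[i0], rc2[i0]
            if ties_method == "efron" and d > 1:
                blk = slice(i0, i1)
                dead = es[blk]
                wd = ws[blk][dead]
                Xd = Xs[blk][dead]
                s0d = wd.sum()
                f = np.arange(d) / d
                a0 = s0 - f * s0d
                ll -= float(np.log(a0).sum())
                if not loglik_only:
                    s1d = wd @ Xd
                    s2d = (wd[:, None] * Xd).T @ Xd
                    for fl, a0l in zip(f, a0):
                        a1 = s1 - fl * s1d
                        a2 = s2 - fl * s2d
                        grad -= a1 / a0l
                        info += a2 / a0l - np.outer(a1, a1) / a0l**2
            else:
                ll -= d * np.log(s0)
                if not loglik_only:
                    grad -= d * s1 / s0
                    info += d * (s2 / s0 - np.outer(s1, s1) / s0**2)
    return ll, grad, info


def cox_fit(
    design: dict[str, np.ndarray] | Sequence[tuple[str, np.ndarray]],
    times,
    events,
    strata=None,
    ties_method: str = "efron",
) -> CoxFit:
    """Fit a center-stratified Cox proportional-hazards model.

    Parameters
    ----------
    design
        Mapping term name -> covariate vector.  Factors must already be
        expanded into indicator columns.
    strata
        Stratum label per observation; ``None`` fits a single stratum.
    ties_method
        ``"efron"`` (default) or ``"breslow"``.

    A monotone partial likelihood (coefficient divergence beyond
    ``COX_DIVERGENCE_BOUND``) is reported, not raised: the affected terms are
    listed in ``infinite_terms`` and summarised downstream as HR = inf with
    an undefined p-value.
    """
    if ties_method not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method: {ties_method!r}")
    items = list(design.items()) if isinstance(design, dict) else list(design)
    names = [k for k, _ in items]
    X = np.column_stack([np.asarray(v, dtype=float) for _, v in items])
    t, e = _as_surv_arrays(times, events)
    if X.shape[0] != t.size:
        raise ValueError("design and survival vectors differ in length")
    if not e.any():
        raise ValueError("at least one event is required")
    strata = np.zeros(t.size, dtype=int) if strata is None else np.asarray(strata)
    for s in np.unique(strata):
        Xs = X[strata == s]
        if Xs.shape[0] > 1 and np.any(np.ptp(Xs, axis=0) == 0) and len(np.unique(strata)) == 1:
            raise ValueError("design contains a constant column")

    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, info = _cox_quantities(beta, X, t, e, strata, ties_method)
    ll_null = ll
    converged = False
    infinite: set[str] = set()
    it = 0
    for it in range(1, COX_MAX_ITER + 1):
        if np.max(np.abs(grad)) < COX_GRADIENT_TOL:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # step-halving: never accept a material decrease in the partial
        # likelihood (slack scaled to its magnitude: float accumulation
        # noise grows with the number of events)
        accept_tol = 1e-11 * (1.0 + abs(ll))
        factor = 1.0
        improved = False
        for _ in range(20):
            cand = beta + factor * step
            ll_new, _, _ = _cox_quantities(cand, X, t, e, strata, ties_method,
                                           loglik_only=True)
            if ll_new >= ll - accept_tol:
                improved = True
                break
            factor /= 2.0
        if not improved:
            # no ascent direction improves the likelihood: a floating-point
            # plateau at the maximum
            converged = True
            break
        beta = beta + factor * step
        diverged = np.abs(beta) > COX_DIVERGENCE_BOUND
        if diverged.any():
            infinite = {names[j] for j in np.nonzero(diverged)[0]}
            break
        ll_prev = ll
        ll, grad, info = _cox_quantities(beta, X, t, e, strata, ties_method)
        # on large data the gradient floor is set by float accumulation
        # noise; a vanishing likelihood change across a Newton step marks
        # the maximum just as well
        if abs(ll - ll_prev) < accept_tol:
            converged = True
            break
    if not infinite and np.max(np.abs(grad)) < COX_GRADIENT_TOL:
        converged = True
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    return CoxFit(
        coefficients=dict(zip(names, beta.tolist())),
        covariance=cov,
        loglik_null=float(ll_null),
        loglik_fitted=float(ll),
        strata_labels=np.unique(strata).tolist(),
        ties_method=ties_method,
        converged=converged and not infinite,
        n=int(t.size),
        n_events=int(e.sum()),
        infinite_terms=frozenset(infinite),
        n_iter=it,
    )


def wald_summary(fit: CoxFit, term: str) -> dict:
    """Hazard ratio, 95% CI and two-sided Wald p for one model term.

    Terms flagged by monotone-likelihood detection propagate as
    HR = inf, CI = (0, inf), p = NaN.
    """
    names = fit.term_names
    if term not in names:
        raise KeyError(f"unknown term: {term!r}")
    if term in fit.infinite_terms:
        return {"hr": float("inf"), "ci_95": (0.0, float("inf")), "p_value": float("nan")}
    j = names.index(term)
    coef = fit.coefficients[term]
    se = float(np.sqrt(max(fit.covariance[j, j], 0.0)))
    z = coef / se if se > 0 else float("nan")
    with np.errstate(over="ignore"):
        return {
            "hr": float(np.exp(coef)),
            "ci_95": (float(np.exp(coef - Z95 * se)), float(np.exp(coef + Z95 * se))),
            "p_value": float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else float("nan"),
            "coef": coef,
            "se": se,
        }


def likelihood_ratio_test(nested: CoxFit, full: CoxFit) -> TestResult:
    """LRT of two nested partial-likelihood fits on the same data."""
    if nested.n != full.n or nested.n_events != full.n_events:
        raise ValueError("models were fitted on different data")
    if nested.ties_method != full.ties_method or nested.strata_labels != full.strata_labels:
        raise ValueError("models differ in ties method or strata")
    if not set(nested.term_names) <= set(full.term_names):
        raise ValueError("models are not nested")
    df = len(full.term_names) - len(nested.term_names)
    stat = max(2.0 * (full.loglik_fitted - nested.loglik_fitted), 0.0)
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return TestResult(stat, max(df, 1), p, "lrt")


# ---------------------------------------------------------------------------
# concordance, RMST, relative importance
# ---------------------------------------------------------------------------


def _concordance_counts(score, t, e) -> tuple[float, int]:
    """Concordant-pair weight and comparable-pair count under censoring.

    A pair is comparable when the earlier time is an event and the other
    subject was observed longer (or equally long but censored).  Ties in the
    risk score count one half.
    """
    conc = 0.0
    n_pairs = 0
    for i in np.nonzero(e)[0]:
        later = (t > t[i]) | ((t == t[i]) & ~e)
        later[i] = False
        n = int(later.sum())
        if n == 0:
            continue
        n_pairs += n
        conc += float((score[i] > score[later]).sum()) + 0.5 * float(
            (score[i] == score[later]).sum()
        )
    return conc, n_pairs


def harrell_c(risk_score, times, events, n_boot: int = 200, seed: int = 0) -> ConcordanceResult:
    """Harrell's C-index with a seeded bootstrap percentile CI.

    Higher ``risk_score`` must mean higher hazard (shorter survival).
    """
    score = np.asarray(risk_score, dtype=float)
    t, e = _as_surv_arrays(times, events)
    if score.shape != t.shape:
        raise ValueError("risk_score and times differ in length")
    conc, n_pairs = _concordance_counts(score, t, e)
    if n_pairs == 0:
        raise ValueError("no comparable pairs under censoring")
    c = conc / n_pairs
    rng = np.random.default_rng(seed)
    boots = []
    n = t.size
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        bc, bp = _concordance_counts(score[idx], t[idx], e[idx])
        if bp > 0:
            boots.append(bc / bp)
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan))
    return ConcordanceResult(float(c), (float(lo), float(hi)), n_pairs)


def _rmst_one(times, events, tau: float) -> tuple[float, float]:
    """RMST (area under KM up to tau) and its large-sample variance."""
    curve = km_estimate(times, events)
    # integration knots: 0, event times below tau, tau
    ts = curve.event_times[curve.event_times < tau]
    surv = np.concatenate([[1.0], curve.survival[: ts.size]])
    knots = np.concatenate([[0.0], ts, [tau]])
    widths = np.diff(knots)
    rmst = float((surv * widths).sum())
    # variance over KM increments: sum_j (area after t_j)^2 * d/(n(n-d))
    var = 0.0
    for j in range(ts.size):
        area_after = float((surv[j + 1 :] * widths[j + 1 :]).sum())
        nr, de = curve.n_at_risk[j], curve.n_events[j]
        if nr > de:
            var += area_after**2 * de / (nr * (nr - de))
    return rmst, var


def rmst_compare(group_a: tuple, group_b: tuple, tau: float | None = None) -> RMSTResult:
    """Two-sample restricted-mean-survival-time comparison.

    ``difference`` is RMST(a) - RMST(b) in months.  Default tau is the
    smaller of the two groups' largest observed times.
    """
    ta, ea = _as_surv_arrays(*group_a)
    tb, eb = _as_surv_arrays(*group_b)
    max_a, max_b = float(ta.max()), float(tb.max())
    if tau is None:
        tau = min(max_a, max_b)
    for label, mx in (("a", max_a), ("b", max_b)):
        if tau > mx:
            raise ValueError(f"tau={tau} exceeds follow-up of group {label} ({mx})")
    ra, va = _rmst_one(ta, ea, tau)
    rb, vb = _rmst_one(tb, eb, tau)
    diff = ra - rb
    se = float(np.sqrt(va + vb))
    z = diff / se if se > 0 else 0.0
    p = float(2.0 * stats.norm.sf(abs(z))) if se > 0 else 1.0
    return RMSTResult(
        tau=float(tau),
        rmst_per_group=(ra, rb),
        difference=float(diff),
        ci_95=(float(diff - Z95 * se), float(diff + Z95 * se)),
        p_value=p,
    )


def chi2_importance(fit: CoxFit, blocks: dict[str, list[str]] | None = None) -> ImportanceResult:
    """Relative importance of model variables by Wald chi-square proportion.

    Each variable's chi-square is ``b' inv(V_bb) b`` over its coefficient
    block; proportions are the block shares of the total and sum to 1.
    Variables whose covariance block is singular are flagged NaN and the
    remaining proportions renormalised.
    """
    if not fit.converged:
        raise ValueError("importance requires a converged fit")
    names = fit.term_names
    if blocks is None:
        blocks = {nm: [nm] for nm in names}
    beta = fit.coef_vector()
    chi2: dict[str, float] = {}
    for var, terms in blocks.items():
        idx = [names.index(t) for t in terms]
        b = beta[idx]
        V = fit.covariance[np.ix_(idx, idx)]
        try:
            chi2[var] = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError:
            chi2[var] = float("nan")
    total = sum(v for v in chi2.values() if np.isfinite(v))
    prop = {
        var: (v / total if np.isfinite(v) and total > 0 else float("nan"))
        for var, v in chi2.items()
    }
    return ImportanceResult(chi2=chi2, proportion=prop)
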