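"""Survival modeling: Kaplan-Meier, log-rank, Cox PH, nested LRT, Uno's c.

The Cox partial likelihood is maximized by Newton-Raphson with Efron's
approximation for tied event times (Breslow available for cross-checks);
convergence requires max|score| < 1e-8 or a relative log-likelihood change
below 1e-10.  Model discrimination uses Uno's inverse-probability-of-
censoring-weighted concordance with a time horizon tau (default: the longest
observed event time), weighting each usable ordered pair by Ghat(t_i-)^-2
where Ghat is the Kaplan-Meier estimate of the censoring survival function.

Kaplan-Meier curves and the log-rank test are delegated to lifelines.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "KMCurve",
    "CoxFit",
    "ConcordanceResult",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "lrt_nested",
    "uno_c",
    "prognostic_dichotomize",
    "univariable_screen",
    "bootstrap_c_ci",
    "NoEventsError",
    "SingularInformationError",
    "ConvergenceError",
]


class NoEventsError(ValueError):
    """No observed events: the partial likelihood is undefined."""


class SingularInformationError(np.linalg.LinAlgError):
    """Information matrix singular on the event risk sets (unidentifiable)."""


class ConvergenceError(RuntimeError):
    pass


@dataclass
class KMCurve:
    times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray
    median: float | None  # None when the curve never drops to <= 0.5


@dataclass
class CoxFit:
    covariates: list[str]
    beta: np.ndarray
    covariance: np.ndarray
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    ties: str = "efron"

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    def confidence_intervals(self, z: float = 1.959963984540054) -> np.ndarray:
        se = self.se
        return np.exp(np.stack([self.beta - z * se, self.beta + z * se], axis=1))

    @property
    def wald_p(self) -> np.ndarray:
        z = self.beta / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    def linear_predictor(self, data: pd.DataFrame) -> np.ndarray:
        return data[self.covariates].to_numpy(dtype=float) @ self.beta

    def summary(self) -> pd.DataFrame:
        ci = self.confidence_intervals()
        return pd.DataFrame(
            {
                "covariate": self.covariates,
                "coef": self.beta,
                "hr": self.hazard_ratios,
                "hr_ci_low": ci[:, 0],
                "hr_ci_high": ci[:, 1],
                "p": self.wald_p,
            }
        )


@dataclass
class ConcordanceResult:
    c: float
    tau: float
    numerator: float
    denominator: float
    n_pairs: int
    n_pairs_excluded: int = 0


def _check_surv(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.shape != event.shape or time.ndim != 1:
        raise ValueError("time and event must be 1-D arrays of equal length")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event flags must be 0/1")
    return time, event.astype(int)


def km_estimate(time, event) -> KMCurve:
    """Product-limit survival curve; median = earliest time with S <= 0.5."""
    from lifelines import KaplanMeierFitter

    time, event = _check_surv(time, event)
    if time.size == 0:
        raise ValueError("need at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    sf = kmf.survival_function_.iloc[:, 0]
    event_times = np.asarray(sf.index, dtype=float)
    surv = sf.to_numpy(dtype=float)
    at_risk = np.array([(time >= t).sum() for t in event_times])
    below = surv <= 0.5 + 1e-12
    median = float(event_times[below][0]) if below.any() else None
    return KMCurve(times=event_times, at_risk=at_risk, survival=surv, median=median)


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group 1-df log-rank test: (chi-square statistic, p)."""
    from lifelines.statistics import logrank_test as _lr

    time, event = _check_surv(time, event)
    group = np.asarray(group)
    levels = np.unique(group)
    if levels.size != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {levels.size}")
    if event.sum() < 1:
        raise ValueError("need at least one event")
    a, b = group == levels[0], group == levels[1]
    res = _lr(time[a], time[b], event_observed_A=event[a], event_observed_B=event[b])
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox partial likelihood (Newton-Raphson; Efron / Breslow tie handling)
# ---------------------------------------------------------------------------


def _cox_loglik_score_info(beta, X, time, event, ties):
    """Partial log-likelihood, score vector, and information matrix.

    Observations are assumed sorted by ascending time so risk sets are
    suffixes.
    """
    n, p = X.shape
    eta = X @ beta
    eta -= eta.max()  # guard exp overflow; cancels in every ratio
    w = np.exp(eta)
    wX = w[:, None] * X
    wXX = wX[:, :, None] * X[:, None, :]
    # suffix (risk-set) sums
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wX[::-1], axis=0)[::-1]
    S2 = np.cumsum(wXX[::-1], axis=0)[::-1]

    ll = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        deaths = np.arange(i, j)[event[i:j] == 1]
        d = deaths.size
        if d:
            s0r, s1r, s2r = S0[i], S1[i], S2[i]
            s0d = w[deaths].sum()
            s1d = wX[deaths].sum(axis=0)
            s2d = wXX[deaths].sum(axis=0)
            ll += eta[deaths].sum()  # shifted eta; the shift cancels against log(s0)
            for ell in range(d):
                frac = ell / d if ties == "efron" else 0.0
                s0 = s0r - frac * s0d
                s1 = s1r - frac * s1d
                s2 = s2r - frac * s2d
                ll -= np.log(s0)
                score -= s1 / s0
                info += s2 / s0 - np.outer(s1, s1) / s0**2
            score += X[deaths].sum(axis=0)
        i = j
    return ll, score, info


def cox_fit(
    data: pd.DataFrame,
    covariates: list[str],
    time_col: str,
    event_col: str,
    ties: str = "efron",
    max_iter: int = 100,
    tol_score: float = 1e-8,
    tol_loglik: float = 1e-10,
) -> CoxFit:
    """Maximize the Cox partial likelihood by Newton-Raphson.

    Raises :class:`NoEventsError` when no events are observed,
    :class:`SingularInformationError` when the information matrix is singular
    on the event risk sets (e.g. a constant covariate), and
    :class:`ConvergenceError` after ``max_iter`` iterations.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    time, event = _check_surv(data[time_col], data[event_col])
    X = data[list(covariates)].to_numpy(dtype=float)
    if event.sum() < 1:
        raise NoEventsError("no events observed; cannot fit a Cox model")
    order = np.argsort(time, kind="stable")
    time, event, X = time[order], event[order], X[order]
    p = X.shape[1]

    beta = np.zeros(p)
    ll, score, info = _cox_loglik_score_info(beta, X, time, event, ties)
    ll0 = ll
    converged = np.max(np.abs(score)) < tol_score
    for _ in range(max_iter):
        if converged:
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SingularInformationError(
                "singular information matrix; covariates unidentifiable on event risk sets"
            ) from exc
        if not np.all(np.isfinite(step)):
            raise SingularInformationError("non-finite Newton step")
        # step-halving keeps the likelihood non-decreasing
        for _h in range(30):
            cand = beta + step
            ll_new, score_new, info_new = _cox_loglik_score_info(cand, X, time, event, ties)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        else:
            raise ConvergenceError("step-halving failed to improve the partial likelihood")
        rel_change = abs(ll_new - ll) / max(abs(ll), 1.0)
        beta, score, info = cand, score_new, info_new
        ll_prev, ll = ll, ll_new
        if np.max(np.abs(score)) < tol_score or rel_change < tol_loglik:
            converged = True
    if not converged:
        raise ConvergenceError(f"Newton-Raphson did not converge in {max_iter} iterations")
    if np.linalg.cond(info) > 1e12:
        raise SingularInformationError("information matrix numerically singular at the optimum")
    cov = np.linalg.inv(info)
    return CoxFit(
        covariates=list(covariates),
        beta=beta,
        covariance=cov,
        loglik=float(ll),
        loglik_null=float(ll0),
        n=len(time),
        n_events=int(event.sum()),
        ties=ties,
    )


def lrt_nested(full: CoxFit, reduced: CoxFit | None) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested pair of Cox fits on the same records.

    ``reduced=None`` compares against the null (all-equal-risk) model using
    the full fit's stored null log-likelihood.  Returns (statistic, df, p).
    """
    if reduced is None:
        ll_red, k_red = full.loglik_null, 0
    else:
        if not set(reduced.covariates) <= set(full.covariates):
            raise ValueError("models are not nested: reduced covariates not a subset")
        if reduced.n != full.n or reduced.n_events != full.n_events:
            raise ValueError("nested LRT requires the same records in both fits")
        ll_red, k_red = reduced.loglik, len(reduced.covariates)
    df = len(full.covariates) - k_red
    if df < 0:
        raise ValueError("full model must have at least as many covariates")
    stat = max(2.0 * (full.loglik - ll_red), 0.0)
    if df == 0:  # identical models: no evidence either way
        return stat, 0, 1.0
    return stat, df, float(stats.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# Uno's IPCW concordance
# ---------------------------------------------------------------------------


def _censoring_km_left(time, event, eval_times):
    """Ghat(t-): KM estimate of censoring survival, left limit at eval_times.

    Ties between event and censoring times are event-first, so a censoring at
    exactly t does not reduce Ghat(t-).
    """
    order = np.argsort(time, kind="stable")
    t_sorted, e_sorted = time[order], event[order]
    n = t_sorted.size
    uniq = np.unique(t_sorted)
    g_vals = [1.0]
    g_times = [-np.inf]
    g = 1.0
    for u in uniq:
        at_risk = n - np.searchsorted(t_sorted, u, side="left")
        n_cens = int(((t_sorted == u) & (e_sorted == 0)).sum())
        if n_cens and at_risk > 0:
            g *= 1.0 - n_cens / at_risk
        g_times.append(u)
        g_vals.append(g)
    g_times = np.asarray(g_times)
    g_vals = np.asarray(g_vals)
    # left limit: value from strictly earlier jump times
    idx = np.searchsorted(g_times, eval_times, side="left") - 1
    return g_vals[np.maximum(idx, 0)]


def uno_c(time, event, linear_predictor, tau: float | None = None) -> ConcordanceResult:
    """Uno's censoring-robust concordance statistic.

    Ordered pairs (i, j) with event_i = 1, t_i < t_j and t_i < tau contribute
    weight Ghat(t_i-)^-2; a pair counts 1 if lp_i > lp_j, 0.5 on ties.  Pairs
    whose weight is undefined (Ghat = 0) are excluded and reported.
    """
    time, event = _check_surv(time, event)
    lp = np.asarray(linear_predictor, dtype=float)
    if tau is None:
        if event.sum() == 0:
            raise NoEventsError("no events: tau undefined and no usable pairs")
        tau = float(time[event == 1].max())
    if tau <= 0:
        raise ValueError("tau must be > 0")
    g_left = _censoring_km_left(time, event, time)

    num = den = 0.0
    n_pairs = n_excl = 0
    for i in np.flatnonzero((event == 1) & (time < tau)):
        js = np.flatnonzero(time > time[i])
        if js.size == 0:
            continue
        if g_left[i] <= 0.0:
            n_excl += js.size
            continue
        w = 1.0 / g_left[i] ** 2
        n_pairs += js.size
        den += w * js.size
        num += w * (np.sum(lp[i] > lp[js]) + 0.5 * np.sum(lp[i] == lp[js]))
    if den == 0:
        raise ValueError("no usable pairs for the concordance statistic")
    if n_excl:
        logger.warning("uno_c: excluded %d pairs with Ghat(t-) = 0", n_excl)
    return ConcordanceResult(
        c=float(num / den),
        tau=float(tau),
        numerator=float(num),
        denominator=float(den),
        n_pairs=n_pairs,
        n_pairs_excluded=n_excl,
    )


def bootstrap_c_ci(
    data: pd.DataFrame,
    covariates: list[str],
    time_col: str,
    event_col: str,
    tau: float | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float, float]:
    """Percentile bootstrap CI for Uno's c of a refit Cox model.

    Each resample redraws patients with replacement, refits the model, and
    recomputes the c-statistic on the resample (tau fixed at its full-sample
    value).  Returns (c, ci_low, ci_high).
    """
    fit = cox_fit(data, covariates, time_col, event_col)
    res = uno_c(data[time_col], data[event_col], fit.linear_predictor(data), tau=tau)
    rng = np.random.default_rng(seed)
    n = len(data)
    cs = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        boot = data.iloc[idx]
        try:
            bfit = cox_fit(boot, covariates, time_col, event_col)
            bres = uno_c(boot[time_col], boot[event_col], bfit.linear_predictor(boot), tau=res.tau)
        except (NoEventsError, SingularInformationError, ConvergenceError, ValueError):
            continue
        cs.append(bres.c)
    if len(cs) < max(20, n_boot // 10):
        warnings.warn("bootstrap_c_ci: most resamples failed; CI unreliable")
    lo, hi = np.percentile(cs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return res.c, float(lo), float(hi)


def prognostic_dichotomize(fit: CoxFit, data: pd.DataFrame, time_col: str, event_col: str):
    """Split at the median prognostic score (x'beta); ties go to the low group.

    Returns a dict with the boolean high-score indicator, per-group KM curves,
    and the two-group log-rank (statistic, p).
    """
    scores = fit.linear_predictor(data)
    if np.allclose(scores, scores[0]):
        raise ValueError("all prognostic scores equal; median split undefined")
    med = float(np.median(scores))
    high = scores > med
    time, event = _check_surv(data[time_col], data[event_col])
    stat, p = logrank_test(time, event, high)
    return {
        "high_score": high,
        "median_score": med,
        "km_low": km_estimate(time[~high], event[~high]),
        "km_high": km_estimate(time[high], event[high]),
        "logrank_statistic": stat,
        "logrank_p": p,
    }


def univariable_screen(
    data: pd.DataFrame,
    candidates: list[str],
    time_col: str,
    event_col: str,
    threshold: float = 0.2,
    always_keep: tuple[str, ...] = ("n_mutations",),
) -> dict:
    """One univariable Cox fit per candidate; retain Wald p <= threshold.

    Covariates in ``always_keep`` are retained regardless of their p-value
    (the study kept mutation count in the multivariable model at p = 0.97).
    Candidates whose fit fails are skipped with a warning.
    """
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    pvals: dict[str, float] = {}
    fits: dict[str, CoxFit] = {}
    skipped: list[str] = []
    for name in candidates:
        try:
            fit = cox_fit(data, [name], time_col, event_col)
        except (NoEventsError, SingularInformationError, ConvergenceError) as exc:
            warnings.warn(f"univariable screen: skipping {name!r}: {exc}")
            skipped.append(name)
            continue
        fits[name] = fit
        pvals[name] = float(fit.wald_p[0])
    retained = [c for c in candidates if c in pvals and pvals[c] <= threshold]
    for name in always_keep:
        if name not in retained and name in data.columns and name not in skipped:
            retained.append(name)
            if name not in fits:
                fits[name] = cox_fit(data, [name], time_col, event_col)
                pvals[name] = float(fits[name].wald_p[0])
    return {"retained": retained, "p_values": pvals, "fits": fits, "skipped": skipped}
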