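"""Survival statistics implemented from the partial-likelihood up.

Right-censored time-to-event analysis for cohort endpoints (OS/PFS, in
months, no delayed entry):

* Kaplan-Meier product-limit estimation with Greenwood variance,
* the k-sample log-rank test and its Gehan-Breslow weighted variant
  (the "Wilcoxon" of clinical software; weight = number at risk),
* Cox proportional-hazards regression by Newton-Raphson maximization of
  the partial likelihood, with Efron (default) or Breslow tie handling,
  Wald tests and 95% CIs,
* a univariate screen over a covariate set (no multiplicity correction),
* forward stepwise model building with a p-to-enter rule (default 0.2)
  and clinically forced-in covariates.

These estimators are written here directly rather than delegated, so they
can be checked against hand-enumerated risk sets and independent fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "SurvTestResult",
    "CoxModel",
    "StepwiseSpec",
    "km_estimate",
    "km_median",
    "logrank_test",
    "gehan_wilcoxon_test",
    "cox_fit",
    "univariate_screen",
    "stepwise_cox",
]


@dataclass
class SurvivalRecord:
    subject_id: str
    time: float            # months, > 0
    event: bool            # True = event observed, False = censored
    endpoint: str = "OS"   # OS | PFS

    def __post_init__(self) -> None:
        if not (math.isfinite(self.time) and self.time > 0):
            raise ValueError(f"time must be finite and positive, got {self.time}")


def _as_arrays(records) -> tuple[np.ndarray, np.ndarray]:
    """Accept a list of SurvivalRecord or a (time, event) pair of arrays."""
    if isinstance(records, tuple) and len(records) == 2:
        t = np.asarray(records[0], dtype=float)
        e = np.asarray(records[1], dtype=bool)
    else:
        t = np.array([r.time for r in records], dtype=float)
        e = np.array([r.event for r in records], dtype=bool)
    if t.size == 0:
        raise ValueError("no survival records supplied")
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise ValueError("times must be finite and positive")
    return t, e


@dataclass
class KMCurve:
    """Product-limit estimate over the distinct event times.

    Censoring tied with an event time is handled after the events (the
    standard convention): censored subjects still count in that risk set.
    """

    event_times: np.ndarray    # distinct times with >= 1 event
    survival: np.ndarray       # S(t) immediately after each event time
    at_risk: np.ndarray        # n at risk just before each event time
    events: np.ndarray         # d at each event time
    greenwood_var: np.ndarray  # Greenwood variance of S(t)

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


def km_estimate(records) -> KMCurve:
    """Kaplan-Meier estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    t, e = _as_arrays(records)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    ev_times = np.unique(t[e])
    n = t.size
    times, surv, atrisk, nevents, gvar = [], [], [], [], []
    s = 1.0
    gsum = 0.0
    for ti in ev_times:
        ni = int(np.sum(t >= ti))
        di = int(np.sum((t == ti) & e))
        s *= 1.0 - di / ni
        if ni > di:
            gsum += di / (ni * (ni - di))
            var = s * s * gsum
        else:
            var = 0.0  # S hit zero; Greenwood term degenerate
        times.append(ti)
        surv.append(s)
        atrisk.append(ni)
        nevents.append(di)
        gvar.append(var)
    return KMCurve(np.array(times), np.array(surv), np.array(atrisk),
                   np.array(nevents), np.array(gvar))


def km_median(records) -> float:
    """Median survival time: first event time with S(t) <= 0.5 (inf if never)."""
    curve = km_estimate(records)
    below = np.nonzero(curve.survival <= 0.5)[0]
    return float(curve.event_times[below[0]]) if below.size else math.inf


@dataclass
class SurvTestResult:
    statistic: float
    df: int
    p_value: float
    variant: str  # logrank | gehan_wilcoxon


def _weighted_rank_test(groups, weight: str) -> SurvTestResult:
    """k-sample weighted log-rank statistic with hypergeometric variance.

    ``weight`` is "logrank" (w=1) or "gehan" (w = total at risk), summed
    over distinct event times; chi-square reference on k-1 df via the
    pseudo-inverse of the summed covariance.
    """
    arrays = [_as_arrays(g) for g in groups]
    k = len(arrays)
    if k < 2:
        raise ValueError("need at least two groups")
    t = np.concatenate([a[0] for a in arrays])
    e = np.concatenate([a[1] for a in arrays])
    g = np.concatenate([np.full(a[0].size, i) for i, a in enumerate(arrays)])
    ev_times = np.unique(t[e])
    if ev_times.size == 0:
        raise ValueError("no events in any group; statistic undefined")

    score = np.zeros(k)
    cov = np.zeros((k, k))
    for ti in ev_times:
        at_risk = t >= ti
        n_i = int(at_risk.sum())
        d_i = int(((t == ti) & e).sum())
        if n_i == 0 or d_i == 0:
            continue
        n_ij = np.array([(at_risk & (g == j)).sum() for j in range(k)], float)
        d_ij = np.array([(((t == ti) & e) & (g == j)).sum() for j in range(k)], float)
        expected = d_i * n_ij / n_i
        w = float(n_i) if weight == "gehan" else 1.0
        score += w * (d_ij - expected)
        if n_i > 1:
            p = n_ij / n_i
            v = d_i * (n_i - d_i) / (n_i - 1) * (np.diag(p) - np.outer(p, p))
            cov += w * w * v
    # covariance is singular (rows sum to 0); test on any k-1 subvector
    sub = slice(0, k - 1)
    v_sub = cov[sub, sub]
    s_sub = score[sub]
    try:
        chi2 = float(s_sub @ np.linalg.solve(v_sub, s_sub))
    except np.linalg.LinAlgError:
        chi2 = float(s_sub @ np.linalg.pinv(v_sub) @ s_sub)
    chi2 = max(chi2, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return SurvTestResult(chi2, df, p,
                          "gehan_wilcoxon" if weight == "gehan" else "logrank")


def logrank_test(groups) -> SurvTestResult:
    """k-sample log-rank test (observed minus expected, unit weights)."""
    return _weighted_rank_test(groups, "logrank")


def gehan_wilcoxon_test(groups) -> SurvTestResult:
    """Gehan-Breslow generalized Wilcoxon test (weight = n at risk).

    Emphasizes early hazard differences relative to the log-rank test.
    """
    return _weighted_rank_test(groups, "gehan")


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxModel:
    covariate_names: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    hazard_ratios: np.ndarray
    ci95_low: np.ndarray
    ci95_high: np.ndarray
    wald_p: np.ndarray
    log_partial_likelihood: float
    n_iterations: int
    converged: bool
    ties_method: str = "efron"
    separation_flag: bool = False
    n: int = 0
    n_events: int = 0

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.coefficients, "se": self.standard_errors,
            "HR": self.hazard_ratios, "ci95_low": self.ci95_low,
            "ci95_high": self.ci95_high, "p": self.wald_p,
        }, index=self.covariate_names)


def _cox_loglik_grad_hess(beta, t, e, X, ties):
    """Log partial likelihood, score and information, Efron or Breslow ties.

    Arrays must be sorted by ascending time.  Risk-set sums are suffix
    sums; tied deaths at one time form one Efron correction block.
    """
    n, p = X.shape
    eta = X @ beta
    eta -= eta.max()  # guard overflow; cancels in the ratios and in rel. loglik
    r = np.exp(eta)
    rx = r[:, None] * X
    rxx = np.einsum("i,ij,ik->ijk", r, X, X)
    # suffix sums over the risk set {j : t_j >= t_i}
    S0 = np.cumsum(r[::-1])[::-1]
    S1 = np.cumsum(rx[::-1], axis=0)[::-1]
    S2 = np.cumsum(rxx[::-1], axis=0)[::-1]

    loglik = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        deaths = [m for m in range(i, j) if e[m]]
        d = len(deaths)
        if d:
            xd = X[deaths]
            loglik += eta[deaths].sum()
            s0, s1, s2 = S0[i], S1[i], S2[i]
            if ties == "breslow" or d == 1:
                for _ in range(d):
                    mu = s1 / s0
                    loglik -= math.log(s0) if ties == "breslow" else 0.0
                    grad -= mu
                    info += s2 / s0 - np.outer(mu, mu)
                if ties != "breslow":
                    loglik -= d * math.log(s0)
            else:
                rd = r[deaths].sum()
                r1 = rx[deaths].sum(axis=0)
                r2 = rxx[deaths].sum(axis=0)
                for l in range(d):
                    f = l / d
                    a0 = s0 - f * rd
                    a1 = s1 - f * r1
                    a2 = s2 - f * r2
                    mu = a1 / a0
                    loglik -= math.log(a0)
                    grad -= mu
                    info += a2 / a0 - np.outer(mu, mu)
            grad += xd.sum(axis=0)
        i = j
    return loglik, grad, info


def cox_fit(records, covariates, covariate_names: Optional[list[str]] = None,
            ties_method: str = "efron", tol: float = 1e-9,
            max_iter: int = 25) -> CoxModel:
    """Cox proportional-hazards fit by Newton-Raphson.

    ``records`` is a list of SurvivalRecord or a (time, event) pair;
    ``covariates`` an (n, p) matrix row-aligned with the records.
    Convergence when the score max-norm drops below ``tol``.  A coefficient
    diverging past |beta| > 25 flags monotone likelihood (separation).
    """
    t, e = _as_arrays(records)
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] != t.size:
        X = X.T
    if X.shape[0] != t.size:
        raise ValueError("covariate rows must align with records")
    n, p = X.shape
    if covariate_names is None:
        covariate_names = [f"x{j}" for j in range(p)]
    if e.sum() < 1:
        raise ValueError("need at least one event")
    if ties_method not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method {ties_method!r}")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant covariate column supplied")

    order = np.argsort(t, kind="stable")
    ts, es, Xs = t[order], e[order], X[order]
    # center for conditioning; partial likelihood is shift-invariant
    xm = Xs.mean(axis=0)
    Xc = Xs - xm

    beta = np.zeros(p)
    converged = False
    separation = False
    loglik = -math.inf
    it = 0
    for it in range(1, max_iter + 1):
        loglik, grad, info = _cox_loglik_grad_hess(beta, ts, es, Xc, ties_method)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # step-halving keeps Newton from overshooting on steep likelihoods
        for _ in range(6):
            cand = beta + step
            ll_new = _cox_loglik_grad_hess(cand, ts, es, Xc, ties_method)[0]
            if ll_new >= loglik - 1e-12:
                break
            step /= 2.0
        beta = beta + step
        if np.max(np.abs(beta)) > 25:
            separation = True
            break
    loglik, grad, info = _cox_loglik_grad_hess(beta, ts, es, Xc, ties_method)
    if not separation and np.max(np.abs(grad)) < tol:
        converged = True
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    # monotone likelihood: the score can vanish numerically while beta and
    # its standard error diverge; treat both as separation
    if np.any(np.abs(beta) > 15) or np.any(se > 50):
        separation = True
    z = np.divide(beta, se, out=np.full(p, np.nan), where=se > 0)
    wald_p = 2 * stats.norm.sf(np.abs(z))
    zcrit = stats.norm.ppf(0.975)
    with np.errstate(over="ignore"):  # CI bounds overflow under separation
        ci_lo = np.exp(beta - zcrit * se)
        ci_hi = np.exp(beta + zcrit * se)
    return CoxModel(
        covariate_names=list(covariate_names),
        coefficients=beta,
        standard_errors=se,
        hazard_ratios=np.exp(beta),
        ci95_low=ci_lo,
        ci95_high=ci_hi,
        wald_p=wald_p,
        log_partial_likelihood=float(loglik),
        n_iterations=it,
        converged=bool(converged and not separation),
        ties_method=ties_method,
        separation_flag=separation,
        n=n,
        n_events=int(e.sum()),
    )


def univariate_screen(records, covariate_frame: pd.DataFrame,
                      ties_method: str = "efron") -> pd.DataFrame:
    """One single-covariate Cox fit per column, sorted by Wald p-value.

    No multiplicity correction is applied.  Per-covariate failures are
    reported in an ``error`` column rather than aborting the screen.
    """
    rows = []
    for name in covariate_frame.columns:
        x = covariate_frame[name].to_numpy(dtype=float)
        try:
            m = cox_fit(records, x[:, None], [name], ties_method=ties_method)
            rows.append({"covariate": name, "coef": m.coefficients[0],
                         "se": m.standard_errors[0], "HR": m.hazard_ratios[0],
                         "ci95_low": m.ci95_low[0], "ci95_high": m.ci95_high[0],
                         "p": m.wald_p[0], "converged": m.converged,
                         "error": None})
        except Exception as exc:  # noqa: BLE001 - reported, not fatal
            rows.append({"covariate": name, "coef": np.nan, "se": np.nan,
                         "HR": np.nan, "ci95_low": np.nan, "ci95_high": np.nan,
                         "p": np.nan, "converged": False, "error": str(exc)})
    out = pd.DataFrame(rows, columns=["covariate", "coef", "se", "HR",
                                      "ci95_low", "ci95_high", "p",
                                      "converged", "error"])
    return out.sort_values("p", na_position="last").reset_index(drop=True)


@dataclass
class StepwiseSpec:
    candidate_covariates: list[str]
    forced_in_covariates: list[str] = field(default_factory=list)
    p_enter: float = 0.2
    direction: str = "forward"  # forward | both

    def __post_init__(self) -> None:
        if not 0 < self.p_enter <= 1:
            raise ValueError("p_enter must be in (0, 1]")
        # forced-in variables are removed from the candidate pool
        self.candidate_covariates = [
            c for c in self.candidate_covariates
            if c not in self.forced_in_covariates]


def stepwise_cox(records, covariate_frame: pd.DataFrame, spec: StepwiseSpec,
                 ties_method: str = "efron") -> tuple[CoxModel, list[dict]]:
    """Forward stepwise Cox model building.

    Forced-in covariates enter unconditionally first; then at each step the
    candidate with the smallest Wald p-value below ``p_enter`` (evaluated in
    the current model) is added.  With ``direction="both"``, after each
    addition any non-forced covariate whose p-value rose above ``p_enter``
    is removed.  Returns the final model and the selection trace.
    """
    selected = list(spec.forced_in_covariates)
    remaining = list(spec.candidate_covariates)
    trace: list[dict] = []

    def fit(cols):
        X = covariate_frame[cols].to_numpy(dtype=float)
        return cox_fit(records, X, cols, ties_method=ties_method)

    for name in selected:
        trace.append({"action": "force_in", "covariate": name, "p": None})

    while remaining:
        best_name, best_p = None, math.inf
        for name in remaining:
            try:
                m = fit(selected + [name])
                p = float(m.wald_p[-1])
            except Exception:
                continue
            if math.isfinite(p) and p < best_p:
                best_name, best_p = name, p
        if best_name is None or best_p >= spec.p_enter:
            break
        selected.append(best_name)
        remaining.remove(best_name)
        trace.append({"action": "enter", "covariate": best_name, "p": best_p})
        if spec.direction == "both" and len(selected) > 1:
            m = fit(selected)
            for j, name in enumerate(list(selected)):
                if name in spec.forced_in_covariates or name == best_name:
                    continue
                if m.wald_p[j] >= spec.p_enter:
                    selected.remove(name)
                    remaining.append(name)
                    trace.append({"action": "remove", "covariate": name,
                                  "p": float(m.wald_p[j])})

    if selected:
        model = fit(selected)
    else:
        model = CoxModel([], np.array([]), np.array([]), np.array([]),
                         np.array([]), np.array([]), np.array([]),
                         math.nan, 0, True, ties_method)
    return model, trace
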