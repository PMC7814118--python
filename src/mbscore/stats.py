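"""Survival and classification statistics.

Self-contained implementations of the estimators the scoring pipeline rests
on: the Kaplan-Meier product-limit estimator with Greenwood variance, the
k-sample log-rank test, Cox proportional-hazards regression by Newton
maximization of the partial likelihood (Efron or Breslow tie handling),
Harrell's concordance index, ROC AUC with DeLong variance and the paired
DeLong test, a scaled-Schoenfeld-residual check of the proportional-hazards
assumption, and the simple group-comparison tests (Mann-Whitney, Kruskal-
Wallis, chi-square, Fisher).

Conventions
-----------
* Times are months; events are 1 for observed death, 0 for right censoring.
* Scores are risk-oriented: a higher value predicts earlier death.
* All p-values are two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConvergenceError, ValidationError

_Z975 = sps.norm.ppf(0.975)


@dataclass
class TestResult:
    """Outcome of a hypothesis test."""

    statistic: float
    p_value: float
    name: str
    df: int | None = None

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValidationError(f"p-value out of [0,1]: {self.p_value}")


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit estimate of the survival function.

    ``event_times`` are the distinct observed death times; ``survival`` the
    estimate just after each, with Greenwood variance ``greenwood_var``.
    ``median_time`` is the smallest event time with S(t) <= 0.5, or ``None``
    when the curve never reaches 0.5 ("not reached").
    """

    event_times: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    n: int
    median_time: float | None
    ci_level: float = 0.95

    def survival_at(self, t: float) -> float:
        """S(t): the estimate at the last event time <= t (1.0 before any)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def ci_at(self, t: float) -> tuple[float, float]:
        """Pointwise CI for S(t) on the log(-log) scale (bounds stay in [0,1])."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        if idx < 0:
            return (1.0, 1.0)
        s = float(self.survival[idx])
        v = float(self.greenwood_var[idx])
        if s <= 0.0:
            return (0.0, 0.0)
        if s >= 1.0 or v == 0.0:
            return (s, s)
        z = sps.norm.ppf(0.5 + self.ci_level / 2.0)
        se_loglog = np.sqrt(v) / (s * abs(np.log(s)))
        lo = s ** np.exp(z * se_loglog)
        hi = s ** np.exp(-z * se_loglog)
        return (float(lo), float(hi))


def km_fit(times, events, ci_level: float = 0.95) -> KMCurve:
    """Kaplan-Meier product-limit fit with Greenwood variance."""
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValidationError("km_fit: empty input")
    if t.shape != d.shape:
        raise ValidationError("km_fit: times and events differ in length")
    if np.any(t <= 0) or not np.all(np.isfinite(t)):
        raise ValidationError("km_fit: times must be finite and > 0")
    order = np.argsort(t, kind="stable")
    t, d = t[order], d[order]
    n = t.size

    event_times = np.unique(t[d == 1])
    if event_times.size == 0:
        return KMCurve(
            event_times=np.array([]),
            survival=np.array([]),
            greenwood_var=np.array([]),
            n_at_risk=np.array([], dtype=int),
            n_events=np.array([], dtype=int),
            n=n,
            median_time=None,
            ci_level=ci_level,
        )
    # at-risk count just before each event time; deaths at each event time
    n_at_risk = n - np.searchsorted(t, event_times, side="left")
    td = t[d == 1]
    n_events = np.searchsorted(td, event_times, side="right") - np.searchsorted(
        td, event_times, side="left"
    )
    frac = 1.0 - n_events / n_at_risk
    survival = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        greenwood_terms = n_events / (n_at_risk * (n_at_risk - n_events))
        greenwood_terms = np.where(n_at_risk > n_events, greenwood_terms, np.inf)
        # S(t) = 0 makes the cumulative term infinite; the variance of an
        # exactly-zero estimate is reported as 0
        greenwood_var = survival**2 * np.cumsum(greenwood_terms)
    greenwood_var = np.where(survival == 0.0, 0.0, greenwood_var)

    below = survival <= 0.5 + 1e-12
    median_time = float(event_times[below][0]) if below.any() else None
    return KMCurve(
        event_times=event_times,
        survival=survival,
        greenwood_var=greenwood_var,
        n_at_risk=n_at_risk.astype(int),
        n_events=n_events.astype(int),
        n=n,
        median_time=median_time,
        ci_level=ci_level,
    )


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

def logrank(times, events, groups) -> TestResult:
    """k-sample log-rank test (chi-square with k-1 degrees of freedom)."""
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    if not (t.shape == d.shape == g.shape):
        raise ValidationError("logrank: input lengths differ")
    labels, gidx = np.unique(g, return_inverse=True)
    k = labels.size
    if k < 2:
        raise ValidationError("logrank: need at least two groups")
    counts = np.bincount(gidx, minlength=k)
    if np.any(counts == 0):  # pragma: no cover - unique() precludes this
        raise ValidationError("logrank: a group has zero subjects")

    event_times = np.unique(t[d == 1])
    observed = np.zeros(k)
    expected = np.zeros(k)
    V = np.zeros((k, k))
    for et in event_times:
        at_risk = t >= et
        n_i = at_risk.sum()
        if n_i < 1:
            continue
        dead = at_risk & (t == et) & (d == 1)
        d_i = dead.sum()
        n_ij = np.bincount(gidx[at_risk], minlength=k).astype(float)
        d_ij = np.bincount(gidx[dead], minlength=k).astype(float)
        p = n_ij / n_i
        observed += d_ij
        expected += d_i * p
        if n_i > 1:
            mult = d_i * (n_i - d_i) / (n_i - 1)
            V += mult * (np.diag(p) - np.outer(p, p))
    u = (observed - expected)[:-1]
    Vsub = V[:-1, :-1]
    if u.size == 0 or not np.any(Vsub):
        chi2 = 0.0
    else:
        chi2 = float(u @ np.linalg.pinv(Vsub) @ u)
        chi2 = max(chi2, 0.0)
    df = k - 1
    return TestResult(
        statistic=chi2, p_value=float(sps.chi2.sf(chi2, df)), name="logrank", df=df
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model.

    ``names`` are the expanded design-matrix columns (categorical covariates
    are reference-coded); per-column Wald statistics use one degree of
    freedom; ``joint_tests`` holds a joint Wald test per multi-level source
    covariate.  ``monotone_flags`` marks coefficients that diverged
    (complete separation / monotone partial likelihood).
    """

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    loglik_null: float
    converged: bool
    n_iter: int
    ties: str
    n: int
    n_events: int
    monotone_flags: np.ndarray
    joint_tests: dict = field(default_factory=dict)
    _times: np.ndarray | None = None
    _events: np.ndarray | None = None
    _X: np.ndarray | None = None

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci_lower(self) -> np.ndarray:
        with np.errstate(over="ignore"):
            return np.exp(self.beta - _Z975 * self.se)

    @property
    def ci_upper(self) -> np.ndarray:
        with np.errstate(over="ignore"):
            return np.exp(self.beta + _Z975 * self.se)

    @property
    def wald_chi2(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.se > 0, (self.beta / self.se) ** 2, np.inf)

    @property
    def p_values(self) -> np.ndarray:
        return sps.chi2.sf(self.wald_chi2, 1)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.names,
                "coef": self.beta,
                "hr": self.hazard_ratios,
                "hr_lower": self.ci_lower,
                "hr_upper": self.ci_upper,
                "se": self.se,
                "wald_chi2": self.wald_chi2,
                "p": self.p_values,
                "monotone": self.monotone_flags,
            }
        )


def _expand_design(covariates) -> tuple[np.ndarray, list[str], dict]:
    """Reference-code a DataFrame (or pass through an array) into a design
    matrix; returns (X, names, source-covariate → column-indices map)."""
    if isinstance(covariates, pd.DataFrame):
        cols, names, groups = [], [], {}
        for col in covariates.columns:
            s = covariates[col]
            if pd.api.types.is_numeric_dtype(s):
                groups[col] = [len(names)]
                names.append(str(col))
                cols.append(s.to_numpy(dtype=float))
            else:
                levels = pd.unique(s.dropna())
                if len(levels) < 2:
                    raise ValidationError(
                        f"categorical covariate {col!r} has a single level"
                    )
                idxs = []
                for lev in levels[1:]:  # first level = reference
                    idxs.append(len(names))
                    names.append(f"{col}[{lev}]")
                    cols.append((s == lev).to_numpy(dtype=float))
                groups[str(col)] = idxs
        X = np.column_stack(cols)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i}" for i in range(X.shape[1])]
        groups = {n: [i] for i, n in enumerate(names)}
    return X, names, groups


def cox_loglik(beta, times, events, X, ties: str = "efron"):
    """Log partial likelihood with analytic gradient and Hessian.

    Returns ``(loglik, gradient, hessian)``; the Hessian is the matrix of
    second derivatives (negative definite away from degeneracy).
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    order = np.argsort(t, kind="stable")
    t, d, Xs = t[order], d[order], X[order]
    n, p = Xs.shape
    eta = Xs @ beta
    eta = eta - eta.max()  # overflow guard; cancels in all ratios and is
    r = np.exp(eta)        # restored in the log-likelihood below
    # suffix sums over the risk set {i : t_i >= t}
    S0 = np.cumsum(r[::-1])[::-1]
    S1 = np.cumsum((r[:, None] * Xs)[::-1], axis=0)[::-1]
    S2 = np.cumsum((r[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]))[::-1], axis=0)[::-1]

    if ties not in ("efron", "breslow"):
        raise ValidationError(f"unknown ties method {ties!r}")
    loglik = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    event_times = np.unique(t[d == 1])
    starts_all = np.searchsorted(t, event_times, side="left")
    td = t[d == 1]
    dn_all = np.searchsorted(td, event_times, side="right") - np.searchsorted(
        td, event_times, side="left"
    )
    # untied event times (or any, under Breslow with d=1) in one vectorized pass
    # (extreme beta during Newton step exploration can underflow S0 to zero;
    # the resulting non-finite loglik is rejected by the step-halving caller)
    untied = dn_all == 1
    if untied.any():
        ev_t = event_times[untied]
        starts_u = starts_all[untied]
        # the single death at each untied time, located among the sorted deaths
        death_rows = np.flatnonzero(d == 1)
        ev_rows = death_rows[np.searchsorted(td, ev_t, side="left")]
        s0 = S0[starts_u]
        with np.errstate(divide="ignore", invalid="ignore"):
            mcol = S1[starts_u] / s0[:, None]
            loglik += float(eta[ev_rows].sum() - np.log(s0).sum())
            grad += Xs[ev_rows].sum(axis=0) - mcol.sum(axis=0)
            hess -= (S2[starts_u] / s0[:, None, None]).sum(axis=0) - np.einsum(
                "ij,ik->jk", mcol, mcol
            )
    for et, start, Dn in zip(
        event_times[~untied], starts_all[~untied], dn_all[~untied]
    ):
        in_set = (t == et) & (d == 1)
        Dn = int(Dn)
        xD = Xs[in_set]
        rD = r[in_set]
        s0, s1, s2 = S0[start], S1[start], S2[start]
        loglik += float(eta[in_set].sum())
        grad += xD.sum(axis=0)
        if ties == "breslow":
            loglik -= Dn * np.log(s0)
            m = s1 / s0
            grad -= Dn * m
            hess -= Dn * (s2 / s0 - np.outer(m, m))
        else:
            s0D = rD.sum()
            s1D = (rD[:, None] * xD).sum(axis=0)
            s2D = (rD[:, None, None] * (xD[:, :, None] * xD[:, None, :])).sum(axis=0)
            for k in range(Dn):
                f = k / Dn
                phi0 = s0 - f * s0D
                phi1 = s1 - f * s1D
                phi2 = s2 - f * s2D
                loglik -= np.log(phi0)
                m = phi1 / phi0
                grad -= m
                hess -= phi2 / phi0 - np.outer(m, m)
    # the eta shift cancels within every per-event term (eta_i minus a
    # log-sum-exp over the risk set), so loglik is already on the true scale
    return loglik, grad, hess


def cox_fit(
    times,
    events,
    covariates,
    ties: str = "efron",
    max_iter: int = 100,
    tol: float = 1e-10,
    names: list[str] | None = None,
) -> CoxFit:
    """Fit a Cox model by Newton maximization of the partial likelihood.

    ``covariates`` may be a numeric array (columns = covariates) or a
    DataFrame whose non-numeric columns are expanded to reference-coded
    indicators.  Ties are handled by Efron's method (default) or Breslow's.
    Coefficients that diverge (monotone likelihood / complete separation)
    are flagged rather than silently returned.
    """
    if ties not in ("efron", "breslow"):
        raise ValidationError(f"unknown ties method {ties!r}")
    X, auto_names, groups = _expand_design(covariates)
    if names is not None:
        if len(names) != len(auto_names):
            raise ValidationError("names length does not match design columns")
        auto_names = list(names)
        groups = {n: [i] for i, n in enumerate(auto_names)}
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    if X.shape[0] != t.size or t.size != d.size:
        raise ValidationError("cox_fit: input lengths differ")
    if np.isnan(X).any():
        raise ValidationError("cox_fit: missing covariate values (complete cases only)")
    n_events = int(d.sum())
    if n_events == 0:
        raise ValidationError("cox_fit: no events")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [auto_names[i] for i in np.flatnonzero(sd == 0)]
        raise ValidationError(f"cox_fit: constant covariates {bad}")

    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = cox_loglik(beta, t, d, X, ties)
    loglik_null = ll
    converged = False
    n_iter = 0
    monotone = np.zeros(p, dtype=bool)
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
        # step halving to guarantee ascent
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, grad_new, hess_new = cox_loglik(cand, t, d, X, ties)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        monotone = np.abs(beta) > 15.0
        if monotone.any():
            warnings.warn(
                "cox_fit: monotone partial likelihood detected for "
                f"{[auto_names[i] for i in np.flatnonzero(monotone)]}; "
                "coefficients are unstable",
                stacklevel=2,
            )
            break
        if np.max(np.abs(scale * step)) < tol and np.linalg.norm(grad) < 1e-6:
            converged = True
            break
    if not converged and not monotone.any():
        if np.linalg.norm(grad) < 1e-6:
            converged = True
        else:
            raise ConvergenceError(
                f"cox_fit did not converge in {max_iter} iterations "
                f"(gradient norm {np.linalg.norm(grad):.3g})",
                last_beta=beta,
            )

    info = -hess
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:  # pragma: no cover
        cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    fit = CoxFit(
        names=auto_names,
        beta=beta,
        se=se,
        cov=cov,
        loglik=ll,
        loglik_null=loglik_null,
        converged=converged,
        n_iter=n_iter,
        ties=ties,
        n=t.size,
        n_events=n_events,
        monotone_flags=monotone,
        _times=t,
        _events=d,
        _X=X,
    )
    # joint Wald test per multi-level source covariate
    for src, idxs in groups.items():
        if len(idxs) > 1:
            b = beta[idxs]
            Vb = cov[np.ix_(idxs, idxs)]
            chi2 = float(b @ np.linalg.solve(Vb, b))
            fit.joint_tests[src] = TestResult(
                statistic=chi2,
                p_value=float(sps.chi2.sf(chi2, len(idxs))),
                name="wald_joint",
                df=len(idxs),
            )
    return fit


def profile_lower_bound(fit: CoxFit, index: int, level: float = 0.95) -> float:
    """Profile-likelihood lower confidence bound for one coefficient.

    Intended for monotone-likelihood coefficients whose Wald interval is
    meaningless; scans beta_j downward until the profile log-likelihood
    drops by the chi-square threshold.
    """
    t, d, X = fit._times, fit._events, fit._X
    if t is None:
        raise ValidationError("fit does not carry its data")
    thresh = sps.chi2.ppf(level, 1) / 2.0
    ll_hat = fit.loglik

    def profile_ll(bj: float) -> float:
        others = [i for i in range(X.shape[1]) if i != index]
        offset_x = X[:, index] * bj
        if not others:
            ll, _, _ = cox_loglik(np.array([bj]), t, d, X[:, [index]], fit.ties)
            return ll
        # refit the remaining coefficients with beta_j fixed via an offset
        # column trick: absorb bj*x_j into an unpenalized offset by augmenting
        # the partial likelihood directly.
        Xo = X[:, others]
        beta_o = fit.beta[others].copy()
        for _ in range(50):
            ll, g, h = _cox_loglik_offset(beta_o, t, d, Xo, offset_x, fit.ties)
            try:
                step = np.linalg.solve(-h, g)
            except np.linalg.LinAlgError:
                break
            beta_o = beta_o + step
            if np.max(np.abs(step)) < 1e-9:
                break
        ll, _, _ = _cox_loglik_offset(beta_o, t, d, Xo, offset_x, fit.ties)
        return ll

    bj = min(fit.beta[index], 15.0)
    lo, hi = bj - 40.0, bj
    # bisect for profile_ll(b) = ll_hat - thresh
    target = ll_hat - thresh
    if profile_ll(lo) > target:
        return float("-inf")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if profile_ll(mid) < target:
            lo = mid
        else:
            hi = mid
    return float(0.5 * (lo + hi))


def _cox_loglik_offset(beta, times, events, X, offset, ties):
    """Partial likelihood with a fixed offset added to the linear predictor."""
    Xa = np.column_stack([X, offset]) if X.size else offset[:, None]
    ba = np.append(beta, 1.0) if X.size else np.array([1.0])
    ll, g, h = cox_loglik(ba, times, events, Xa, ties)
    if X.size:
        p = X.shape[1]
        return ll, g[:p], h[:p, :p]
    return ll, np.array([]), np.zeros((0, 0))


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

def harrell_c(times, events, scores) -> float:
    """Harrell's concordance index for a risk-oriented score.

    Usable pairs under right censoring: (i, j) with ``t_i < t_j`` and subject
    i dead, or ``t_i == t_j`` with i dead and j censored.  A pair is
    concordant when the earlier death has the higher score; score ties count
    one half.
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    s = np.asarray(scores, dtype=float)
    if not (t.shape == d.shape == s.shape):
        raise ValidationError("harrell_c: input lengths differ")
    ti, tj = t[:, None], t[None, :]
    di = d[:, None].astype(bool)
    dj = d[None, :].astype(bool)
    usable = (di & (ti < tj)) | (di & ~dj & (ti == tj))
    n_usable = int(usable.sum())
    if n_usable == 0:
        raise ValidationError("harrell_c: no comparable pairs")
    si, sj = s[:, None], s[None, :]
    concordant = usable & (si > sj)
    tied = usable & (si == sj)
    return float((concordant.sum() + 0.5 * tied.sum()) / n_usable)


# ---------------------------------------------------------------------------
# Binary AUC and DeLong
# ---------------------------------------------------------------------------

@dataclass
class AUCResult:
    """ROC AUC with DeLong structural-component variance."""

    auc: float
    delong_variance: float
    n_pos: int
    n_neg: int
    _v10: np.ndarray | None = None
    _v01: np.ndarray | None = None


def binary_auc(labels, scores) -> AUCResult:
    """AUC of a risk score against a binary label (Mann-Whitney identity;
    midranks handle score ties)."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValidationError("binary_auc: input lengths differ")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValidationError("binary_auc: labels must be 0/1")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("binary_auc: both classes must be present")
    pos = s[y == 1]
    neg = s[y == 0]
    tz = sps.rankdata(np.concatenate([pos, neg]))
    tpos = sps.rankdata(pos)
    tneg = sps.rankdata(neg)
    v10 = (tz[:n1] - tpos) / n0
    v01 = 1.0 - (tz[n1:] - tneg) / n1
    auc = float((tz[:n1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))
    var = 0.0
    if n1 > 1:
        var += float(np.var(v10, ddof=1)) / n1
    if n0 > 1:
        var += float(np.var(v01, ddof=1)) / n0
    return AUCResult(auc=auc, delong_variance=var, n_pos=n1, n_neg=n0, _v10=v10, _v01=v01)


def delong_test(a: AUCResult, b: AUCResult, paired: bool = True) -> TestResult:
    """DeLong z-test for the difference of two AUCs.

    For paired comparisons both AUCs must come from the same subjects in the
    same order; the covariance of the structural components is then used.
    """
    if a._v10 is None or b._v10 is None:
        raise ValidationError("delong_test: AUCResult lacks structural components")
    delta = a.auc - b.auc
    if paired:
        if a.n_pos != b.n_pos or a.n_neg != b.n_neg:
            raise ValidationError("delong_test: paired AUCs need identical subjects")
        var = 0.0
        if a.n_pos > 1:
            var += float(np.var(a._v10 - b._v10, ddof=1)) / a.n_pos
        if a.n_neg > 1:
            var += float(np.var(a._v01 - b._v01, ddof=1)) / a.n_neg
    else:
        var = a.delong_variance + b.delong_variance
    if var <= 0.0:
        z = 0.0 if delta == 0.0 else np.inf * np.sign(delta)
    else:
        z = delta / np.sqrt(var)
    p = 1.0 if not np.isfinite(z) and delta == 0 else float(2.0 * sps.norm.sf(abs(z)))
    name = "delong_paired" if paired else "delong_unpaired"
    return TestResult(statistic=float(z), p_value=min(p, 1.0), name=name)


# ---------------------------------------------------------------------------
# Proportional hazards check (Grambsch-Therneau score test)
# ---------------------------------------------------------------------------

def check_ph(fit: CoxFit, transform: str = "km") -> list[TestResult]:
    """Score test for non-proportional hazards per covariate.

    Correlates scaled Schoenfeld residuals with a transform of event time
    (default: the Kaplan-Meier transform ``1 - S(t)``); under proportional
    hazards the correlation is zero and the statistic is chi-square(1).
    """
    if fit._times is None:
        raise ValidationError("check_ph: fit does not carry its data")
    t = fit._times
    d = fit._events
    X = fit._X
    if int(d.sum()) < 3:
        raise ValidationError("check_ph: fewer than 3 events")
    order = np.argsort(t, kind="stable")
    t, d, Xs = t[order], d[order], X[order]
    r = np.exp(Xs @ fit.beta - (Xs @ fit.beta).max())
    S0 = np.cumsum(r[::-1])[::-1]
    S1 = np.cumsum((r[:, None] * Xs)[::-1], axis=0)[::-1]
    ev = np.flatnonzero(d == 1)
    # risk set of each event = suffix from the first index sharing its time
    starts = np.searchsorted(t, t[ev], side="left")
    xbar = S1[starts] / S0[starts][:, None]
    resid = Xs[ev] - xbar  # Schoenfeld residuals (Breslow form), one per death

    if transform == "km":
        km = km_fit(t, d)
        g = np.array([1.0 - km.survival_at(ti) for ti in t[ev]])
    elif transform == "rank":
        g = sps.rankdata(t[ev]).astype(float)
    elif transform == "identity":
        g = t[ev].astype(float)
    else:
        raise ValidationError(f"unknown time transform {transform!r}")
    gc = g - g.mean()
    m = int(d.sum())
    inv_info = fit.cov  # (sum of per-event covariance)^-1
    scaled = m * resid @ inv_info
    denom_g = float((gc**2).sum())
    out = []
    for j, name in enumerate(fit.names):
        u = float(gc @ scaled[:, j])
        var = m * inv_info[j, j] * denom_g
        stat = 0.0 if var <= 0 else u * u / var
        out.append(
            TestResult(
                statistic=float(stat),
                p_value=float(sps.chi2.sf(stat, 1)),
                name=f"ph_test[{name}]",
                df=1,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Simple group comparisons
# ---------------------------------------------------------------------------

def compare_groups(values, groups, kind: str) -> TestResult:
    """Two-sided group-comparison tests used for cohort tables.

    ``mann_whitney`` / ``kruskal`` compare a continuous variable across 2 / k
    groups; ``chisq`` / ``fisher`` compare two categorical variables (fisher
    restricted to 2x2 tables).
    """
    v = np.asarray(values)
    g = np.asarray(groups)
    if v.shape != g.shape:
        raise ValidationError("compare_groups: input lengths differ")
    labels = pd.unique(pd.Series(g))
    if kind == "mann_whitney":
        if len(labels) != 2:
            raise ValidationError("mann_whitney needs exactly two groups")
        a = v[g == labels[0]].astype(float)
        b = v[g == labels[1]].astype(float)
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                          name="mann_whitney")
    if kind == "kruskal":
        samples = [v[g == lab].astype(float) for lab in labels]
        res = sps.kruskal(*samples)
        return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                          name="kruskal", df=len(labels) - 1)
    if kind in ("chisq", "fisher"):
        table = pd.crosstab(pd.Series(v), pd.Series(g)).to_numpy()
        if kind == "fisher":
            if table.shape != (2, 2):
                raise ValidationError("fisher is restricted to 2x2 tables")
            _, p = sps.fisher_exact(table, alternative="two-sided")
            return TestResult(statistic=float("nan"), p_value=float(p), name="fisher")
        chi2, p, df, expected = sps.chi2_contingency(table)
        if (expected < 1).any():
            warnings.warn(
                "chi-square with an expected cell count below 1; "
                "consider fisher for 2x2 tables",
                stacklevel=2,
            )
        return TestResult(statistic=float(chi2), p_value=float(p), name="chisq", df=int(df))
    raise ValidationError(f"unknown test kind {kind!r}")
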