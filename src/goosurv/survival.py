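"""Native survival layer: Kaplan-Meier, log-rank, Cox proportional hazards
(Efron ties), Schoenfeld diagnostics, VIF screening and AIC model selection.

The Kaplan-Meier estimator is the product-limit form

    S(t) = prod_{i: t_i <= t} (1 - d_i / n_i)

over event times t_i with d_i events among n_i at risk. Group curves are
compared with the log-rank test. The Cox model h(t|X) = h0(t) exp(beta'X) is
fit by Newton-Raphson on the Efron partial likelihood; hazard ratios are
reported with Wald confidence intervals. Covariates are z-scored before
fitting by default (coefficients are reported on both scales). The
proportional-hazards assumption is checked by correlating scaled Schoenfeld
residuals with Kaplan-Meier-scaled time. Collinearity is screened by
iteratively dropping covariates with variance inflation factor above 5, and
model selection enumerates all covariate subsets, retains the AIC set with
delta AIC < 2, and picks the most parsimonious member.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KMCurve", "km_fit", "logrank_test", "CoxFit", "cox_fit",
    "schoenfeld_test", "vif_screen", "ModelSelection", "model_select",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge; carries the iteration trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass
class KMCurve:
    times: np.ndarray        # distinct event times
    n_risk: np.ndarray       # at risk just before each event time
    d: np.ndarray            # events at each time
    survival: np.ndarray     # S(t) just after each event time
    median: float | None     # first t with S(t) <= 0.5, None if never reached
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        k = int(np.searchsorted(self.times, t, side="right"))
        return 1.0 if k == 0 else float(self.survival[k - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "n_risk": self.n_risk, "n_events": self.d, "survival": self.survival}
        )


def _km_single(durations: np.ndarray, events: np.ndarray) -> KMCurve:
    if len(durations) == 0:
        raise ValueError("empty group in Kaplan-Meier fit")
    if (durations <= 0).any():
        raise ValueError("survival times must be positive")
    ut = np.unique(durations[events == 1])
    n_risk = np.array([(durations >= t).sum() for t in ut], dtype=np.int64)
    d = np.array([((durations == t) & (events == 1)).sum() for t in ut], dtype=np.int64)
    surv = np.cumprod(1.0 - d / n_risk) if len(ut) else np.array([])
    median = None
    hit = np.flatnonzero(surv <= 0.5 + 1e-12)
    if hit.size:
        median = float(ut[hit[0]])
    return KMCurve(times=ut, n_risk=n_risk, d=d, survival=surv, median=median,
                   n=len(durations), n_events=int(events.sum()))


def km_fit(durations, events, groups=None):
    """Product-limit estimate with right-censoring.

    With ``groups`` returns {group label: KMCurve}, else a single KMCurve.
    """
    t = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=int)
    if groups is None:
        return _km_single(t, e)
    g = np.asarray(groups)
    return {lbl: _km_single(t[g == lbl], e[g == lbl]) for lbl in pd.unique(g)}


def logrank_test(durations, events, groups):
    """Log-rank test across >= 2 groups: returns (chi2, df, p)."""
    t = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    labels = pd.unique(g)
    G = len(labels)
    if G < 2:
        raise ValueError("log-rank test needs >= 2 groups")
    if e.sum() == 0:
        raise ValueError("log-rank test undefined with zero events")
    ut = np.unique(t[e == 1])
    O = np.zeros(G)
    E = np.zeros(G)
    V = np.zeros((G, G))
    for u in ut:
        at_risk = t >= u
        n = at_risk.sum()
        d = ((t == u) & (e == 1)).sum()
        ng = np.array([(at_risk & (g == lbl)).sum() for lbl in labels], dtype=float)
        dg = np.array([((t == u) & (e == 1) & (g == lbl)).sum() for lbl in labels], dtype=float)
        O += dg
        E += d * ng / n
        if n > 1:
            p = ng / n
            V += d * (n - d) / (n - 1) * (np.diag(p) - np.outer(p, p))
    diff = (O - E)[:-1]
    chi2 = float(diff @ np.linalg.pinv(V[:-1, :-1]) @ diff)
    df = G - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron partial likelihood)
# ---------------------------------------------------------------------------

def _efron_quantities(beta, X, t, e):
    """(log partial likelihood, gradient, information) with Efron ties.

    Rows must be sorted ascending by t.
    """
    n, k = X.shape
    eta = X @ beta if k else np.zeros(n)
    eta = eta - eta.max() if n else eta  # guard overflow; shifts cancel
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = X[:, :, None] * X[:, None, :] * w[:, None, None]
    # suffix (risk-set) sums
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]
    loglik = 0.0
    grad = np.zeros(k)
    info = np.zeros((k, k))
    i = 0
    # Extreme trial betas (rejected by step-halving) can underflow every
    # risk-set weight to 0; -inf/nan quantities are handled by the caller.
    with np.errstate(divide="ignore", invalid="ignore"):
        while i < n:
            j = i
            while j + 1 < n and t[j + 1] == t[i]:
                j += 1
            D = np.arange(i, j + 1)[e[i : j + 1] == 1]
            d = len(D)
            if d:
                s0t = w[D].sum()
                s1t = wx[D].sum(axis=0)
                s2t = wxx[D].sum(axis=0)
                frac = (np.arange(d) / d)[:, None]
                denom = S0[i] - frac[:, 0] * s0t                       # (d,)
                s1_l = S1[i][None, :] - frac * s1t[None, :]            # (d, k)
                xbar = s1_l / denom[:, None] if k else s1_l
                loglik += eta[D].sum() - np.log(denom).sum()
                if k:
                    s2_l = S2[i][None, :, :] - frac[:, :, None] * s2t[None, :, :]
                    grad += X[D].sum(axis=0) - xbar.sum(axis=0)
                    info += (s2_l / denom[:, None, None]).sum(axis=0) - np.einsum(
                        "li,lj->ij", xbar, xbar
                    )
            i = j + 1
    return loglik, grad, info


def _newton_cox(X, t, e, max_iter=100, tol=1e-9):
    k = X.shape[1]
    beta = np.zeros(k)
    loglik, grad, info = _efron_quantities(beta, X, t, e)
    trace = [(0, loglik, float(np.linalg.norm(grad)))]
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        alpha = 1.0
        for _ in range(30):
            new = beta + alpha * step
            ll_new, g_new, i_new = _efron_quantities(new, X, t, e)
            if ll_new >= loglik - 1e-12:
                break
            alpha /= 2.0
        beta, loglik, grad, info = new, ll_new, g_new, i_new
        trace.append((it, loglik, float(np.linalg.norm(grad))))
        if np.linalg.norm(grad) < tol:
            return beta, loglik, grad, info, trace
    raise ConvergenceError(f"Cox Newton-Raphson did not converge in {max_iter} iterations", trace)


def _concordance(t, e, risk):
    """Harrell's c: fraction of comparable pairs correctly risk-ordered."""
    conc = ties = comp = 0.0
    for i in np.flatnonzero(e == 1):
        later = (t > t[i]) | ((t == t[i]) & (e == 0))
        comp += later.sum()
        conc += (risk[later] < risk[i]).sum()
        ties += (risk[later] == risk[i]).sum()
    if comp == 0:
        return np.nan
    return float((conc + 0.5 * ties) / comp)


@dataclass
class CoxFit:
    covariates: list[str]
    beta: np.ndarray            # on the fitted (standardized by default) scale
    se: np.ndarray
    hr: np.ndarray
    hr_ci_low: np.ndarray
    hr_ci_high: np.ndarray
    p: np.ndarray
    beta_raw: np.ndarray        # per-original-unit coefficients
    se_raw: np.ndarray
    log_partial_lik: float
    log_partial_lik_null: float
    aic: float
    concordance: float
    global_score_chi2: float
    global_score_p: float
    n: int
    n_events: int
    standardized: bool
    means: np.ndarray
    sds: np.ndarray
    cov: np.ndarray = field(repr=False, default=None)
    schoenfeld_p: dict | None = None
    flags: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.beta,
                "se": self.se,
                "HR": self.hr,
                "HR 95% CI low": self.hr_ci_low,
                "HR 95% CI high": self.hr_ci_high,
                "p": self.p,
            },
            index=self.covariates,
        )


def cox_fit(
    df: pd.DataFrame,
    covariates,
    duration_col: str = "survival_days",
    event_col: str = "event",
    ties: str = "efron",
    standardize: bool = True,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by maximizing the Efron partial
    likelihood with Newton-Raphson.

    Covariates are z-scored by default; coefficients on the original scale
    are also reported (``beta_raw``). A coefficient walking past |beta| > 15
    on the standardized scale is flagged as possible separation.
    """
    if ties != "efron":
        raise ValueError("only Efron tie handling is implemented")
    covariates = list(covariates)
    t = df[duration_col].to_numpy(dtype=float)
    e = df[event_col].to_numpy(dtype=int)
    X = df[covariates].to_numpy(dtype=float) if covariates else np.empty((len(df), 0))
    if np.isnan(X).any() or np.isnan(t).any():
        raise ValueError("missing values in Cox inputs; screen covariates first")
    sds = X.std(axis=0, ddof=1) if covariates else np.array([])
    means = X.mean(axis=0) if covariates else np.array([])
    if covariates and (sds == 0).any():
        bad = [c for c, s in zip(covariates, sds) if s == 0]
        raise ValueError(f"constant covariate(s): {', '.join(bad)}")
    Xs = (X - means) / sds if (standardize and covariates) else X

    order = np.argsort(t, kind="stable")
    t_s, e_s, X_s = t[order], e[order], Xs[order]

    ll0, g0, i0 = _efron_quantities(np.zeros(X_s.shape[1]), X_s, t_s, e_s)
    if covariates:
        beta, loglik, grad, info, trace = _newton_cox(X_s, t_s, e_s, max_iter, tol)
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
        chi2 = float(g0 @ np.linalg.solve(i0, g0))
        p_score = float(stats.chi2.sf(chi2, len(covariates)))
    else:
        beta = np.array([])
        loglik = ll0
        cov = np.zeros((0, 0))
        se = np.array([])
        chi2, p_score = 0.0, 1.0

    zval = beta / se if covariates else np.array([])
    pvals = 2.0 * stats.norm.sf(np.abs(zval)) if covariates else np.array([])
    ci = 1.959963984540054
    scale = sds if (standardize and covariates) else np.ones(len(covariates))
    flags = {}
    if covariates:
        # monotone likelihood (separation) shows up either as a runaway
        # coefficient or as a flat ridge with an absurd standard error
        suspect = (np.abs(beta) > 15) | (se > 100.0)
        if suspect.any():
            flags["possible_separation"] = [c for c, s in zip(covariates, suspect) if s]
    risk = X_s @ beta if covariates else np.zeros(len(t_s))
    with np.errstate(over="ignore"):
        hr = np.exp(beta)
        hr_lo = np.exp(beta - ci * se)
        hr_hi = np.exp(beta + ci * se)
    return CoxFit(
        covariates=covariates,
        beta=beta,
        se=se,
        hr=hr,
        hr_ci_low=hr_lo,
        hr_ci_high=hr_hi,
        p=pvals,
        beta_raw=beta / scale if covariates else beta,
        se_raw=se / scale if covariates else se,
        log_partial_lik=float(loglik),
        log_partial_lik_null=float(ll0),
        aic=float(-2.0 * loglik + 2.0 * len(covariates)),
        concordance=_concordance(t_s, e_s, risk),
        global_score_chi2=chi2,
        global_score_p=p_score,
        n=len(t),
        n_events=int(e.sum()),
        standardized=standardize,
        means=means,
        sds=sds,
        cov=cov,
        flags=flags,
    )


def _schoenfeld_residuals(fit: CoxFit, df, duration_col, event_col):
    """Efron Schoenfeld residuals (one per event) and their event times."""
    t = df[duration_col].to_numpy(dtype=float)
    e = df[event_col].to_numpy(dtype=int)
    X = df[fit.covariates].to_numpy(dtype=float)
    if fit.standardized:
        X = (X - fit.means) / fit.sds
    order = np.argsort(t, kind="stable")
    t, e, X = t[order], e[order], X[order]
    w = np.exp(X @ fit.beta)
    wx = w[:, None] * X
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    times, resids = [], []
    n = len(t)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        D = np.arange(i, j + 1)[e[i : j + 1] == 1]
        d = len(D)
        if d:
            s0t = w[D].sum()
            s1t = wx[D].sum(axis=0)
            frac = (np.arange(d) / d)[:, None]
            xbar_l = (S1[i][None, :] - frac * s1t[None, :]) / (S0[i] - frac[:, 0] * s0t)[:, None]
            xbar = xbar_l.mean(axis=0)
            for idx in D:
                times.append(t[idx])
                resids.append(X[idx] - xbar)
        i = j + 1
    return np.asarray(times), np.asarray(resids)


def schoenfeld_test(fit: CoxFit, df, duration_col="survival_days", event_col="event") -> dict:
    """Proportional-hazards check per covariate.

    Scaled Schoenfeld residuals are correlated (Pearson) against the
    Kaplan-Meier transform of event time, g(t) = 1 - S_KM(t); the returned
    p-values come from the corresponding t-test. A time-varying effect shows
    up as a trend in the residuals and a small p.
    """
    if not fit.covariates:
        return {}
    times, resid = _schoenfeld_residuals(fit, df, duration_col, event_col)
    m = len(times)
    if m < 3:
        raise ValueError("Schoenfeld test needs >= 3 events")
    scaled = fit.beta[None, :] + m * (resid @ fit.cov.T)
    km = km_fit(df[duration_col], df[event_col])
    g = np.array([1.0 - km.survival_at(u) for u in times])
    out = {}
    for j, name in enumerate(fit.covariates):
        if np.ptp(g) == 0 or np.ptp(scaled[:, j]) == 0:
            out[name] = 1.0
            continue
        r = float(np.corrcoef(g, scaled[:, j])[0, 1])
        tstat = r * np.sqrt((m - 2) / max(1e-12, 1.0 - r * r))
        out[name] = float(2.0 * stats.t.sf(abs(tstat), m - 2))
    fit.schoenfeld_p = out
    return out


# ---------------------------------------------------------------------------
# collinearity screening and model selection
# ---------------------------------------------------------------------------

def _vif_one(X: np.ndarray, j: int) -> float:
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    A = np.column_stack([np.ones(len(y)), others])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    sst = ((y - y.mean()) ** 2).sum()
    if sst == 0:
        return np.inf
    r2 = 1.0 - (resid**2).sum() / sst
    return np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)


def vif_screen(df: pd.DataFrame, covariates, threshold: float = 5.0):
    """Iteratively drop the highest-VIF covariate until all VIF <= threshold.

    Returns (retained, dropped) where dropped is a list of (name, vif) in
    drop order. Ties (e.g. perfect collinearity) are broken alphabetically.
    """
    remaining = sorted(covariates)
    dropped: list[tuple[str, float]] = []
    while len(remaining) > 1:
        X = df[remaining].to_numpy(dtype=float)
        vifs = np.array([_vif_one(X, j) for j in range(len(remaining))])
        worst = float(np.nanmax(vifs))
        if worst <= threshold:
            break
        cand = [remaining[j] for j in range(len(remaining)) if vifs[j] == worst]
        drop = sorted(cand)[0]
        dropped.append((drop, worst))
        remaining.remove(drop)
    # restore caller's ordering for the retained set
    retained = [c for c in covariates if c in remaining]
    return retained, dropped


@dataclass
class ModelSelection:
    table: pd.DataFrame                 # all subsets ranked by AIC
    retained: list[tuple]               # covariate tuples with delta AIC < 2
    final_covariates: tuple
    final: CoxFit | None                # None for the empty (null) model
    null_aic: float
    stepwise_path: list[dict]


def _forward_stepwise(df, candidates, duration_col, event_col, alpha=0.05):
    chosen: list[str] = []
    path: list[dict] = []
    current_ll = cox_fit(df, [], duration_col, event_col).log_partial_lik
    while True:
        best = None
        for c in candidates:
            if c in chosen:
                continue
            try:
                fit = cox_fit(df, chosen + [c], duration_col, event_col)
            except (ConvergenceError, ValueError):
                continue
            lr = 2.0 * (fit.log_partial_lik - current_ll)
            p = float(stats.chi2.sf(lr, 1))
            if best is None or p < best[1]:
                best = (c, p, fit)
        if best is None or best[1] >= alpha:
            break
        chosen.append(best[0])
        current_ll = best[2].log_partial_lik
        path.append({"added": best[0], "lr_p": best[1], "aic": best[2].aic})
    return path


def model_select(
    df: pd.DataFrame,
    candidates,
    duration_col: str = "survival_days",
    event_col: str = "event",
    delta_aic: float = 2.0,
) -> ModelSelection:
    """All-subsets Cox regression ranked by AIC.

    Every subset of the candidates (including the empty/null model) is fit;
    models within ``delta_aic`` of the best are retained, and the final model
    is the most parsimonious of those (ties broken by lower AIC). A forward
    stepwise path (likelihood-ratio entry at p < 0.05) is also reported as a
    diagnostic.
    """
    candidates = list(candidates)
    if len(candidates) > 15:
        raise ValueError("all-subsets enumeration limited to 15 candidates")
    rows = []
    fits: dict[tuple, CoxFit] = {}
    null_aic = None
    for r in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, r):
            try:
                fit = cox_fit(df, list(subset), duration_col, event_col)
            except (ConvergenceError, ValueError):
                continue
            if fit.flags.get("possible_separation"):
                continue
            fits[subset] = fit
            rows.append({"covariates": subset, "k": r, "aic": fit.aic})
            if r == 0:
                null_aic = fit.aic
    if not rows:
        raise ValueError("no fittable covariate subset")
    table = pd.DataFrame(rows).sort_values(["aic", "k"], kind="stable").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].iloc[0]
    retained_df = table[table["delta_aic"] < delta_aic]
    retained = list(retained_df["covariates"])
    final_row = retained_df.sort_values(["k", "aic"], kind="stable").iloc[0]
    final_cov = tuple(final_row["covariates"])
    final = fits[final_cov] if final_cov else None
    return ModelSelection(
        table=table,
        retained=retained,
        final_covariates=final_cov,
        final=final,
        null_aic=float(null_aic) if null_aic is not None else float("nan"),
        stepwise_path=_forward_stepwise(df, candidates, duration_col, event_col),
    )
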