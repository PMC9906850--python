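"""Cox proportional-hazards survival analysis by partial likelihood.

The survival table carries one record per individual (duration in days
from first tracked day, event = 1 dead / 0 censored) with its movement
covariates (mean max-displacement, mean rIIV, sex, age group, tracking
duration).  Individuals that cross the juvenile-to-adult boundary while
tracked contribute two independent records: the juvenile span (censored
at the first birthday unless death occurred before it) and the adult
span from transition to fate.

The fitter maximizes the Breslow (optionally Efron) log partial
likelihood by Newton-Raphson with step-halving; standard errors come
from the inverse observed information, hazard ratios are exp(beta) with
Wald 95% intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm


@dataclass
class CoxFit:
    coef: pd.Series
    se: pd.Series
    loglik: float
    n: int
    n_events: int
    ties: str
    converged: bool = True
    flagged: list[str] = field(default_factory=list)

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.coef)


def build_survival_table(
    cohort: pd.DataFrame,
    fates: pd.DataFrame,
    index_summary: pd.DataFrame | None = None,
    riiv: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble survival records, splitting age-transition individuals.

    ``cohort`` needs individual, sex, hatch_date, track_start;
    ``fates`` needs individual, duration_days, event.  Per-individual
    covariates (mean max-displacement from ``index_summary``, overall
    rIIV from ``riiv``) are attached when given; individuals without a
    rIIV estimate are dropped with a warning.
    """
    fates = fates.set_index("individual")
    mean_disp = None
    if index_summary is not None:
        mean_disp = index_summary.groupby("individual")["mean_max_disp_km"].mean()
    riiv_map = None
    if riiv is not None:
        overall = riiv[riiv["scope"] == "overall"] if "scope" in riiv else riiv
        riiv_map = overall.set_index("individual")["riiv_km"]

    rows = []
    dropped = []
    for rec in cohort.itertuples(index=False):
        ind = rec.individual
        if ind not in fates.index:
            continue
        if riiv_map is not None and ind not in riiv_map.index:
            dropped.append(ind)
            continue
        duration = float(fates.loc[ind, "duration_days"])
        event = int(fates.loc[ind, "event"])
        hatch = rec.hatch_date
        start = rec.track_start
        days_to_transition = 365 - (start - hatch).days  # <0 if adult at start
        common = {
            "individual": ind,
            "sex": rec.sex,
            "mean_max_disp_km": float(mean_disp.get(ind, np.nan)) if mean_disp is not None else np.nan,
            "riiv_km": float(riiv_map.get(ind, np.nan)) if riiv_map is not None else np.nan,
        }
        if days_to_transition <= 0:
            rows.append({**common, "record": f"{ind}/adult", "age_group": "adult",
                         "duration_days": duration, "event": event})
        elif duration <= days_to_transition:
            rows.append({**common, "record": f"{ind}/juvenile", "age_group": "juvenile",
                         "duration_days": duration, "event": event})
        else:
            rows.append({**common, "record": f"{ind}/juvenile", "age_group": "juvenile",
                         "duration_days": float(days_to_transition), "event": 0})
            rows.append({**common, "record": f"{ind}/adult", "age_group": "adult",
                         "duration_days": duration - days_to_transition, "event": event})
    if dropped:
        warnings.warn(f"{len(dropped)} individuals without rIIV dropped from survival table")
    out = pd.DataFrame(rows)
    if len(out):
        out["track_days"] = out["duration_days"]
    return out


def _prepare(records: pd.DataFrame, covariates: list[str], standardize: bool):
    df = records.copy()
    Xcols = []
    for c in covariates:
        if df[c].dtype == object or str(df[c].dtype) == "category":
            dummies = pd.get_dummies(df[c].astype(str), prefix=c, drop_first=True, dtype=float)
            for dc in dummies.columns:
                df[dc] = dummies[dc]
                Xcols.append(dc)
        else:
            df[c] = df[c].astype(float)
            Xcols.append(c)
    X = df[Xcols].to_numpy(float)
    const = X.std(axis=0) == 0
    if const.any():
        bad = [Xcols[i] for i in np.flatnonzero(const)]
        raise ValueError(f"constant covariate(s): {', '.join(bad)}")
    if standardize:
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    return X, Xcols, df


def _breslow_loglik_grad_hess(beta, t, d, X):
    """Log partial likelihood with Breslow ties, score and information."""
    order = np.argsort(-t, kind="mergesort")  # decreasing time
    t, d, X = t[order], d[order], X[order]
    eta = X @ beta
    w = np.exp(eta)
    n, p = X.shape
    cw = np.cumsum(w)
    cwx = np.cumsum(X * w[:, None], axis=0)
    cwxx = np.cumsum(np.einsum("ij,ik->ijk", X, X) * w[:, None, None], axis=0)
    # risk set of an event at time t includes all with time >= t; with rows
    # in decreasing time order that is the cumulative sum up to the LAST
    # index of the tied block
    block_last = np.empty(n, dtype=int)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        block_last[i : j + 1] = j
        i = j + 1
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    ev = np.flatnonzero(d == 1)
    for i in ev:
        k = block_last[i]
        S0 = cw[k]
        S1 = cwx[k]
        S2 = cwxx[k]
        ll += eta[i] - np.log(S0)
        grad += X[i] - S1 / S0
        hess -= S2 / S0 - np.outer(S1, S1) / S0**2
    return ll, grad, hess


def _efron_loglik_grad_hess(beta, t, d, X):
    order = np.argsort(-t, kind="mergesort")
    t, d, X = t[order], d[order], X[order]
    eta = X @ beta
    w = np.exp(eta)
    n, p = X.shape
    cw = np.cumsum(w)
    cwx = np.cumsum(X * w[:, None], axis=0)
    cwxx = np.cumsum(np.einsum("ij,ik->ijk", X, X) * w[:, None, None], axis=0)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        ev = [k for k in range(i, j + 1) if d[k] == 1]
        m = len(ev)
        if m:
            S0 = cw[j]
            S1 = cwx[j]
            S2 = cwxx[j]
            d0 = w[ev].sum()
            d1 = (X[ev] * w[ev, None]).sum(axis=0)
            d2 = np.einsum("ij,ik->jk", X[ev] * w[ev, None], X[ev])
            for r in range(m):
                f = r / m
                R0 = S0 - f * d0
                R1 = S1 - f * d1
                R2 = S2 - f * d2
                ll += -np.log(R0)
                grad += -R1 / R0
                hess -= R2 / R0 - np.outer(R1, R1) / R0**2
            ll += eta[ev].sum()
            grad += X[ev].sum(axis=0)
        i = j + 1
    return ll, grad, hess


def fit_cox(
    records: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "duration_days",
    event_col: str = "event",
    ties: str = "breslow",
    standardize: bool = False,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> CoxFit:
    """Newton-Raphson maximization of the Cox log partial likelihood."""
    X, names, df = _prepare(records, covariates, standardize)
    t = df[duration_col].to_numpy(float)
    d = df[event_col].to_numpy(int)
    if d.sum() < 1:
        raise ValueError("need at least one event")
    fun = _efron_loglik_grad_hess if ties == "efron" else _breslow_loglik_grad_hess
    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = fun(beta, t, d, X)
    converged = False
    flagged: list[str] = []
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
        scale = 1.0
        for _h in range(30):
            new = beta + scale * step
            ll_new, grad_new, hess_new = fun(new, t, d, X)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2
        rel = abs(ll_new - ll) / (abs(ll) + 1e-12)
        beta, ll, grad, hess = new, ll_new, grad_new, hess_new
        if rel < tol:
            converged = True
            break
    big = np.abs(beta) > 50
    if big.any():
        for i in np.flatnonzero(big):
            flagged.append(names[i])
            beta[i] = np.sign(beta[i]) * 50
        warnings.warn(
            f"monotone likelihood suspected; coefficients capped: {flagged}"
        )
        ll, grad, hess = fun(beta, t, d, X)
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    if converged and np.max(np.abs(grad)) > 1e-4 and not flagged:
        warnings.warn("score not fully zero at optimum")
    return CoxFit(
        coef=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        loglik=float(ll),
        n=len(t),
        n_events=int(d.sum()),
        ties=ties,
        converged=converged,
        flagged=flagged,
    )


def hazard_ratio_table(fit: CoxFit, level: float = 0.95) -> pd.DataFrame:
    """Forest-style table: HR, Wald CI and p per covariate."""
    z = norm.ppf(0.5 + level / 2)
    hr = np.exp(fit.coef)
    lo = np.exp(fit.coef - z * fit.se)
    hi = np.exp(fit.coef + z * fit.se)
    zstat = fit.coef / fit.se
    pval = 2 * norm.sf(np.abs(zstat))
    return pd.DataFrame(
        {
            "covariate": fit.coef.index,
            "coef": fit.coef.to_numpy(),
            "hr": hr.to_numpy(),
            "ci_low": lo.to_numpy(),
            "ci_high": hi.to_numpy(),
            "z": zstat.to_numpy(),
            "p": pval,
        }
    ).reset_index(drop=True)


def brute_force_cox(t, d, X, grid=None):
    """Grid maximization of the Breslow partial likelihood (oracle, 1-2 covariates)."""
    t = np.asarray(t, float)
    d = np.asarray(d, int)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    if grid is None:
        grid = np.linspace(-5, 5, 2001)
    if X.shape[1] == 1:
        lls = [
            _breslow_loglik_grad_hess(np.array([b]), t, d, X)[0] for b in grid
        ]
        i = int(np.argmax(lls))
        # local quadratic refinement
        lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
        fine = np.linspace(lo, hi, 2001)
        lls_f = [
            _breslow_loglik_grad_hess(np.array([b]), t, d, X)[0] for b in fine
        ]
        return np.array([fine[int(np.argmax(lls_f))]])
    raise NotImplementedError("brute force supports a single covariate")
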