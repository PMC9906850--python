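"""Variance partitioning: repeatability (Rp), CVi, and bootstrap intervals.

The engine is a one-random-intercept linear mixed model estimated by
(restricted) maximum likelihood, profiled over the variance ratio
theta = var_among / var_within: for a fixed theta the GLS fixed effects
and the residual variance have closed forms, so the criterion reduces to
a smooth one-dimensional optimization.  On balanced designs the REML
estimates coincide with the classical one-way ANOVA moment estimators.

Rp = var_among / (var_among + var_within) is the intraclass correlation
sensu Nakagawa & Schielzeth; CVi = sqrt(var_among) / trait mean is the
coefficient of among-individual variation.  Confidence intervals come
from a parametric bootstrap (simulate from the fitted model, refit,
percentile interval).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar


@dataclass
class VarianceComponents:
    var_among: float
    var_within: float
    grand_mean: float
    method: str = "REML"
    beta: np.ndarray | None = None
    beta_cov: np.ndarray | None = None
    loglik: float | None = None
    n_obs: int = 0
    n_groups: int = 0
    singleton_only: bool = False


@dataclass
class RepeatabilityEstimate:
    rp: float
    cvi: float
    rp_ci: tuple[float, float]
    cvi_ci: tuple[float, float]
    n_individuals: int
    n_obs: int
    n_boot: int
    seed: int


def _group_stats(groups: np.ndarray, y: np.ndarray, X: np.ndarray):
    uniq, idx = np.unique(groups, return_inverse=True)
    n_g = np.bincount(idx).astype(float)
    return uniq, idx, n_g


def _profiled_neg2ll(
    theta: float,
    y: np.ndarray,
    X: np.ndarray,
    idx: np.ndarray,
    n_g: np.ndarray,
    reml: bool,
):
    """-2 log (RE)ML profiled over beta and sigma^2, at variance ratio theta.

    V = sigma^2 (I + theta Z Z'); per group (I + theta J)^-1 =
    I - theta/(1 + n_g theta) J, so all GLS quantities reduce to group sums.
    """
    n, p = X.shape
    c = theta / (1.0 + n_g * theta)           # per group
    # group sums
    sy = np.bincount(idx, weights=y)
    sX = np.column_stack([np.bincount(idx, weights=X[:, j]) for j in range(p)])
    XtX = X.T @ X - (sX * c[:, None]).T @ sX
    Xty = X.T @ y - sX.T @ (c * sy)
    yty = y @ y - np.sum(c * sy**2)
    beta = np.linalg.solve(XtX, Xty)
    rss = yty - 2 * beta @ Xty + beta @ XtX @ beta
    logdetV = np.sum(np.log1p(n_g * theta))
    if reml:
        dof = n - p
        sigma2 = rss / dof
        # log|X'V0^-1 X| depends on theta and must stay in the criterion
        sign, logdetXVX = np.linalg.slogdet(XtX)
        crit = dof * np.log(2 * np.pi * sigma2) + logdetV + logdetXVX + dof
    else:
        sigma2 = rss / n
        crit = n * np.log(2 * np.pi * sigma2) + logdetV + n
    return crit, beta, sigma2, XtX


def fit_lmm(
    obs: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "individual",
    fixed: list[str] | None = None,
    reml: bool = True,
) -> VarianceComponents:
    """One-random-intercept LMM via profiled (RE)ML on the variance ratio."""
    y = obs[value_col].to_numpy(float)
    groups = obs[group_col].to_numpy()
    if fixed:
        dummies = pd.get_dummies(
            obs[fixed].astype({c: str for c in fixed if obs[c].dtype == object}),
            drop_first=True,
            dtype=float,
        )
        X = np.column_stack([np.ones(len(y)), dummies.to_numpy()])
    else:
        X = np.ones((len(y), 1))
    uniq, idx, n_g = _group_stats(groups, y, X)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    singleton_only = bool((n_g <= 1).all())
    if singleton_only and reml:
        warnings.warn("all groups are singletons: var_among is inestimable")

    if np.ptp(y) == 0:
        return VarianceComponents(
            0.0, 0.0, float(y.mean()), "REML" if reml else "ML",
            beta=np.array([y.mean()]), loglik=np.inf,
            n_obs=len(y), n_groups=len(uniq), singleton_only=singleton_only,
        )

    def obj(log_theta: float) -> float:
        return _profiled_neg2ll(np.exp(log_theta), y, X, idx, n_g, reml)[0]

    res = minimize_scalar(obj, bounds=(-30.0, 15.0), method="bounded",
                          options={"xatol": 1e-12})
    crit0, beta0, s2_0, _ = _profiled_neg2ll(0.0, y, X, idx, n_g, reml)
    if crit0 <= res.fun:  # boundary solution: no among-group variance
        theta = 0.0
        crit, beta, sigma2, XtX = crit0, beta0, s2_0, _profiled_neg2ll(0.0, y, X, idx, n_g, reml)[3]
    else:
        theta = float(np.exp(res.x))
        crit, beta, sigma2, XtX = _profiled_neg2ll(theta, y, X, idx, n_g, reml)
    return VarianceComponents(
        var_among=theta * sigma2,
        var_within=sigma2,
        grand_mean=float(y.mean()),
        method="REML" if reml else "ML",
        beta=beta,
        beta_cov=np.linalg.inv(XtX) * sigma2,
        loglik=-0.5 * crit,
        n_obs=len(y),
        n_groups=len(uniq),
        singleton_only=singleton_only,
    )


def fit_lmm_reml(obs, value_col="value", group_col="individual", fixed=None):
    return fit_lmm(obs, value_col, group_col, fixed, reml=True)


def anova_components(obs: pd.DataFrame, value_col="value", group_col="individual"):
    """Balanced one-way ANOVA moment estimators (oracle for balanced REML)."""
    g = obs.groupby(group_col)[value_col]
    k = g.ngroups
    m = g.size().iloc[0]
    if not (g.size() == m).all():
        raise ValueError("anova_components requires a balanced design")
    means = g.mean()
    grand = obs[value_col].mean()
    msb = m * ((means - grand) ** 2).sum() / (k - 1)
    msw = ((obs[value_col] - obs[group_col].map(means)) ** 2).sum() / (k * (m - 1))
    return max((msb - msw) / m, 0.0), msw


def repeatability(vc: VarianceComponents) -> float:
    """Among-individual share of total variance."""
    tot = vc.var_among + vc.var_within
    if tot == 0:
        return float("nan")
    return vc.var_among / tot


def cvi(vc: VarianceComponents) -> float:
    """Among-individual SD standardized by the trait mean."""
    if vc.grand_mean <= 0:
        raise ValueError("CVi requires a positive trait mean")
    return float(np.sqrt(vc.var_among) / vc.grand_mean)


def bootstrap_ci(
    obs: pd.DataFrame,
    statistic,
    n_boot: int = 1000,
    seed: int = 0,
    value_col: str = "value",
    group_col: str = "individual",
    level: float = 0.95,
) -> tuple[float, float]:
    """Parametric bootstrap percentile interval for an LMM-based statistic.

    ``statistic`` maps a VarianceComponents to a scalar (e.g. ``repeatability``
    or ``cvi``).  Datasets are simulated from the fitted model (Gaussian
    intercepts and residuals), refit, and the statistic's percentile
    interval returned.  More than 5% refit failures widens the interval to
    the min/max of successful replicates with a warning.
    """
    vc = fit_lmm_reml(obs, value_col, group_col)
    if vc.var_among == 0 and vc.var_within == 0:
        val = statistic(vc)
        if not np.isfinite(val):  # 0/0 ratio on fully degenerate data
            val = 0.0
        return (val, val)
    rng = np.random.default_rng(seed)
    groups = obs[group_col].to_numpy()
    uniq, idx = np.unique(groups, return_inverse=True)
    base = float(vc.beta[0]) if vc.beta is not None else vc.grand_mean
    vals = []
    failures = 0
    for _ in range(n_boot):
        u = rng.normal(0, np.sqrt(vc.var_among), len(uniq))
        e = rng.normal(0, np.sqrt(vc.var_within), len(groups))
        sim = pd.DataFrame({group_col: groups, value_col: base + u[idx] + e})
        try:
            vals.append(statistic(fit_lmm_reml(sim, value_col, group_col)))
        except Exception:
            failures += 1
    vals = np.array(vals)
    alpha = (1 - level) / 2
    if failures > 0.05 * n_boot:
        warnings.warn(f"{failures} bootstrap refits failed; widening interval")
        return (float(vals.min()), float(vals.max()))
    return (float(np.quantile(vals, alpha)), float(np.quantile(vals, 1 - alpha)))


def estimate_repeatability(
    obs: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "individual",
    n_boot: int = 1000,
    seed: int = 0,
) -> RepeatabilityEstimate:
    """Rp and CVi with parametric-bootstrap 95% intervals."""
    vc = fit_lmm_reml(obs, value_col, group_col)
    return RepeatabilityEstimate(
        rp=repeatability(vc),
        cvi=cvi(vc),
        rp_ci=bootstrap_ci(obs, repeatability, n_boot, seed, value_col, group_col),
        cvi_ci=bootstrap_ci(obs, cvi, n_boot, seed + 1, value_col, group_col),
        n_individuals=vc.n_groups,
        n_obs=vc.n_obs,
        n_boot=n_boot,
        seed=seed,
    )


def riiv_consistency(
    period_riiv: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> RepeatabilityEstimate:
    """Repeatability of log-rIIV across periods (is predictability itself stable?).

    Expects the period-scoped rIIV table (individual, scope, riiv_km);
    individuals present in fewer than 2 periods contribute no within-
    individual contrast but are retained for the among-individual term.
    """
    scopes = period_riiv["scope"].unique()
    if len(scopes) < 2:
        raise ValueError("rIIV consistency requires at least 2 periods")
    multi = period_riiv.groupby("individual")["scope"].transform("nunique") >= 2
    if period_riiv[multi]["individual"].nunique() < 2:
        raise ValueError("need >= 2 individuals observed in >= 2 periods")
    obs = pd.DataFrame(
        {
            "individual": period_riiv["individual"],
            "value": np.log(period_riiv["riiv_km"]),
        }
    )
    vc = fit_lmm_reml(obs)
    return RepeatabilityEstimate(
        rp=repeatability(vc),
        cvi=float(np.sqrt(vc.var_among) / abs(vc.grand_mean)) if vc.grand_mean != 0 else float("nan"),
        rp_ci=bootstrap_ci(obs, repeatability, n_boot, seed),
        cvi_ci=(float("nan"), float("nan")),
        n_individuals=vc.n_groups,
        n_obs=vc.n_obs,
        n_boot=n_boot,
        seed=seed,
    )
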