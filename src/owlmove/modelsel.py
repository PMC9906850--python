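"""All-subsets mixed-model comparison: AICc ranking and full model averaging.

Candidate linear mixed models (random intercept per individual, maximum
likelihood so fixed-effect sets are comparable) are enumerated over
subsets of screened predictors, ranked by the small-sample Akaike
criterion AICc = -2 logL + 2k + 2k(k+1)/(n-k-1), and combined by full
model averaging: a predictor's averaged coefficient is the Akaike-weight
sum over in-scope models with 0 substituted where it is absent, and its
unconditional SE combines within-model variance with the among-model
spread of estimates (Burnham-Anderson).

A two-stage plan mirrors a common workflow: stage 1 enumerates the core
predictors; stage 2 augments the retained top models (within a Delta-AICc
threshold) with secondary terms (geography, density) and re-ranks.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .repeatability import fit_lmm


@dataclass
class CandidateModel:
    response: str
    predictors: tuple[str, ...]
    k: int
    loglik: float
    aicc: float
    coef: pd.Series
    se: pd.Series
    singular: bool = False
    delta: float = float("nan")
    weight: float = float("nan")

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.predictors) if self.predictors else "1"
        return f"{self.response} ~ {rhs}"


def standardize(
    df: pd.DataFrame, columns: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Center to mean 0, scale to sample SD 1; transform parameters returned."""
    out = df.copy()
    params = []
    for c in columns:
        x = df[c].astype(float)
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"zero-variance column: {c}")
        out[c] = (x - x.mean()) / sd
        params.append({"column": c, "mean": x.mean(), "sd": sd})
    return out, pd.DataFrame(params)


def backmap_slope(slope_std: float, params: pd.DataFrame, column: str) -> float:
    """Raw-scale slope from a slope fitted on a standardized covariate."""
    row = params[params["column"] == column].iloc[0]
    return slope_std / row["sd"]


def collinearity_screen(
    df: pd.DataFrame, columns: list[str], r_max: float = 0.7
) -> pd.DataFrame:
    """Pairwise |Pearson r| among numeric predictors; pairs above r_max flagged."""
    if len(columns) < 2:
        raise ValueError("need >= 2 covariates to screen")
    rows = []
    for a, b in itertools.combinations(columns, 2):
        r = float(np.corrcoef(df[a].astype(float), df[b].astype(float))[0, 1])
        rows.append({"a": a, "b": b, "r": r, "flagged": abs(r) > r_max})
    return pd.DataFrame(rows)


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike criterion; undefined when n <= k + 1."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def fit_lmm_ml(
    df: pd.DataFrame,
    response: str,
    predictors: tuple[str, ...],
    group_col: str = "individual",
) -> CandidateModel:
    """One candidate: ML mixed model with the given fixed-effect subset.

    k counts fixed-effect columns (with dummies) plus the two variances.
    A fit whose among-individual variance collapses to the boundary is
    flagged singular (droppable by the caller).
    """
    if df[group_col].nunique() < 2:
        raise ValueError("grouping factor needs >= 2 levels")
    vc = fit_lmm(
        df, value_col=response, group_col=group_col,
        fixed=list(predictors) if predictors else None, reml=False,
    )
    p = len(vc.beta)
    k = p + 2
    names = ["(Intercept)"]
    if predictors:
        dummies = pd.get_dummies(
            df[list(predictors)].astype(
                {c: str for c in predictors if df[c].dtype == object}
            ),
            drop_first=True,
            dtype=float,
        )
        names += list(dummies.columns)
    se = np.sqrt(np.diag(vc.beta_cov))
    return CandidateModel(
        response=response,
        predictors=tuple(predictors),
        k=k,
        loglik=vc.loglik,
        aicc=aicc(vc.loglik, k, vc.n_obs),
        coef=pd.Series(vc.beta, index=names),
        se=pd.Series(se, index=names),
        singular=vc.var_among == 0.0,
    )


def _allowed(subset: tuple[str, ...], excluded_pairs: set[frozenset]) -> bool:
    return not any(
        frozenset((a, b)) in excluded_pairs
        for a, b in itertools.combinations(subset, 2)
    )


def _rank(models: list[CandidateModel]) -> list[CandidateModel]:
    models = sorted(models, key=lambda m: (m.aicc, m.k, " + ".join(m.predictors)))
    best = models[0].aicc
    deltas = np.array([m.aicc - best for m in models])
    w = np.exp(-0.5 * deltas)
    w /= w.sum()
    for m, dlt, wt in zip(models, deltas, w):
        m.delta = float(dlt)
        m.weight = float(wt)
    return models


def enumerate_and_rank(
    df: pd.DataFrame,
    response: str,
    core: list[str],
    group_col: str = "individual",
    forced: tuple[str, ...] = (),
    stage2: list[str] | None = None,
    stage2_delta: float = 4.3,
    excluded_pairs: set[frozenset] | None = None,
    drop_singular: bool = False,
    max_models: int = 4096,
    allow_large: bool = False,
) -> list[CandidateModel]:
    """Enumerate fixed-effect subsets, fit by ML, rank by AICc.

    Stage 1 enumerates all subsets of ``core`` (with ``forced`` always
    included and collinear pairs never co-occurring).  If ``stage2`` terms
    are given, models within ``stage2_delta`` of the stage-1 top are
    augmented with every allowed non-empty subset of them and the union is
    re-ranked.  Ordering is deterministic: AICc, then fewer parameters,
    then the formula string.
    """
    excluded_pairs = excluded_pairs or set()
    free = [c for c in core if c not in forced]
    n_stage1 = 2 ** len(free)
    if n_stage1 > max_models and not allow_large:
        raise ValueError(
            f"{n_stage1} candidate models exceed the cap of {max_models}; "
            "pass allow_large=True to override"
        )

    def fit(subset: tuple[str, ...]) -> CandidateModel | None:
        try:
            return fit_lmm_ml(df, response, subset, group_col)
        except Exception as exc:
            warnings.warn(f"model {subset} failed: {exc}")
            return None

    models: list[CandidateModel] = []
    for r in range(len(free) + 1):
        for combo in itertools.combinations(free, r):
            subset = tuple(forced) + combo
            if not _allowed(subset, excluded_pairs):
                continue
            m = fit(subset)
            if m is None or (drop_singular and m.singular):
                continue
            models.append(m)
    models = _rank(models)

    if stage2:
        top = [m for m in models if m.delta <= stage2_delta]
        augmented: dict[tuple[str, ...], CandidateModel] = {
            m.predictors: m for m in top
        }
        total = len(top) * 2 ** len(stage2)
        if total > max_models and not allow_large:
            raise ValueError(
                f"stage-2 augmentation yields {total} models (> {max_models})"
            )
        for m in top:
            for r in range(1, len(stage2) + 1):
                for extra in itertools.combinations(stage2, r):
                    subset = m.predictors + extra
                    if not _allowed(subset, excluded_pairs):
                        continue
                    if subset in augmented:
                        continue
                    fitted = fit(subset)
                    if fitted is None or (drop_singular and fitted.singular):
                        continue
                    augmented[subset] = fitted
        models = _rank(list(augmented.values()))
    return models


def models_table(models: list[CandidateModel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "formula": [m.formula for m in models],
            "k": [m.k for m in models],
            "loglik": [m.loglik for m in models],
            "aicc": [m.aicc for m in models],
            "delta_aicc": [m.delta for m in models],
            "weight": [m.weight for m in models],
            "singular": [m.singular for m in models],
        }
    )


def model_average(
    models: list[CandidateModel], delta_max: float = 4.0
) -> pd.DataFrame:
    """Full model-averaged coefficients with unconditional SEs.

    Scope: models with Delta-AICc < ``delta_max`` (weights renormalized).
    Full averaging substitutes 0 where a predictor is absent; the
    unconditional SE is sum_m w_m sqrt(se_m^2 + (b_m - b_bar)^2).
    """
    scope = [m for m in models if m.delta < delta_max]
    if not scope:
        raise ValueError("no models within the averaging scope")
    w = np.array([m.weight for m in scope])
    w = w / w.sum()
    terms: list[str] = []
    for m in scope:
        for t in m.coef.index:
            if t not in terms:
                terms.append(t)
    rows = []
    for t in terms:
        b = np.array([m.coef.get(t, 0.0) for m in scope])
        s = np.array([m.se.get(t, 0.0) for m in scope])
        est = float(np.sum(w * b))
        se_u = float(np.sum(w * np.sqrt(s**2 + (b - est) ** 2)))
        rows.append(
            {
                "term": t,
                "estimate": est,
                "unconditional_se": se_u,
                "ci_low": est - 1.96 * se_u,
                "ci_high": est + 1.96 * se_u,
                "n_models": int(np.sum([t in m.coef.index for m in scope])),
            }
        )
    return pd.DataFrame(rows)
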