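"""Comorbidity-PIRA association analyses.

Hypothesis-driven: per-comorbidity odds ratios from logistic regression,
crude and fully adjusted (all baseline characteristics + the other
pre-specified flags), with multiple imputation by chained equations for
the adjusted model (20 imputations, 10 burn-in iterations) pooled by
Rubin's rules.

Data-driven: a phenome-wide screen of ICD-10 categories against PIRA using
two-sided Fisher's exact tests with a Bonferroni-corrected threshold, and
the Manhattan-plot table (-log10 p per category).

The two-sided Fisher p-value follows the point-probability convention: the
sum of hypergeometric probabilities, over all tables with the observed
margins, whose point probability does not exceed the observed one (with a
1e-7 relative tolerance for ties). It is computed in exact integer
arithmetic, so tie handling is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ContingencyTable2x2",
    "AssociationResult",
    "PooledEstimate",
    "fisher_exact_two_sided",
    "bonferroni_threshold",
    "manhattan_table",
    "fit_logistic_or",
    "mice_impute",
    "pool_rubin",
    "adjusted_pooled_or",
]

_TIE_NUM = 10_000_000  # 1e-7 relative tie tolerance as an integer ratio
_TIE_DEN = 10_000_001


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: a = exposed & PIRA, b = exposed & no PIRA,
    c = unexposed & PIRA, d = unexposed & no PIRA."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class AssociationResult:
    exposure: str
    estimate: float
    ci_low: float
    ci_high: float
    p: float
    analysis: str  # "crude" | "adjusted_pooled" | "fisher"
    converged: bool = True


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules pooling of m per-imputation estimates."""

    m: int
    Qbar: float
    W: float
    B: float
    T: float
    df: float

    @property
    def se(self) -> float:
        return math.sqrt(self.T)

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        from scipy import stats

        alpha = 1.0 - level
        if not math.isfinite(self.df):
            q = stats.norm.ppf(1 - alpha / 2)
        else:
            q = stats.t.ppf(1 - alpha / 2, self.df)
        return self.Qbar - q * self.se, self.Qbar + q * self.se


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p by point-probability enumeration.

    Any zero margin returns 1.0 by convention.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2
    if min(r1, r2, c1, c2) == 0:
        return 1.0
    # point probability numerators over the common denominator C(n, c1)
    k_lo, k_hi = max(0, c1 - r2), min(r1, c1)
    nums = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(k_lo, k_hi + 1)]
    n_obs = nums[a - k_lo]
    total = sum(nums)
    # include tables with N_k <= N_obs * (1 + 1e-7), exactly in integers
    p_num = sum(nk for nk in nums if nk * _TIE_NUM <= n_obs * _TIE_DEN)
    return p_num / total


def bonferroni_threshold(alpha: float, k: int) -> float:
    """Family-wise threshold alpha / k for k comparisons."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return alpha / k


def manhattan_table(
    icd_matrix: pd.DataFrame,
    pira: np.ndarray,
    lower: float = 0.01,
    upper: float = 0.99,
) -> pd.DataFrame:
    """Per-ICD-category Fisher screen (Manhattan-plot data).

    One row per category, including prevalence-filtered ones (kept=False);
    reports group prevalences, two-sided Fisher p and -log10 p.
    """
    from .comorb import prevalence_filter

    pira = np.asarray(pira, dtype=bool)
    if len(pira) != icd_matrix.shape[0]:
        raise ValueError("labels and matrix rows differ in length")
    kept, _ = prevalence_filter(icd_matrix, lower, upper)
    kept_set = set(kept)
    n_pira = int(pira.sum())
    n_no = int((~pira).sum())
    rows = []
    for cat in icd_matrix.columns:
        x = icd_matrix[cat].to_numpy() > 0
        a = int((x & pira).sum())
        b = int((x & ~pira).sum())
        p = fisher_exact_two_sided(ContingencyTable2x2(a, b, n_pira - a, n_no - b))
        rows.append(
            {
                "category": cat,
                "prev_pira": a / n_pira if n_pira else np.nan,
                "prev_nopira": b / n_no if n_no else np.nan,
                "p": p,
                "neglog10p": -math.log10(p) if p > 0 else math.inf,
                "kept": cat in kept_set,
            }
        )
    return pd.DataFrame(rows)


def fit_logistic_or(
    outcome: np.ndarray,
    exposure: np.ndarray,
    covariates: pd.DataFrame | None = None,
    exposure_name: str = "exposure",
) -> AssociationResult:
    """Maximum-likelihood logistic regression OR with Wald 95% CI.

    Separation / non-convergence is flagged (`converged=False`) rather than
    silently reported.
    """
    y = np.asarray(outcome, dtype=float)
    x = pd.DataFrame({exposure_name: np.asarray(exposure, dtype=float)})
    if covariates is not None:
        x = pd.concat([x, covariates.reset_index(drop=True)], axis=1)
    X = sm.add_constant(x.astype(float), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        coef = fit.params[exposure_name]
        se = fit.bse[exposure_name]
        pval = fit.pvalues[exposure_name]
        ok = bool(fit.mle_retvals.get("converged", True)) and np.isfinite(se) and se < 50
    except Exception:
        coef, se, pval, ok = np.nan, np.nan, np.nan, False
    if not ok:
        return AssociationResult(exposure_name, np.nan, np.nan, np.nan, np.nan, "crude", False)
    return AssociationResult(
        exposure=exposure_name,
        estimate=float(np.exp(coef)),
        ci_low=float(np.exp(coef - 1.96 * se)),
        ci_high=float(np.exp(coef + 1.96 * se)),
        p=float(pval),
        analysis="crude" if covariates is None else "adjusted",
    )


# ---------------------------------------------------------------------------
# multiple imputation by chained equations


def _draw_bayesian_linear(rng, X: np.ndarray, y: np.ndarray, X_mis: np.ndarray) -> np.ndarray:
    """Posterior-draw linear imputation (normal errors, flat prior)."""
    n, p = X.shape
    XtX = X.T @ X + 1e-8 * np.eye(p)
    beta_hat = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta_hat
    dof = max(n - p, 1)
    sigma2 = (resid @ resid) / rng.chisquare(dof)
    cov = sigma2 * np.linalg.inv(XtX)
    beta = rng.multivariate_normal(beta_hat, cov, method="cholesky")
    return X_mis @ beta + rng.normal(0, math.sqrt(sigma2), size=len(X_mis))


def _draw_multinomial(rng, X: np.ndarray, y: np.ndarray, X_mis: np.ndarray, levels) -> np.ndarray:
    from sklearn.linear_model import LogisticRegression

    if len(set(y)) == 1:
        return np.full(len(X_mis), y[0])
    clf = LogisticRegression(max_iter=500, C=1.0)
    codes, uniques = pd.factorize(pd.Series(y), sort=True)
    clf.fit(X, codes)
    probs = clf.predict_proba(X_mis)
    draws = [rng.choice(len(uniques), p=pr / pr.sum()) for pr in probs]
    return uniques.to_numpy()[draws]


def mice_impute(
    data: pd.DataFrame,
    m: int = 20,
    iterations: int = 10,
    seed: int = 0,
    categorical: tuple[str, ...] | None = None,
) -> list[pd.DataFrame]:
    """Multiple imputation by chained equations.

    Each incomplete column is regressed on all other columns (Bayesian
    linear draws for numerics, multinomial logistic draws for categoricals)
    cycling `iterations` times; `m` independent chains give m completed
    datasets. Columns without missing values (including the outcome) act as
    predictors only. Deterministic for a fixed seed.
    """
    data = data.reset_index(drop=True)
    if categorical is None:
        categorical = tuple(c for c in data.columns if data[c].dtype == object)
    missing_cols = [c for c in data.columns if data[c].isna().any()]
    for c in missing_cols:
        if data[c].isna().all():
            raise ValueError(f"column {c!r} has no observed values")
    if not missing_cols:
        return [data.copy() for _ in range(m)]

    def encode(df: pd.DataFrame, exclude: str) -> np.ndarray:
        cols = [c for c in df.columns if c != exclude]
        enc = pd.get_dummies(df[cols], columns=[c for c in cols if c in categorical], dtype=float)
        return np.column_stack([np.ones(len(df)), enc.to_numpy(dtype=float)])

    completed = []
    root = np.random.default_rng(seed)
    chain_seeds = root.integers(0, 2**31 - 1, size=m)
    for chain in range(m):
        rng = np.random.default_rng(chain_seeds[chain])
        df = data.copy()
        # initial fill: random draw from the observed values of each column
        for c in missing_cols:
            obs = df[c].dropna().to_numpy()
            na = df[c].isna()
            df.loc[na, c] = rng.choice(obs, size=int(na.sum()))
        for _ in range(iterations):
            for c in missing_cols:
                na = data[c].isna().to_numpy()
                X_full = encode(df, c)
                X_obs, X_mis = X_full[~na], X_full[na]
                y_obs = data.loc[~na, c].to_numpy()
                if c in categorical:
                    df.loc[na, c] = _draw_multinomial(rng, X_obs, y_obs, X_mis, None)
                else:
                    df.loc[na, c] = _draw_bayesian_linear(
                        rng, X_obs, y_obs.astype(float), X_mis
                    )
        completed.append(df)
    return completed


def pool_rubin(estimates, variances) -> PooledEstimate:
    """Pool m estimates and their squared SEs by Rubin's rules.

    T = W + (1 + 1/m) B; df = (m-1)(1 + W/((1+1/m)B))^2, infinite when B=0.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = len(q)
    if m < 2 or len(u) != m:
        raise ValueError("need m >= 2 estimates with matching variances")
    qbar = float(q.mean())
    w = float(u.mean())
    b = float(q.var(ddof=1))
    t = w + (1 + 1 / m) * b
    df = math.inf if b == 0 else (m - 1) * (1 + w / ((1 + 1 / m) * b)) ** 2
    return PooledEstimate(m=m, Qbar=qbar, W=w, B=b, T=t, df=df)


def adjusted_pooled_or(
    outcome: np.ndarray,
    exposure_name: str,
    design: pd.DataFrame,
    impute_cols: tuple[str, ...],
    categorical: tuple[str, ...] = (),
    m: int = 20,
    iterations: int = 10,
    seed: int = 0,
) -> AssociationResult:
    """Adjusted OR for one exposure: MICE over `impute_cols`, per-imputation
    logistic fits, Rubin pooling on the log-OR scale."""
    full = design.copy()
    full["__outcome__"] = np.asarray(outcome, dtype=float)
    completed = mice_impute(full, m=m, iterations=iterations, seed=seed, categorical=categorical)
    ests, variances = [], []
    for df in completed:
        y = df.pop("__outcome__").to_numpy()
        df_enc = pd.get_dummies(df, columns=[c for c in categorical if c in df], drop_first=True, dtype=float)
        covs = df_enc.drop(columns=[exposure_name])
        res = fit_logistic_or(y, df_enc[exposure_name].to_numpy(), covs, exposure_name)
        if res.converged:
            ests.append(math.log(res.estimate))
            variances.append(((math.log(res.ci_high) - math.log(res.estimate)) / 1.96) ** 2)
    if len(ests) < 2:
        return AssociationResult(exposure_name, np.nan, np.nan, np.nan, np.nan, "adjusted_pooled", False)
    pooled = pool_rubin(ests, variances)
    lo, hi = pooled.ci()
    from scipy import stats

    z = abs(pooled.Qbar) / pooled.se if pooled.se > 0 else math.inf
    if math.isfinite(pooled.df):
        p = 2 * stats.t.sf(z, pooled.df)
    else:
        p = 2 * stats.norm.sf(z)
    return AssociationResult(
        exposure=exposure_name,
        estimate=math.exp(pooled.Qbar),
        ci_low=math.exp(lo),
        ci_high=math.exp(hi),
        p=float(p),
        analysis="adjusted_pooled",
    )
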