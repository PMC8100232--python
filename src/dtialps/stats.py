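"""The study's statistical battery.

Covers, in the order the analysis runs them:

* Lilliefors-corrected Kolmogorov-Smirnov normality gate,
* single-rater absolute-agreement two-way random-effects ICC — McGraw-Wong
  ICC(A,1) — with F-based 95% CI and p-value,
* age/sex-adjusted ANCOVA with Bonferroni-corrected pairwise contrasts of
  covariate-adjusted group means (pooled residual variance,
  estimated-marginal-means style) and Bonferroni-widened CIs,
* Pearson correlation (binary covariates are entered on their 0/1 coding,
  i.e., point-biserial),
* variance-inflation-factor multicollinearity screening,
* SPSS-style stepwise multivariable linear regression (forward entry at
  p <= 0.05, backward removal at p >= 0.10 on partial F tests) with
  standardized coefficients.

All linear-model fits go through statsmodels OLS; the stepwise selection
loop itself is implemented here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "NormalityResult",
    "IccResult",
    "PairwiseContrast",
    "AncovaResult",
    "CorrelationResult",
    "RegressionResult",
    "ks_normality",
    "icc_absolute_agreement",
    "ancova_pairwise",
    "pearson",
    "vif",
    "stepwise_regression",
    "encode_binary_covariates",
    "SEX_CODES",
    "GRADE_CODES",
    "LOCATION_CODES",
]

# Dichotomy codings used throughout the analysis.
SEX_CODES = {"man": 0.0, "woman": 1.0}
GRADE_CODES = {"I": 0.0, "II_III": 1.0}
LOCATION_CODES = {"non_skull_base": 0.0, "skull_base": 1.0}

_KNOWN_CODES = {"sex": SEX_CODES, "tumor_grade": GRADE_CODES,
                "grade": GRADE_CODES, "location": LOCATION_CODES}


def encode_binary_covariates(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with known dichotomous string columns coded 0/1."""
    out = df.copy()
    for col, codes in _KNOWN_CODES.items():
        if col in out.columns and not pd.api.types.is_numeric_dtype(out[col]):
            out[col] = out[col].map(codes)
    return out


# ---------------------------------------------------------------------------
# Normality gate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p_value: float
    is_normal: bool
    n: int


def ks_normality(values, alpha: float = 0.05) -> NormalityResult:
    """Kolmogorov-Smirnov normality test against a normal with estimated
    mean/SD (Lilliefors-corrected p).

    The flag drives parametric-vs-nonparametric reporting downstream; the
    study's variables passed the gate, so parametric analysis follows it.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 5:
        raise ValueError("normality testing requires at least 5 observations")
    if np.ptp(x) == 0.0:
        raise ValueError("normality test undefined for constant input")
    stat, p = lilliefors(x, dist="norm")
    return NormalityResult(statistic=float(stat), p_value=float(p),
                           is_normal=bool(p >= alpha), n=int(x.size))


# ---------------------------------------------------------------------------
# Inter-observer agreement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IccResult:
    """Single-rater absolute-agreement two-way random ICC with 95% CI."""

    icc: float
    ci_low: float
    ci_high: float
    p_value: float
    n_subjects: int
    n_raters: int
    undefined: bool = False


def icc_absolute_agreement(ratings, alpha: float = 0.05) -> IccResult:
    """McGraw-Wong ICC(A,1) from the two-way random-effects mean squares.

    ``ratings`` is an (n_subjects, n_raters) matrix with no missing cells.
    The CI uses the F-distribution method with Satterthwaite degrees of
    freedom; the p-value is from F = MSR/MSE. Absolute agreement penalises
    a fixed between-rater bias, unlike a consistency formulation.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("ratings must be an (n_subjects, n_raters>=2) matrix")
    if np.any(~np.isfinite(x)):
        raise ValueError("missing cells are not supported")
    n, k = x.shape
    if n < 3:
        raise ValueError("at least 3 subjects are required")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    mse = max(mse, 0.0)  # guard float cancellation

    scale = max(sst / (n * k - 1), np.abs(x).max() ** 2, 1e-300)
    if msr <= 1e-12 * scale:
        return IccResult(icc=float("nan"), ci_low=float("nan"),
                         ci_high=float("nan"), p_value=float("nan"),
                         n_subjects=n, n_raters=k, undefined=True)

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom

    if mse == 0.0 and msc == 0.0:
        # perfect agreement: no rater or residual variance
        return IccResult(icc=1.0, ci_low=1.0, ci_high=1.0, p_value=0.0,
                         n_subjects=n, n_raters=k)

    df_e = (n - 1) * (k - 1)
    f_obs = msr / mse if mse > 0 else np.inf
    p = float(sps.f.sf(f_obs, n - 1, df_e)) if np.isfinite(f_obs) else 0.0

    a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if np.isfinite(a) and np.isfinite(b):
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / df_e)
        f_l = sps.f.ppf(1.0 - alpha / 2.0, n - 1, v)
        f_u = sps.f.ppf(1.0 - alpha / 2.0, v, n - 1)
        lower = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
        upper = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr)
    else:
        lower = upper = 1.0
    return IccResult(icc=float(icc), ci_low=float(lower), ci_high=float(upper),
                     p_value=p, n_subjects=n, n_raters=k)


# ---------------------------------------------------------------------------
# Covariate-adjusted group contrasts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairwiseContrast:
    group_a: str
    group_b: str
    diff: float       # adjusted mean of a minus adjusted mean of b
    p_raw: float
    p_adj: float      # Bonferroni: min(1, m * p_raw)
    ci_low: float     # joint 95% Bonferroni CI of the difference
    ci_high: float


@dataclass(frozen=True)
class AncovaResult:
    contrasts: tuple[PairwiseContrast, ...]
    omnibus_p: float
    covariates: tuple[str, ...]
    group_sizes: dict
    n_pairs: int
    alpha: float = 0.05

    def contrast(self, a: str, b: str) -> PairwiseContrast:
        for c in self.contrasts:
            if {c.group_a, c.group_b} == {a, b}:
                return c
        raise KeyError(f"no contrast between {a!r} and {b!r}")


def ancova_pairwise(df: pd.DataFrame, response: str, group_col: str = "group",
                    covariates: tuple[str, ...] = ("age", "sex"),
                    alpha: float = 0.05,
                    group_order: list[str] | None = None) -> AncovaResult:
    """ANCOVA ``response ~ group + covariates`` with Bonferroni pairwise contrasts.

    Group contrasts compare covariate-adjusted (marginal) group means at
    the covariate means, using the pooled residual variance of the single
    fitted model; each raw pairwise p is multiplied by the number of pairs
    (capped at 1) and the CIs widened to joint 95% Bonferroni coverage.
    Known dichotomous string covariates (sex/grade/location) are coded 0/1
    automatically.
    """
    data = encode_binary_covariates(df[[response, group_col, *covariates]].copy())
    data = data.dropna()
    groups = group_order or list(dict.fromkeys(data[group_col]))
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    sizes = {g: int((data[group_col] == g).sum()) for g in groups}
    for g, n_g in sizes.items():
        if n_g < 3:
            raise ValueError(f"group {g!r} has fewer than 3 observations")
    for cov in covariates:
        if np.ptp(data[cov].to_numpy(dtype=float)) == 0.0:
            raise ValueError(f"covariate {cov!r} is constant")

    y = data[response].to_numpy(dtype=float)
    n = y.size
    dummies = np.column_stack([
        (data[group_col] == g).to_numpy(dtype=float) for g in groups[1:]
    ])
    covs = data[list(covariates)].to_numpy(dtype=float)
    X = np.column_stack([np.ones(n), dummies, covs])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix: groups/covariates are "
                         "confounded or redundant")

    fit = sm.OLS(y, X).fit()
    kg = len(groups)
    # omnibus: all group-dummy coefficients zero
    R = np.zeros((kg - 1, X.shape[1]))
    for i in range(kg - 1):
        R[i, 1 + i] = 1.0
    omnibus_p = float(fit.f_test(R).pvalue)

    # coefficient vector position of each group's offset (reference = 0)
    coef_index = {g: 1 + i for i, g in enumerate(groups[1:])}
    m = kg * (kg - 1) // 2
    tcrit = sps.t.ppf(1.0 - alpha / (2.0 * m), fit.df_resid)
    cov_params = fit.cov_params()
    contrasts = []
    for ga, gb in itertools.combinations(groups, 2):
        c = np.zeros(X.shape[1])
        if ga in coef_index:
            c[coef_index[ga]] += 1.0
        if gb in coef_index:
            c[coef_index[gb]] -= 1.0
        diff = float(c @ fit.params)
        se = float(np.sqrt(c @ cov_params @ c))
        tstat = diff / se
        p_raw = float(2.0 * sps.t.sf(abs(tstat), fit.df_resid))
        contrasts.append(PairwiseContrast(
            group_a=ga, group_b=gb, diff=diff, p_raw=p_raw,
            p_adj=float(min(1.0, m * p_raw)),
            ci_low=diff - tcrit * se, ci_high=diff + tcrit * se))
    return AncovaResult(contrasts=tuple(contrasts), omnibus_p=omnibus_p,
                        covariates=tuple(covariates), group_sizes=sizes,
                        n_pairs=m, alpha=alpha)


# ---------------------------------------------------------------------------
# Correlation and multicollinearity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int


def pearson(x, y) -> CorrelationResult:
    """Sample Pearson r with the two-sided t-based p-value."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y differ in length")
    if x.size < 3:
        raise ValueError("Pearson correlation requires n >= 3")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("Pearson correlation undefined for constant input")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), p_value=float(p), n=int(x.size))


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor 1/(1 - R_j^2) per candidate column.

    Each candidate is regressed (with intercept) on all the others. Exact
    collinearity is reported as ``inf`` — the flag callers should act on
    before any regression modelling.
    """
    X = pd.DataFrame(X)
    cols = list(X.columns)
    if len(cols) < 2:
        raise ValueError("VIF needs at least 2 candidate columns")
    A = X.to_numpy(dtype=float)
    if A.shape[0] <= len(cols):
        raise ValueError("VIF needs more rows than candidate columns")
    out = {}
    for j, col in enumerate(cols):
        yj = A[:, j]
        others = np.column_stack(
            [np.ones(A.shape[0]), np.delete(A, j, axis=1)])
        rsq = sm.OLS(yj, others).fit().rsquared
        out[col] = np.inf if 1.0 - rsq < 1e-12 else 1.0 / (1.0 - rsq)
    return pd.Series(out, name="vif")


# ---------------------------------------------------------------------------
# Stepwise multivariable linear regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionResult:
    """Final stepwise model with the step-by-step selection trace."""

    selected: tuple[str, ...]
    coefficients: dict            # unstandardized, including "intercept"
    std_coefficients: dict        # standardized beta per selected predictor
    p_values: dict                # per selected predictor
    r_squared: float
    entry_p: float
    removal_p: float
    vifs: pd.Series | None
    trace: tuple[tuple, ...] = field(default=())  # (step, action, name, p)


def _fit_ols(y: np.ndarray, X: pd.DataFrame, cols: list[str]):
    design = np.column_stack([np.ones(y.size)]
                             + [X[c].to_numpy(dtype=float) for c in cols])
    return sm.OLS(y, design).fit()


def stepwise_regression(X: pd.DataFrame, y, entry_p: float = 0.05,
                        removal_p: float = 0.10,
                        compute_vifs: bool = True) -> RegressionResult:
    """Forward-entry / backward-removal stepwise linear regression.

    A candidate enters when its partial-F (equivalently squared-t) p-value
    in the augmented model is the smallest and <= ``entry_p``; after each
    entry, any in-model predictor whose p-value is >= ``removal_p`` is
    removed (largest p first). Ties break on smaller entry p, then on the
    fixed candidate order of ``X.columns``. If no candidate ever meets the
    entry criterion, the intercept-only model is returned.

    Standardized coefficients are beta_j * sd(x_j) / sd(y) of the final
    model.
    """
    X = encode_binary_covariates(pd.DataFrame(X))
    y = np.asarray(y, dtype=float).ravel()
    cols = list(X.columns)
    if y.size != len(X):
        raise ValueError("X and y differ in length")
    if y.size <= len(cols) + 2:
        raise ValueError("stepwise regression needs n > n_candidates + 2")
    if entry_p > removal_p:
        raise ValueError("entry_p must not exceed removal_p (cycling)")

    vifs = vif(X) if (compute_vifs and len(cols) >= 2) else None

    selected: list[str] = []
    trace: list[tuple] = []
    step = 0
    sst = float(np.sum((y - y.mean()) ** 2))
    for _ in range(2 * len(cols) + 10):
        changed = False
        # numerically perfect fit: further partial F tests are 0/0 noise
        if selected and _fit_ols(y, X, selected).ssr <= 1e-12 * max(sst, 1e-300):
            break
        # forward entry
        remaining = [c for c in cols if c not in selected]
        if remaining:
            pvals = []
            for c in remaining:
                f = _fit_ols(y, X, selected + [c])
                pvals.append(float(f.pvalues[-1]))
            best = int(np.argmin(pvals))  # first index on ties = candidate order
            if pvals[best] <= entry_p:
                step += 1
                selected.append(remaining[best])
                trace.append((step, "enter", remaining[best], pvals[best]))
                changed = True
        # backward removal
        while len(selected) > 0:
            f = _fit_ols(y, X, selected)
            pv = np.asarray(f.pvalues[1:], dtype=float)
            worst = int(np.argmax(pv))
            if pv[worst] >= removal_p:
                step += 1
                name = selected.pop(worst)
                trace.append((step, "remove", name, float(pv[worst])))
                changed = True
            else:
                break
        if not changed:
            break

    fit = _fit_ols(y, X, selected)
    coefs = {"intercept": float(fit.params[0])}
    stds = {}
    ps = {}
    sy = y.std(ddof=1)
    for i, c in enumerate(selected, start=1):
        coefs[c] = float(fit.params[i])
        ps[c] = float(fit.pvalues[i])
        stds[c] = float(fit.params[i]
                        * X[c].to_numpy(dtype=float).std(ddof=1) / sy)
    r2 = float(fit.rsquared) if selected else 0.0
    return RegressionResult(selected=tuple(selected), coefficients=coefs,
                            std_coefficients=stds, p_values=ps, r_squared=r2,
                            entry_p=entry_p, removal_p=removal_p, vifs=vifs,
                            trace=tuple(trace))
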