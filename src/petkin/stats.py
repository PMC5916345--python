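"""Cohort-level statistics: correlations with bootstrap CIs, normality
gating, partial correlation, paired tests with effect size, OLS regression,
Bonferroni flags, correlation power, and inter-rater agreement.

Conventions
-----------
* Correlation CIs are percentile intervals over seeded paired bootstrap
  resamples (1000 by default).
* Partial correlation is the Pearson correlation of the residuals after
  regressing each variable on the covariates (intercept included); its
  p-value uses n - 2 - k degrees of freedom for k covariates.
* Missing values are refused rather than silently dropped — callers are
  expected to apply listwise deletion first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "CorrelationResult", "correlate", "partial_correlate", "shapiro_gate",
    "PairedTestResult", "paired_ttest", "RegressionResult", "ols_regression",
    "correlation_power", "bonferroni", "icc",
]


def _check_1d(name, x, min_n=2):
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    if x.size < min_n:
        raise ValueError(f"{name} needs at least {min_n} observations")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains missing or non-finite values")
    return x


@dataclass(frozen=True)
class CorrelationResult:
    """Point estimate, test and bootstrap CI for one correlation."""

    r: float
    p: float
    ci_low: float
    ci_high: float
    method: str
    n: int
    n_boot: int
    seed: int | None

    def summary(self) -> str:
        return (f"{self.method} r={self.r:.3f} "
                f"[{self.ci_low:.3f}, {self.ci_high:.3f}] "
                f"p={self.p:.4g} (n={self.n}, {self.n_boot} bootstrap samples)")


def _point_corr(x, y, method):
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def correlate(x, y, method: str = "pearson", n_boot: int = 1000,
              seed: int | None = 0) -> CorrelationResult:
    """Pearson or Spearman correlation with a percentile bootstrap CI.

    Pairs (x_i, y_i) are resampled with replacement ``n_boot`` times;
    degenerate resamples (zero variance) are skipped for the CI.
    """
    x = _check_1d("x", x, 4)
    y = _check_1d("y", y, 4)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    r, p = _point_corr(x, y, method)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    boots.fill(np.nan)
    n = x.size
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        xb, yb = x[idx], y[idx]
        if np.std(xb) == 0 or np.std(yb) == 0:
            continue
        boots[b] = _point_corr(xb, yb, method)[0]
    ok = boots[np.isfinite(boots)]
    ci_low, ci_high = (np.percentile(ok, [2.5, 97.5]) if ok.size
                       else (np.nan, np.nan))
    return CorrelationResult(r=r, p=p, ci_low=float(ci_low), ci_high=float(ci_high),
                             method=method, n=n, n_boot=n_boot, seed=seed)


def _residualise(v, Z):
    X = sm.add_constant(Z)
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def partial_correlate(x, y, covariates, n_boot: int = 1000,
                      seed: int | None = 0) -> CorrelationResult:
    """Pearson correlation of x and y with covariates regressed out.

    The p-value uses the t transform with df = n - 2 - k.  The bootstrap
    resamples whole rows (x, y, covariates) and recomputes the residual
    correlation each time.
    """
    x = _check_1d("x", x, 4)
    y = _check_1d("y", y, 4)
    Z = np.asarray(covariates, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if not np.all(np.isfinite(Z)):
        raise ValueError("covariates contain missing values")
    n, k = Z.shape
    if x.size != n or y.size != n:
        raise ValueError("x, y and covariates must have equal length")
    if n <= k + 3:
        raise ValueError("need n > n_covariates + 3")

    def presid_r(xv, yv, Zv):
        rx = _residualise(xv, Zv)
        ry = _residualise(yv, Zv)
        if np.std(rx) < 1e-12 * max(1.0, np.std(xv)) or \
           np.std(ry) < 1e-12 * max(1.0, np.std(yv)):
            raise ValueError("covariate collinear with x or y (zero residual variance)")
        return float(np.corrcoef(rx, ry)[0, 1])

    r = presid_r(x, y, Z)
    df = n - 2 - k
    t = r * np.sqrt(df / max(1e-300, 1.0 - r * r))
    p = float(2.0 * sps.t.sf(abs(t), df))
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            boots.append(presid_r(x[idx], y[idx], Z[idx]))
        except (ValueError, np.linalg.LinAlgError):
            continue
    ci_low, ci_high = (np.percentile(boots, [2.5, 97.5]) if boots
                       else (np.nan, np.nan))
    return CorrelationResult(r=r, p=p, ci_low=float(ci_low), ci_high=float(ci_high),
                             method="partial_pearson", n=n, n_boot=n_boot, seed=seed)


def shapiro_gate(x, alpha: float = 0.05) -> str:
    """Shapiro-Wilk gate: ``"normal"`` unless W's p < alpha.

    A ``"non_normal"`` verdict signals that rank-based (Spearman)
    correlation should be used downstream.
    """
    x = _check_1d("x", x, 3)
    if x.size > 5000:
        raise ValueError("Shapiro-Wilk is calibrated for n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant input")
    _, p = sps.shapiro(x)
    return "non_normal" if p < alpha else "normal"


@dataclass(frozen=True)
class PairedTestResult:
    """Paired t-test with the within-subject effect size dz = mean(d)/sd(d)."""

    t: float
    df: int
    p: float
    dz: float

    def summary(self) -> str:
        return f"t({self.df})={self.t:.2f}, p={self.p:.3g}, dz={self.dz:.2f}"


def paired_ttest(a, b) -> PairedTestResult:
    a = _check_1d("a", a, 2)
    b = _check_1d("b", b, 2)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    d = a - b
    sd = np.std(d, ddof=1)
    if sd == 0:
        raise ValueError("zero variance of differences")
    t, p = sps.ttest_rel(a, b)
    return PairedTestResult(t=float(t), df=a.size - 1, p=float(p),
                            dz=float(np.mean(d) / sd))


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit: per-predictor slopes with t/p, model F and adjusted r^2."""

    params: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    names: tuple[str, ...]
    fvalue: float
    f_pvalue: float
    rsquared: float
    rsquared_adj: float
    n: int

    def summary(self) -> str:
        lines = [f"OLS (n={self.n}): F={self.fvalue:.2f}, p={self.f_pvalue:.3g}, "
                 f"adj r2={self.rsquared_adj:.3f}"]
        for nm, b, t, p in zip(self.names, self.params, self.tvalues, self.pvalues):
            lines.append(f"  {nm:>16s}  b={b: .4g}  t={t: .2f}  p={p:.3g}")
        return "\n".join(lines)


def ols_regression(y, predictors, names=None) -> RegressionResult:
    """Ordinary least squares of y on the predictor columns plus intercept."""
    y = _check_1d("y", y, 3)
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.all(np.isfinite(X)):
        raise ValueError("predictors contain missing values")
    n, k = X.shape
    if y.size != n:
        raise ValueError("y and predictors must have equal length")
    if n <= k + 1:
        raise ValueError("need n > n_predictors + 1")
    if np.linalg.matrix_rank(sm.add_constant(X)) < k + 1:
        raise ValueError("rank-deficient design")
    if names is None:
        names = tuple(f"x{i + 1}" for i in range(k))
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    return RegressionResult(
        params=np.asarray(fit.params), tvalues=np.asarray(fit.tvalues),
        pvalues=np.asarray(fit.pvalues), names=("intercept",) + tuple(names),
        fvalue=float(fit.fvalue), f_pvalue=float(fit.f_pvalue),
        rsquared=float(fit.rsquared), rsquared_adj=float(fit.rsquared_adj), n=n)


def correlation_power(rho: float, n: int | None = None, alpha: float = 0.05,
                      tails: int = 2, target_power: float | None = None):
    """Power of the correlation test, or the minimum n for a target power.

    Uses the Fisher-z approximation: z = atanh(r) is approximately normal
    with SD 1/sqrt(n-3), so
    power = Phi(|atanh(rho)|*sqrt(n-3) - z_crit) (+ the negligible
    opposite-tail term when two-tailed).  Exactly one of ``n`` and
    ``target_power`` must be given.
    """
    if not (-1 < rho < 1):
        raise ValueError("rho must be in (-1, 1)")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    if (n is None) == (target_power is None):
        raise ValueError("give exactly one of n and target_power")
    z_crit = sps.norm.ppf(1.0 - alpha / tails)
    zr = abs(np.arctanh(rho))

    def power_at(nn):
        s = np.sqrt(nn - 3.0)
        pw = sps.norm.cdf(zr * s - z_crit)
        if tails == 2:
            pw += sps.norm.cdf(-zr * s - z_crit)
        return float(pw)

    if n is not None:
        if n < 4:
            raise ValueError("need n >= 4")
        return power_at(n)
    if rho == 0 and target_power > alpha:
        raise ValueError("no finite n achieves that power at rho=0")
    if not (0 < target_power < 1):
        raise ValueError("target_power must be in (0, 1)")
    nn = 4
    while power_at(nn) < target_power:
        nn += 1
        if nn > 10**7:  # pragma: no cover
            raise RuntimeError("power target unreachable")
    return nn


def bonferroni(p_values, m: int, alpha: float = 0.05) -> np.ndarray:
    """Boolean flags for p < alpha/m (family-wise control over m tests)."""
    p = np.asarray(p_values, dtype=float)
    if m < 1:
        raise ValueError("m must be >= 1")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return p < alpha / m


def icc(ratings) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is (n_targets, n_raters), complete.  From the two-way ANOVA
    mean squares, ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE)/n).
    """
    R = np.asarray(ratings, dtype=float)
    if R.ndim != 2 or R.shape[0] < 2 or R.shape[1] < 2:
        raise ValueError("ratings must be (>=2 targets, >=2 raters)")
    if not np.all(np.isfinite(R)):
        raise ValueError("ratings table must be complete")
    if np.ptp(R) == 0:
        raise ValueError("constant ratings table")
    n, k = R.shape
    grand = R.mean()
    row_means = R.mean(axis=1)
    col_means = R.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((R - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))
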