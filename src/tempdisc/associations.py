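"""Correlation/regression layer linking discounting quantities to symptoms.

Conventions mirrored from the study design: values more than 3 SD from the
mean are excluded per variable (mean/SD from the full non-missing sample);
Pearson correlations and regressions of the two framing versions on the
same predictor are Holm-corrected across that two-outcome family; OLS uses
heteroskedasticity-consistent (HC3 by default) sandwich standard errors
with the studentized (Koenker) Breusch-Pagan test attached; regressors and
outcome are z-standardized so coefficients are standardized betas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special, stats


def exclude_outliers(x: np.ndarray, z_threshold: float = 3.0) -> np.ndarray:
    """Inclusion mask: True where |x - mean| <= z_threshold * SD.

    Mean and SD are computed once on the full non-missing sample; missing
    values are excluded. A zero-SD vector yields no exclusions (warning).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need n >= 2")
    ok = np.isfinite(x)
    m = x[ok].mean()
    s = x[ok].std(ddof=1)
    if s == 0:
        warnings.warn("zero SD: no outlier exclusions possible")
        return ok
    return ok & (np.abs(np.where(ok, x, m) - m) <= z_threshold * s)


def holm_correct(pvals: np.ndarray) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * (m - np.arange(m))
    adj = np.minimum(np.maximum.accumulate(adj), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _pearson_ci(r: float, n: int) -> tuple[float, float]:
    if n <= 3 or abs(r) >= 1:
        return (np.nan, np.nan)
    z = np.arctanh(r)
    half = 1.959963984540054 / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def pearson_with_holm(
    td_vars: pd.DataFrame,
    scales: pd.DataFrame,
    z_threshold: float = 3.0,
) -> pd.DataFrame:
    """Pearson correlations of each symptom scale with each discounting DV.

    Outlier masks are computed per variable on the full sample and applied
    pairwise; the Holm family is the set of discounting DVs tested per
    scale (the two framing versions in the primary analysis). Pairs with
    fewer than 4 complete cases are skipped with a warning.
    """
    masks_td = {c: exclude_outliers(td_vars[c].to_numpy()) for c in td_vars.columns}
    masks_sc = {c: exclude_outliers(scales[c].to_numpy()) for c in scales.columns}
    rows = []
    for scale in scales.columns:
        family = []
        for dv in td_vars.columns:
            m = masks_td[dv] & masks_sc[scale]
            n = int(m.sum())
            if n < 4:
                warnings.warn(f"pair ({dv}, {scale}): n={n} < 4, skipped")
                continue
            r, p = stats.pearsonr(td_vars[dv].to_numpy()[m], scales[scale].to_numpy()[m])
            lo, hi = _pearson_ci(r, n)
            family.append({"td_var": dv, "scale": scale, "r": r, "ci_low": lo,
                           "ci_high": hi, "p": p, "n": n})
        if family:
            pc = holm_correct(np.array([f["p"] for f in family]))
            for f, q in zip(family, pc):
                f["p_c"] = q
            rows.extend(family)
    return pd.DataFrame(rows)


@dataclass
class RegressionResult:
    outcome: str
    table: pd.DataFrame            # term, beta, se, ci_low, ci_high, p
    hc_type: str
    breusch_pagan: float
    breusch_pagan_p: float
    n: int
    r_squared: float


def robust_ols(
    y: np.ndarray | pd.Series,
    X: pd.DataFrame,
    hc_type: str = "HC3",
    standardize: bool = True,
    outcome: str = "y",
) -> RegressionResult:
    """OLS with sandwich standard errors and the Breusch-Pagan test.

    When ``standardize`` is set, the outcome and all non-binary regressors
    are z-standardized so coefficients are standardized betas; binary (dummy)
    columns are left as-is. Rank-deficient designs raise an error naming the
    collinear columns.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    X = X.astype(float).copy()
    ok = np.isfinite(y) & np.isfinite(X.to_numpy()).all(axis=1)
    y = y[ok]
    X = X.loc[ok]
    if standardize:
        y = (y - y.mean()) / y.std(ddof=1)
        for c in X.columns:
            vals = X[c].to_numpy()
            if np.unique(vals).size > 2:
                X[c] = (vals - vals.mean()) / vals.std(ddof=1)
    Xd = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xd.to_numpy())
    if rank < Xd.shape[1]:
        bad = []
        base = Xd[["const"]].to_numpy()
        for c in X.columns:
            cand = np.column_stack([base, Xd[c].to_numpy()])
            if np.linalg.matrix_rank(cand) == np.linalg.matrix_rank(base):
                bad.append(c)
        if not bad:  # collinear combination across columns
            corr = X.corr().abs()
            np.fill_diagonal(corr.values, 0)
            i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
            bad = [corr.index[i], corr.columns[j]]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(y, Xd).fit(cov_type=hc_type)
    ci = fit.conf_int()
    table = pd.DataFrame(
        {
            "term": Xd.columns,
            "beta": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "ci_low": ci[0].to_numpy(),
            "ci_high": ci[1].to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    )
    bp_stat, bp_p = breusch_pagan(fit.resid.to_numpy(), Xd.to_numpy())
    return RegressionResult(
        outcome=outcome,
        table=table,
        hc_type=hc_type,
        breusch_pagan=bp_stat,
        breusch_pagan_p=bp_p,
        n=int(ok.sum()),
        r_squared=float(fit.rsquared),
    )


def holm_across_outcomes(results: list[RegressionResult]) -> list[RegressionResult]:
    """Holm-correct each term's p-values across a family of outcomes.

    Mirrors correcting across the two framing versions: for every regressor
    the family is its p-values over the supplied models; adds a ``p_c``
    column to each result table in place and returns the list.
    """
    terms = results[0].table["term"].tolist()
    for res in results:
        res.table["p_c"] = np.nan
    for t in terms:
        ps, locs = [], []
        for res in results:
            row = res.table.index[res.table["term"] == t]
            if len(row):
                ps.append(float(res.table.loc[row[0], "p"]))
                locs.append((res, row[0]))
        pc = holm_correct(np.array(ps))
        for (res, i), q in zip(locs, pc):
            res.table.loc[i, "p_c"] = q
    return results


def breusch_pagan(residuals: np.ndarray, X: np.ndarray) -> tuple[float, float]:
    """Studentized (Koenker) Breusch-Pagan test.

    Regresses squared residuals on the design (including constant);
    statistic = n * R^2, chi-square with df = number of non-constant
    regressors. Constant residuals give statistic 0.
    """
    e = np.asarray(residuals, dtype=float)
    X = np.asarray(X, dtype=float)
    if e.ndim != 1 or X.shape[0] != e.size:
        raise ValueError("residuals and design are misaligned")
    e2 = e**2
    if np.all(e2 == 0):
        raise ValueError("degenerate residuals: all zero")
    # ensure a constant column
    if not np.any(np.all(X == X[0], axis=0)):
        X = np.column_stack([np.ones(e.size), X])
    df = X.shape[1] - 1
    if np.var(e2) == 0:
        return 0.0, 1.0
    beta, *_ = np.linalg.lstsq(X, e2, rcond=None)
    fitted = X @ beta
    ss_res = np.sum((e2 - fitted) ** 2)
    ss_tot = np.sum((e2 - e2.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot
    stat = e.size * r2
    p = float(stats.chi2.sf(stat, df))
    return float(stat), p


# ------------------------------------------------------ exact power for r

def _log_pdf_r(r: np.ndarray, rho: float, n: int) -> np.ndarray:
    """Exact log density of the sample correlation under bivariate normality."""
    r = np.asarray(r, dtype=float)
    lg = special.gammaln
    hyp = special.hyp2f1(0.5, 0.5, n - 0.5, (1.0 + rho * r) / 2.0)
    return (
        np.log(n - 2.0)
        + lg(n - 1.0)
        - 0.5 * np.log(2.0 * np.pi)
        - lg(n - 0.5)
        + ((n - 1.0) / 2.0) * np.log1p(-rho * rho)
        + ((n - 4.0) / 2.0) * np.log1p(-(r * r))
        - (n - 1.5) * np.log1p(-rho * r)
        + np.log(hyp)
    )


def correlation_test_power(n: int, rho: float, alpha: float = 0.05) -> float:
    """Exact power of the two-sided test of zero correlation at sample size n."""
    if n < 4:
        return 0.0
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    r_crit = t_crit / np.sqrt(n - 2 + t_crit**2)

    def pdf(r):
        return np.exp(_log_pdf_r(r, rho, n))

    upper, _ = integrate.quad(pdf, r_crit, 1.0, limit=200)
    lower, _ = integrate.quad(pdf, -1.0, -r_crit, limit=200)
    return float(upper + lower)


def power_n_correlation(
    rho: float = 0.10, alpha: float = 0.05, power: float = 0.80, n_cap: int = 1_000_000
) -> int:
    """Smallest n at which the exact two-sided correlation test reaches power.

    Uses the exact sampling distribution of r under bivariate normality (not
    the Fisher-z approximation) and bisection over n.
    """
    if not (0 < rho < 1) or not (0 < alpha < 1) or not (0 < power < 1):
        raise ValueError("rho, alpha, power must lie in (0, 1)")
    lo, hi = 4, 8
    while correlation_test_power(hi, rho, alpha) < power:
        lo = hi
        hi *= 2
        if hi > n_cap:
            raise RuntimeError(f"target power unreachable below n = {n_cap}")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if correlation_test_power(mid, rho, alpha) >= power:
            hi = mid
        else:
            lo = mid
    return hi
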