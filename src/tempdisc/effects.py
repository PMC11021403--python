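"""Date/delay and magnitude effect inference.

Implements the one-group "Bayesian estimation supersedes the t-test" (BEST)
model on paired differences (t likelihood with location mu, scale sigma and
normality df nu, canonical broad priors), the frequentist paired t-test with
the averaged-SD Hedges effect size g_av, and a one-way repeated-measures
ANOVA with Greenhouse-Geisser correction and post-hoc pairwise t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats


@dataclass
class BESTResult:
    prob_above_zero: float
    posterior_median_mu: float
    hdi95: tuple[float, float]
    n_iterations: int
    mu: np.ndarray = field(repr=False)      # (chains, draws)
    sigma: np.ndarray = field(repr=False)
    nu: np.ndarray = field(repr=False)
    diagnostics: dict = field(default_factory=dict)


def _t_loglik(d: np.ndarray, mu, sigma, nu) -> np.ndarray:
    """Student-t log-likelihood summed over data, vectorized over chains."""
    x = (d[None, :] - mu[:, None]) / sigma[:, None]
    n = d.size
    const = (
        special.gammaln((nu + 1) / 2)
        - special.gammaln(nu / 2)
        - 0.5 * np.log(nu * np.pi)
        - np.log(sigma)
    )
    return n * const - ((nu + 1) / 2) * np.log1p(x**2 / nu[:, None]).sum(axis=1)


def best_paired(
    differences: np.ndarray,
    iterations: int = 30_000,
    seed: int | None = None,
    chains: int = 3,
    warmup: int = 2_000,
) -> BESTResult:
    """Fit the one-group BEST model to paired differences by adaptive MH.

    Priors follow the canonical specification: mu ~ Normal(mean(d),
    1000*SD(d)), sigma ~ Uniform(SD/1000, SD*1000), nu ~ 1 + Exponential(29).
    ``iterations`` is the total number of retained MCMC draws across chains.
    """
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1 or d.size < 2:
        raise ValueError("differences must be a 1-d vector with n >= 2")
    if not np.all(np.isfinite(d)):
        raise ValueError("differences contain non-finite values")
    if iterations < 1000:
        raise ValueError("need at least 1000 iterations")
    m, s = float(d.mean()), float(d.std(ddof=1))
    if s == 0:
        raise ValueError("zero-variance differences: BEST scale prior undefined")

    lo_s, hi_s = np.log(s / 1000.0), np.log(s * 1000.0)

    def logpost(mu, log_sigma, log_num1):
        sigma = np.exp(log_sigma)
        nu = 1.0 + np.exp(log_num1)
        lp = _t_loglik(d, mu, sigma, nu)
        lp += -0.5 * ((mu - m) / (1000.0 * s)) ** 2
        lp += np.where((log_sigma > lo_s) & (log_sigma < hi_s), log_sigma, -np.inf)
        lp += -(nu - 1.0) / 29.0 + log_num1
        return lp

    rng = np.random.default_rng(seed)
    K = chains
    draws = int(np.ceil(iterations / K))
    mu = m + s * rng.normal(0, 0.5, K)
    log_sigma = np.log(s) + rng.normal(0, 0.3, K)
    log_num1 = np.log(29.0) + rng.normal(0, 0.3, K)
    cur = logpost(mu, log_sigma, log_num1)
    scale = np.full(K, 0.5)
    base = np.array([s / np.sqrt(d.size), 0.1, 0.5])

    S = np.empty((K, draws, 3))
    kept = 0
    for t_i in range(warmup + draws):
        in_warmup = t_i < warmup
        gain = 2.0 / (t_i + 20.0) ** 0.6 if in_warmup else 0.0
        eps = rng.standard_normal((K, 3)) * base * scale[:, None]
        p_mu, p_ls, p_ln = mu + eps[:, 0], log_sigma + eps[:, 1], log_num1 + eps[:, 2]
        new = logpost(p_mu, p_ls, p_ln)
        acc = np.log(rng.random(K)) < new - cur
        mu = np.where(acc, p_mu, mu)
        log_sigma = np.where(acc, p_ls, log_sigma)
        log_num1 = np.where(acc, p_ln, log_num1)
        cur = np.where(acc, new, cur)
        if in_warmup:
            scale *= np.exp(gain * (acc.astype(float) - 0.3))
        else:
            S[:, kept] = np.stack([mu, np.exp(log_sigma), 1.0 + np.exp(log_num1)], axis=1)
            kept += 1

    import arviz as az

    mu_d, sigma_d, nu_d = S[..., 0], S[..., 1], S[..., 2]
    flat = mu_d.ravel()
    hdi_arr = np.asarray(az.hdi(mu_d.ravel(), hdi_prob=0.95)).ravel()
    hdi = (float(hdi_arr[0]), float(hdi_arr[1]))
    diagnostics = {"rhat_mu": float(az.rhat(mu_d)), "ess_mu": float(az.ess(mu_d))}
    return BESTResult(
        prob_above_zero=float(np.mean(flat > 0)),
        posterior_median_mu=float(np.median(flat)),
        hdi95=hdi,
        n_iterations=int(mu_d.size),
        mu=mu_d,
        sigma=sigma_d,
        nu=nu_d,
        diagnostics=diagnostics,
    )


@dataclass
class PairedTResult:
    t: float
    df: int
    p: float
    g_av: float
    g_av_ci: tuple[float, float]
    mean_diff: float


def paired_t(x: np.ndarray, y: np.ndarray) -> PairedTResult:
    """Classical paired t-test with the averaged-SD Hedges effect size.

    g_av = mean(x - y) / ((SD(x) + SD(y)) / 2), bias-corrected by
    J = 1 - 3 / (4 df - 1); its 95% CI is obtained by inverting the
    noncentral-t distribution of the observed t statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length vectors with n >= 2")
    d = x - y
    n = d.size
    sd_d = d.std(ddof=1)
    if sd_d == 0:
        raise ValueError("zero-variance differences: t undefined")
    t_stat = d.mean() / (sd_d / np.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t_stat), df)
    s_av = (x.std(ddof=1) + y.std(ddof=1)) / 2.0
    J = 1.0 - 3.0 / (4.0 * df - 1.0)
    g_av = J * d.mean() / s_av

    # noncentral-t inversion for the CI of the standardized effect
    def _cdf(nc: float) -> float:
        v = stats.nct.cdf(t_stat, df, nc)
        if np.isnan(v):  # extreme noncentrality underflow
            return 0.0 if nc > t_stat else 1.0
        return float(v)

    def ncp_for(q: float, t_obs: float) -> float:
        f = lambda nc: _cdf(nc) - q
        half = 4.0
        lo, hi = t_obs - half, t_obs + half
        while f(lo) < 0:
            lo -= half
        while f(hi) > 0:
            hi += half
        return optimize.brentq(f, lo, hi)

    ncp_lo = ncp_for(0.975, t_stat)
    ncp_hi = ncp_for(0.025, t_stat)
    # convert d_z-scale bounds to the g_av metric
    ratio = (sd_d / s_av) * J / np.sqrt(n)
    ci = (float(ncp_lo * ratio), float(ncp_hi * ratio))
    return PairedTResult(float(t_stat), df, float(p), float(g_av), ci, float(d.mean()))


@dataclass
class RMAnovaResult:
    F: float
    df_num: float
    df_den: float
    p: float
    partial_eta_squared: float
    eps: float
    mauchly_W: float | None
    mauchly_p: float | None
    posthoc: pd.DataFrame


def rm_anova(matrix: np.ndarray | pd.DataFrame, correct_posthoc: bool = False) -> RMAnovaResult:
    """One-way within-subject ANOVA on a participants x conditions matrix.

    Applies the Greenhouse-Geisser epsilon to the degrees of freedom
    (reported F is unchanged), reports partial eta squared and Mauchly's
    sphericity test, and runs all-pairs post-hoc paired t-tests
    (uncorrected by default; Holm with ``correct_posthoc=True``).
    """
    import pingouin as pg

    if isinstance(matrix, pd.DataFrame):
        conditions = list(matrix.columns)
        arr = matrix.to_numpy(dtype=float)
    else:
        arr = np.asarray(matrix, dtype=float)
        conditions = [f"c{i}" for i in range(arr.shape[1])]
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("need a participants x conditions matrix with >= 2 conditions")
    if not np.all(np.isfinite(arr)):
        raise ValueError("incomplete rows: repeated-measures ANOVA requires complete cases")

    n, c = arr.shape
    centered = arr - arr.mean(axis=1, keepdims=True)
    if np.allclose(centered.var(axis=0).sum() + centered.mean(axis=0).var(), 0.0):
        # no within-subject condition variation at all: F defined as 0
        posthoc = pd.DataFrame(columns=["a", "b", "t", "df", "p"])
        return RMAnovaResult(0.0, float(c - 1), float((c - 1) * (n - 1)), 1.0,
                             0.0, 1.0, None, None, posthoc)
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), c),
            "condition": np.tile(conditions, n),
            "value": arr.ravel(),
        }
    )
    aov = pg.rm_anova(
        data=long, dv="value", within="condition", subject="subject",
        correction=True, effsize="np2", detailed=False,
    )
    row = aov.iloc[0]
    eps = 1.0
    if "eps" in aov.columns and np.isfinite(row["eps"]):
        eps = float(row["eps"])
    f_val = float(row["F"])
    df1, df2 = float(row["ddof1"]), float(row["ddof2"])
    p_val = float(row["p_unc"])
    if "p_GG_corr" in aov.columns and np.isfinite(row["p_GG_corr"]):
        p_val = float(row["p_GG_corr"])
    mW = float(row["W_spher"]) if "W_spher" in aov.columns and c > 2 else None
    mp = float(row["p_spher"]) if "p_spher" in aov.columns and c > 2 else None

    rows = []
    from itertools import combinations

    for i, j in combinations(range(c), 2):
        res = stats.ttest_rel(arr[:, i], arr[:, j])
        rows.append(
            {
                "a": conditions[i],
                "b": conditions[j],
                "t": float(res.statistic),
                "df": n - 1,
                "p": float(res.pvalue),
            }
        )
    posthoc = pd.DataFrame(rows)
    if correct_posthoc and len(posthoc):
        from .associations import holm_correct

        posthoc["p_c"] = holm_correct(posthoc["p"].to_numpy())

    return RMAnovaResult(
        F=f_val,
        df_num=df1 * eps,
        df_den=df2 * eps,
        p=p_val,
        partial_eta_squared=float(row["np2"]),
        eps=eps,
        mauchly_W=mW,
        mauchly_p=mp,
        posthoc=posthoc,
    )


@dataclass
class FramingTestReport:
    """Bundle of Bayesian and frequentist effect tests for one contrast."""

    label: str
    best: BESTResult | None = None
    paired: PairedTResult | None = None
    anova: RMAnovaResult | None = None

    def to_dict(self) -> dict:
        out: dict = {"label": self.label}
        if self.best is not None:
            out["best"] = {
                "prob_above_zero": self.best.prob_above_zero,
                "posterior_median_mu": self.best.posterior_median_mu,
                "hdi95": list(self.best.hdi95),
                "n_iterations": self.best.n_iterations,
            }
        if self.paired is not None:
            out["paired_t"] = {
                "t": self.paired.t,
                "df": self.paired.df,
                "p": self.paired.p,
                "g_av": self.paired.g_av,
                "g_av_ci": list(self.paired.g_av_ci),
            }
        if self.anova is not None:
            out["rm_anova"] = {
                "F": self.anova.F,
                "df_num": self.anova.df_num,
                "df_den": self.anova.df_den,
                "p": self.anova.p,
                "partial_eta_squared": self.anova.partial_eta_squared,
            }
        return out
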