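"""Adaptive Metropolis-within-Gibbs engine for the hierarchical choice model.

Design: participant-level parameter vectors (ln k per condition, ln tau,
and logit beta for the quasi-hyperbolic family) are updated with vectorized
random-walk Metropolis proposals whose step sizes adapt per participant
during warmup. Group means are updated by exact conjugate Gibbs steps given
the participant values; group SDs and the condition correlation matrix
(canonical-partial-correlation parameterization with an LKJ-type prior) use
adaptive random-walk Metropolis. Chains are vectorized in the leading axis.

Priors:
    mu_lnk[c]   ~ Normal(-4, 3)
    sd_lnk[c]   ~ Half-Normal(2)
    corr(ln k)  ~ LKJ-type (eta = 2) on canonical partial correlations
    ln tau_i    ~ Normal(mu_lntau, sd_lntau),  mu ~ N(0,1), sd ~ Half-Normal(1)
    logit beta_i~ Normal(mu_lbeta, sd_lbeta),  mu ~ N(1.5,1), sd ~ Half-Normal(1)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

# group-level prior constants
MU0, MU0_SD = -4.0, 3.0
SD_SCALE = 2.0
LKJ_ETA = 2.0
MUTAU0, MUTAU0_SD, SDTAU_SCALE = 0.0, 1.0, 1.0
MUB0, MUB0_SD, SDB_SCALE = 1.5, 1.0, 1.0

FRAME_ORDER = ["delay", "date"]
BAND_ORDER = ["small", "medium", "large"]


@dataclass
class ObsData:
    """Choice observations sorted by participant, ready for vector math."""

    p_idx: np.ndarray       # (N,) participant index, sorted ascending
    c_idx: np.ndarray       # (N,) condition index
    ysign: np.ndarray       # (N,) +1 chose larger-later, -1 smaller-sooner
    a_ss: np.ndarray
    d_ss: np.ndarray
    a_ll: np.ndarray
    d_ll: np.ndarray
    starts: np.ndarray      # (n,) reduceat boundaries per participant
    n: int
    C: int
    participants: list
    conditions: list
    condition_var: str
    row_order: np.ndarray   # original table positions of each observation


def prepare_obs(table: pd.DataFrame, condition_var: str) -> ObsData:
    codes, uniques = pd.factorize(table["participant_id"], sort=True)
    order = FRAME_ORDER if condition_var == "frame" else BAND_ORDER
    present = [c for c in order if c in set(table[condition_var])]
    extra = set(table[condition_var]) - set(order)
    if extra:
        raise ValueError(f"unknown {condition_var} levels: {sorted(extra)}")
    if len(present) < 2:
        raise ValueError(f"need at least two {condition_var} levels")
    cmap = {c: i for i, c in enumerate(present)}
    c_codes = table[condition_var].map(cmap).to_numpy()

    counts = np.zeros((len(uniques), len(present)), dtype=int)
    np.add.at(counts, (codes, c_codes), 1)
    if (counts == 0).any():
        p_i, c_i = np.argwhere(counts == 0)[0]
        raise ValueError(
            f"participant {uniques[p_i]!r} has no observations in "
            f"{condition_var}={present[c_i]!r}"
        )

    sorter = np.argsort(codes, kind="stable")
    p_sorted = codes[sorter]
    starts = np.searchsorted(p_sorted, np.arange(len(uniques)))
    sub = table.iloc[sorter]
    return ObsData(
        p_idx=p_sorted,
        c_idx=c_codes[sorter],
        ysign=(2.0 * sub["choice"].to_numpy(dtype=float) - 1.0),
        a_ss=sub["ss_amount"].to_numpy(dtype=float),
        d_ss=sub["ss_delay_days"].to_numpy(dtype=float),
        a_ll=sub["ll_amount"].to_numpy(dtype=float),
        d_ll=sub["ll_delay_days"].to_numpy(dtype=float),
        starts=starts,
        n=len(uniques),
        C=len(present),
        participants=list(uniques),
        conditions=present,
        condition_var=condition_var,
        row_order=sorter,
    )


def _values(a, d, k, family, beta=None):
    if family == "hyperbolic":
        return a / (1.0 + k * d)
    if family == "exponential":
        return a * np.exp(-k * d)
    # quasi-hyperbolic with delta = exp(-k): V = A at D=0 else A*beta*exp(-kD)
    return np.where(d == 0, a, a * beta * np.exp(-k * d))


def obs_loglik(lnk, lntau, lbeta, data: ObsData, family: str) -> np.ndarray:
    """Per-observation Bernoulli log-likelihood, shape (K, N)."""
    k = np.exp(lnk[:, data.p_idx, data.c_idx])
    beta = None
    if family == "quasi_hyperbolic":
        beta = 1.0 / (1.0 + np.exp(-lbeta[:, data.p_idx]))
    v_ll = _values(data.a_ll, data.d_ll, k, family, beta)
    v_ss = _values(data.a_ss, data.d_ss, k, family, beta)
    tau = np.exp(lntau[:, data.p_idx])
    x = data.ysign * tau * (v_ll - v_ss)
    return -np.logaddexp(0.0, -x)


def participant_loglik(lnk, lntau, lbeta, data: ObsData, family: str) -> np.ndarray:
    """Log-likelihood summed per participant, shape (K, n)."""
    return np.add.reduceat(obs_loglik(lnk, lntau, lbeta, data, family), data.starts, axis=1)


# ---------------------------------------------------------------- correlation

def corr_from_cpc(z: np.ndarray, C: int) -> np.ndarray:
    """Correlation matrix from canonical partial correlations (strict lower)."""
    L = np.zeros((C, C))
    L[0, 0] = 1.0
    idx = 0
    for i in range(1, C):
        rem = 1.0
        for j in range(i):
            L[i, j] = z[idx] * np.sqrt(rem)
            rem -= L[i, j] ** 2
            idx += 1
        L[i, i] = np.sqrt(max(rem, 1e-12))
    return L @ L.T


def _cpc_beta_shapes(C: int) -> np.ndarray:
    shapes = []
    for i in range(1, C):
        for j in range(i):
            shapes.append(LKJ_ETA + (C - 1 - (j + 1)) / 2.0)
    return np.array(shapes)


def _halfnormal_lp(x, scale):
    return -0.5 * np.sum((x / scale) ** 2)


class _GroupState:
    """Per-chain covariance cache for the participant ln_k prior."""

    def __init__(self, K: int, C: int):
        self.K, self.C = K, C
        self.Sigma_inv = np.tile(np.eye(C), (K, 1, 1))
        self.logdet = np.zeros(K)
        self.chol = np.tile(np.eye(C), (K, 1, 1))

    def update(self, k, sd, R):
        Sigma = np.outer(sd, sd) * R
        try:
            L = np.linalg.cholesky(Sigma)
        except np.linalg.LinAlgError:
            return False
        Linv = np.linalg.inv(L)
        self.Sigma_inv[k] = Linv.T @ Linv
        self.logdet[k] = 2.0 * np.sum(np.log(np.diag(L)))
        self.chol[k] = L
        return True


def run(
    data: ObsData,
    family: str,
    chains: int = 4,
    warmup: int = 1000,
    draws: int = 1000,
    thin: int = 1,
    seed: int | None = None,
    target_accept: float = 0.30,
):
    from .discounting import PosteriorFit

    rng = np.random.default_rng(seed)
    K, n, C = chains, data.n, data.C
    qh = family == "quasi_hyperbolic"
    M = C * (C - 1) // 2
    cpc_shapes = _cpc_beta_shapes(C)

    # initial values, overdispersed across chains
    lnk = rng.normal(-4.0, 1.0, (K, 1, 1)) + rng.normal(0.0, 0.5, (K, n, C))
    lntau = rng.normal(-0.7, 0.3, (K, n))
    lbeta = rng.normal(1.5, 0.3, (K, n)) if qh else None
    mu = lnk.mean(axis=1)
    log_sd = np.zeros((K, C))
    u_corr = np.zeros((K, M))
    mu_tau = lntau.mean(axis=1)
    log_sd_tau = np.full(K, np.log(0.5))
    if qh:
        mu_b = lbeta.mean(axis=1)
        log_sd_b = np.full(K, np.log(0.5))

    grp = _GroupState(K, C)
    for k in range(K):
        grp.update(k, np.exp(log_sd[k]), corr_from_cpc(np.tanh(u_corr[k]), C))

    def participant_logprior(lnk_, lntau_, lbeta_):
        dev = lnk_ - mu[:, None, :]
        q = np.einsum("knc,kcd,knd->kn", dev, grp.Sigma_inv, dev)
        sd_tau = np.exp(log_sd_tau)
        lp = -0.5 * q - 0.5 * grp.logdet[:, None]
        lp += (
            -0.5 * ((lntau_ - mu_tau[:, None]) / sd_tau[:, None]) ** 2
            - log_sd_tau[:, None]
        )
        if qh:
            sd_b = np.exp(log_sd_b)
            lp += (
                -0.5 * ((lbeta_ - mu_b[:, None]) / sd_b[:, None]) ** 2
                - log_sd_b[:, None]
            )
        return lp

    cur_ll = participant_loglik(lnk, lntau, lbeta, data, family)
    cur_lp = participant_logprior(lnk, lntau, lbeta)

    step_p = np.full((K, n), 0.25)
    step_sig = np.full(K, 0.15)
    step_st = np.full(K, 0.3)
    step_sb = np.full(K, 0.3) if qh else None
    step_scale_all = np.full(K, 0.5 / np.sqrt(n))
    step_scale_c = np.full((K, C), 0.8 / np.sqrt(n))

    n_keep = draws
    S_mu = np.empty((K, n_keep, C))
    S_sd = np.empty((K, n_keep, C))
    S_u = np.empty((K, n_keep, M))
    S_mt = np.empty((K, n_keep))
    S_st = np.empty((K, n_keep))
    S_lnk = np.empty((K, n_keep, n, C), dtype=np.float32)
    S_ltau = np.empty((K, n_keep, n), dtype=np.float32)
    S_lb = np.empty((K, n_keep, n), dtype=np.float32) if qh else None
    S_mb = np.empty((K, n_keep)) if qh else None

    V0inv = np.eye(C) / MU0_SD**2
    V0inv_m0 = V0inv @ np.full(C, MU0)

    def _theta_to_sigma(theta):
        sd = np.exp(theta[:C])
        R = corr_from_cpc(np.tanh(theta[C:]), C)
        return np.outer(sd, sd) * R

    _tril = np.tril_indices(C)

    def _log_jac_theta(theta, h=1e-6):
        """log |d vech(Sigma) / d theta| by central differences (C <= 3)."""
        D = C + M
        J = np.empty((D, D))
        for j in range(D):
            e = np.zeros(D)
            e[j] = h
            J[:, j] = (
                _theta_to_sigma(theta + e)[_tril] - _theta_to_sigma(theta - e)[_tril]
            ) / (2 * h)
        sign, logdet = np.linalg.slogdet(J)
        return logdet if sign != 0 else -np.inf

    def _sigma_to_theta(Sigma):
        sd = np.sqrt(np.diag(Sigma))
        R = Sigma / np.outer(sd, sd)
        L = np.linalg.cholesky(R)
        z = np.empty(M)
        idx = 0
        for i in range(1, C):
            rem = 1.0
            for j in range(i):
                z[idx] = L[i, j] / np.sqrt(rem)
                rem -= L[i, j] ** 2
                idx += 1
        return np.concatenate([np.log(sd), np.arctanh(np.clip(z, -0.999999, 0.999999))])

    def sigma_target(k, log_sd_k, u_k):
        sd = np.exp(log_sd_k)
        z = np.tanh(u_k)
        R = corr_from_cpc(z, C)
        Sigma = np.outer(sd, sd) * R
        try:
            L = np.linalg.cholesky(Sigma)
        except np.linalg.LinAlgError:
            return -np.inf, None
        Linv = np.linalg.inv(L)
        Sinv = Linv.T @ Linv
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        dev = lnk[k] - mu[k]
        q = np.einsum("nc,cd,nd->", dev, Sinv, dev)
        lp = -0.5 * q - 0.5 * n * logdet
        lp += _halfnormal_lp(sd, SD_SCALE) + np.sum(log_sd_k)       # prior+jacobian
        lp += np.sum(cpc_shapes * np.log1p(-z**2))                  # lkj-type + tanh jac
        return lp, (Sinv, logdet, R, sd)

    cur_sig_lp = np.empty(K)
    cur_R = np.empty((K, C, C))
    for k in range(K):
        cur_sig_lp[k], aux = sigma_target(k, log_sd[k], u_corr[k])
        cur_R[k] = aux[2]

    def scalar_sd_target(vals, mu_v, log_sd_v, scale):
        sd = np.exp(log_sd_v)
        resid = vals - mu_v[:, None]
        return (
            -0.5 * np.sum(resid**2, axis=1) / sd**2
            - n * log_sd_v
            - 0.5 * (sd / scale) ** 2
            + log_sd_v
        )

    total = warmup + draws * thin
    acc_p_sum = np.zeros((K, n))
    kept = 0
    for t in range(total):
        in_warmup = t < warmup
        gain = 2.0 / (t + 20.0) ** 0.6 if in_warmup else 0.0

        # --- participant block (random-walk MH, vectorized) ---
        for _ in range(2):
            prop_lnk = lnk + step_p[:, :, None] * rng.standard_normal((K, n, C))
            prop_ltau = lntau + 0.6 * step_p * rng.standard_normal((K, n))
            prop_lb = (
                lbeta + 0.6 * step_p * rng.standard_normal((K, n)) if qh else None
            )
            prop_ll = participant_loglik(prop_lnk, prop_ltau, prop_lb, data, family)
            prop_lp = participant_logprior(prop_lnk, prop_ltau, prop_lb)
            logr = (prop_ll + prop_lp) - (cur_ll + cur_lp)
            acc = np.log(rng.random((K, n))) < logr
            lnk = np.where(acc[:, :, None], prop_lnk, lnk)
            lntau = np.where(acc, prop_ltau, lntau)
            if qh:
                lbeta = np.where(acc, prop_lb, lbeta)
            cur_ll = np.where(acc, prop_ll, cur_ll)
            cur_lp = np.where(acc, prop_lp, cur_lp)
            if in_warmup:
                step_p *= np.exp(gain * (acc.astype(float) - target_accept))
            else:
                acc_p_sum += acc

        # prior-refresh independence move: propose ln k from the conditional
        # prior N(mu, Sigma); the prior cancels, so acceptance is the pure
        # likelihood ratio -- it refreshes weakly-identified participants
        # (e.g. all-larger-later responders) that random walks move slowly
        z = rng.standard_normal((K, n, C))
        prop_lnk = mu[:, None, :] + np.einsum("kcd,knd->knc", grp.chol, z)
        prop_ll = participant_loglik(prop_lnk, lntau, lbeta, data, family)
        acc = np.log(rng.random((K, n))) < (prop_ll - cur_ll)
        lnk = np.where(acc[:, :, None], prop_lnk, lnk)
        cur_ll = np.where(acc, prop_ll, cur_ll)
        cur_lp = participant_logprior(lnk, lntau, lbeta)

        # --- group means: conjugate Gibbs ---
        for k in range(K):
            prec = V0inv + n * grp.Sigma_inv[k]
            b = V0inv_m0 + grp.Sigma_inv[k] @ lnk[k].sum(axis=0)
            Lp = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, b)
            mu[k] = mean + np.linalg.solve(Lp.T, rng.standard_normal(C))
        cur_lp = participant_logprior(lnk, lntau, lbeta)
        for k in range(K):
            cur_sig_lp[k], _aux = sigma_target(k, log_sd[k], u_corr[k])

        # --- group covariance: independence MH from the inverse-Wishart
        # conditional likelihood of the deviations (acceptance corrects for
        # the half-normal/LKJ prior), plus a random-walk sweep as fallback ---
        if n > 2 * C + 2:
            from scipy.stats import invwishart

            df_iw = n - C - 1
            for k in range(K):
                dev = lnk[k] - mu[k]
                S_dev = dev.T @ dev + 1e-10 * np.eye(C)
                try:
                    Sig_star = invwishart.rvs(
                        df=df_iw, scale=S_dev,
                        random_state=np.random.RandomState(rng.integers(2**31)),
                    )
                    theta_star = _sigma_to_theta(Sig_star)
                except (np.linalg.LinAlgError, FloatingPointError, ValueError):
                    continue
                lp_star, aux = sigma_target(k, theta_star[:C], theta_star[C:])
                if not np.isfinite(lp_star):
                    continue
                theta_cur = np.concatenate([log_sd[k], u_corr[k]])
                Sig_cur = _theta_to_sigma(theta_cur)
                q_star = invwishart.logpdf(Sig_star, df=df_iw, scale=S_dev) + _log_jac_theta(theta_star)
                q_cur = invwishart.logpdf(Sig_cur, df=df_iw, scale=S_dev) + _log_jac_theta(theta_cur)
                if np.log(rng.random()) < (lp_star + q_cur) - (cur_sig_lp[k] + q_star):
                    log_sd[k], u_corr[k] = theta_star[:C], theta_star[C:]
                    cur_sig_lp[k] = lp_star
                    grp.Sigma_inv[k], grp.logdet[k], cur_R[k] = aux[0], aux[1], aux[2]
                    grp.chol[k] = np.linalg.cholesky(
                        np.outer(aux[3], aux[3]) * aux[2]
                    )
        for _ in range(2):
            for k in range(K):
                prop_ls = log_sd[k] + step_sig[k] * rng.standard_normal(C)
                prop_u = (
                    u_corr[k] + step_sig[k] * rng.standard_normal(M) if M else u_corr[k]
                )
                lp_new, aux = sigma_target(k, prop_ls, prop_u)
                if np.log(rng.random()) < lp_new - cur_sig_lp[k]:
                    log_sd[k], u_corr[k] = prop_ls, prop_u
                    cur_sig_lp[k] = lp_new
                    grp.Sigma_inv[k], grp.logdet[k], cur_R[k] = aux[0], aux[1], aux[2]
                    grp.chol[k] = np.linalg.cholesky(np.outer(aux[3], aux[3]) * aux[2])
                    if in_warmup:
                        step_sig[k] *= np.exp(gain * (1.0 - target_accept))
                elif in_warmup:
                    step_sig[k] *= np.exp(gain * (0.0 - target_accept))

        # joint scale moves: rescale participant ln k deviations and group SDs
        # together (the MVN prior change cancels against the Jacobian, so only
        # the likelihood and the SD priors enter). One move scales all
        # conditions, then one per condition; adaptive n-scaled steps keep
        # sd_lnk mixing healthy as the number of participants grows
        for c_move in range(-1, C):
            sl = slice(None) if c_move < 0 else slice(c_move, c_move + 1)
            step = step_scale_all if c_move < 0 else step_scale_c[:, c_move]
            eps_c = step * rng.standard_normal(K)
            gam = np.exp(eps_c)
            prop_lnk = lnk.copy()
            prop_lnk[:, :, sl] = mu[:, None, sl] + gam[:, None, None] * (
                lnk[:, :, sl] - mu[:, None, sl]
            )
            prop_ll = participant_loglik(prop_lnk, lntau, lbeta, data, family)
            sd_sel = np.exp(log_sd[:, sl])
            logr = (
                (prop_ll - cur_ll).sum(axis=1)
                - 0.5 * ((gam[:, None] ** 2 - 1.0) * (sd_sel / SD_SCALE) ** 2).sum(axis=1)
                + (1 if c_move >= 0 else C) * eps_c
            )
            accC = np.log(rng.random(K)) < logr
            if in_warmup:
                adj = np.exp(gain * (accC.astype(float) - target_accept))
                if c_move < 0:
                    step_scale_all *= adj
                else:
                    step_scale_c[:, c_move] *= adj
            if accC.any():
                lnk = np.where(accC[:, None, None], prop_lnk, lnk)
                cur_ll = np.where(accC[:, None], prop_ll, cur_ll)
                log_sd[accC, sl] += eps_c[accC, None]
                for k in np.flatnonzero(accC):
                    grp.update(k, np.exp(log_sd[k]), cur_R[k])
                    cur_sig_lp[k], _aux = sigma_target(k, log_sd[k], u_corr[k])

        # --- tau hierarchy: Gibbs mean, MH sd ---
        sd_tau = np.exp(log_sd_tau)
        post_var = 1.0 / (1.0 / MUTAU0_SD**2 + n / sd_tau**2)
        post_mean = post_var * (MUTAU0 / MUTAU0_SD**2 + lntau.sum(axis=1) / sd_tau**2)
        mu_tau = post_mean + np.sqrt(post_var) * rng.standard_normal(K)
        for _ in range(5):
            prop = log_sd_tau + step_st * rng.standard_normal(K)
            lp_cur = scalar_sd_target(lntau, mu_tau, log_sd_tau, SDTAU_SCALE)
            lp_new = scalar_sd_target(lntau, mu_tau, prop, SDTAU_SCALE)
            acc1 = np.log(rng.random(K)) < lp_new - lp_cur
            log_sd_tau = np.where(acc1, prop, log_sd_tau)
            if in_warmup:
                step_st *= np.exp(gain * (acc1.astype(float) - target_accept))

        # joint translation / scale moves of the tau hierarchy (mu_tau and all
        # ln tau_i move together): breaks the random-walk stickiness between
        # levels; repeated at several proposal scales
        for move_scale in (0.05, 0.12):
            delta = move_scale * rng.standard_normal(K)
            prop_ltau = lntau + delta[:, None]
            prop_mu_tau = mu_tau + delta
            prop_ll = participant_loglik(lnk, prop_ltau, lbeta, data, family)
            logr = (prop_ll - cur_ll).sum(axis=1) + (
                -0.5 * ((prop_mu_tau - MUTAU0) / MUTAU0_SD) ** 2
                + 0.5 * ((mu_tau - MUTAU0) / MUTAU0_SD) ** 2
            )
            accT = np.log(rng.random(K)) < logr
            lntau = np.where(accT[:, None], prop_ltau, lntau)
            mu_tau = np.where(accT, prop_mu_tau, mu_tau)
            cur_ll = np.where(accT[:, None], prop_ll, cur_ll)

            # joint scale move: rescale participant tau deviations and sd_tau together
            eps = move_scale * rng.standard_normal(K)
            c = np.exp(eps)
            prop_ltau = mu_tau[:, None] + c[:, None] * (lntau - mu_tau[:, None])
            prop_ll = participant_loglik(lnk, prop_ltau, lbeta, data, family)
            sd_tau = np.exp(log_sd_tau)
            logr = (
                (prop_ll - cur_ll).sum(axis=1)
                - 0.5 * (c**2 - 1.0) * (sd_tau / SDTAU_SCALE) ** 2
                + eps
            )
            accS = np.log(rng.random(K)) < logr
            lntau = np.where(accS[:, None], prop_ltau, lntau)
            log_sd_tau = np.where(accS, log_sd_tau + eps, log_sd_tau)
            cur_ll = np.where(accS[:, None], prop_ll, cur_ll)

        if qh:
            sd_b = np.exp(log_sd_b)
            post_var = 1.0 / (1.0 / MUB0_SD**2 + n / sd_b**2)
            post_mean = post_var * (MUB0 / MUB0_SD**2 + lbeta.sum(axis=1) / sd_b**2)
            mu_b = post_mean + np.sqrt(post_var) * rng.standard_normal(K)
            prop = log_sd_b + step_sb * rng.standard_normal(K)
            lp_cur = scalar_sd_target(lbeta, mu_b, log_sd_b, SDB_SCALE)
            lp_new = scalar_sd_target(lbeta, mu_b, prop, SDB_SCALE)
            acc2 = np.log(rng.random(K)) < lp_new - lp_cur
            log_sd_b = np.where(acc2, prop, log_sd_b)
            if in_warmup:
                step_sb *= np.exp(gain * (acc2.astype(float) - target_accept))

        cur_lp = participant_logprior(lnk, lntau, lbeta)

        if not in_warmup and (t - warmup) % thin == thin - 1 and kept < n_keep:
            S_mu[:, kept] = mu
            S_sd[:, kept] = np.exp(log_sd)
            if M:
                S_u[:, kept] = u_corr
            S_mt[:, kept] = mu_tau
            S_st[:, kept] = np.exp(log_sd_tau)
            S_lnk[:, kept] = lnk
            S_ltau[:, kept] = lntau
            if qh:
                S_lb[:, kept] = lbeta
                S_mb[:, kept] = mu_b
            kept += 1

    corr_draws = np.empty((K, n_keep, C, C))
    for k in range(K):
        for s in range(n_keep):
            corr_draws[k, s] = corr_from_cpc(np.tanh(S_u[k, s]), C) if M else np.eye(C)

    diagnostics = _diagnose(S_mu, S_sd, S_mt, S_st, data.conditions)
    diagnostics["accept_rate_participants"] = float(
        (acc_p_sum / max(1, 2 * draws * thin)).mean()
    )
    return PosteriorFit(
        family=family,
        condition_var=data.condition_var,
        conditions=list(data.conditions),
        participants=list(data.participants),
        mu=S_mu,
        sd=S_sd,
        corr=corr_draws,
        mu_tau=S_mt,
        sd_tau=S_st,
        ln_k=S_lnk,
        ln_tau=S_ltau,
        diagnostics=diagnostics,
        seed=seed,
        logit_beta=S_lb,
        mu_beta=S_mb,
        _data=data,
    )


def _diagnose(S_mu, S_sd, S_mt, S_st, conditions) -> dict:
    import arviz as az

    rhats, esss = {}, {}
    for c_i, c in enumerate(conditions):
        rhats[f"mu_lnk[{c}]"] = float(az.rhat(S_mu[..., c_i]))
        esss[f"mu_lnk[{c}]"] = float(az.ess(S_mu[..., c_i]))
        rhats[f"sd_lnk[{c}]"] = float(az.rhat(S_sd[..., c_i]))
        esss[f"sd_lnk[{c}]"] = float(az.ess(S_sd[..., c_i]))
    rhats["mu_lntau"] = float(az.rhat(S_mt))
    esss["mu_lntau"] = float(az.ess(S_mt))
    rhats["sd_lntau"] = float(az.rhat(S_st))
    esss["sd_lntau"] = float(az.ess(S_st))
    max_rhat = max(rhats.values())
    return {
        "rhat": rhats,
        "ess": esss,
        "max_rhat": max_rhat,
        "divergences": 0,
        "converged": bool(np.isfinite(max_rhat) and max_rhat <= 1.05),
    }


def pointwise_loglik(fit, batch: int = 100) -> np.ndarray:
    """Pointwise log-likelihood (total draws x observations) from stored draws."""
    data: ObsData = fit._data
    K, S = fit.ln_k.shape[:2]
    N = data.p_idx.shape[0]
    out = np.empty((K * S, N))
    lnk = fit.ln_k.reshape(K * S, data.n, fit.ln_k.shape[3]).astype(np.float64)
    ltau = fit.ln_tau.reshape(K * S, data.n).astype(np.float64)
    lb = (
        fit.logit_beta.reshape(K * S, data.n).astype(np.float64)
        if fit.logit_beta is not None
        else None
    )
    for s0 in range(0, K * S, batch):
        s1 = min(s0 + batch, K * S)
        out[s0:s1] = obs_loglik(
            lnk[s0:s1],
            ltau[s0:s1],
            lb[s0:s1] if lb is not None else None,
            data,
            fit.family,
        )
    return out
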