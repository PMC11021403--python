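"""Discount functions, the softmax choice rule, and hierarchical estimation.

The observational unit is one binary intertemporal choice. A participant's
preference is governed by a condition-specific log discount rate ``ln k``
(conditions are either the two time frames or the three reward-magnitude
bands) and an inverse temperature ``tau`` shared across conditions:

    P(choose larger-later) = logistic(tau * (V_LL - V_SS))

with ``V`` given by the hyperbolic, exponential or quasi-hyperbolic (beta-
delta) discount function. Group- and participant-level parameters are
estimated jointly by MCMC (adaptive Metropolis-within-Gibbs; see
``_sampler``), with participant ``ln k`` vectors across conditions modelled
as correlated multivariate normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .items import ChoiceItem

FAMILIES = ("hyperbolic", "exponential", "quasi_hyperbolic")

CHOICE_COLUMNS = [
    "participant_id",
    "item_id",
    "frame",
    "ss_amount",
    "ss_delay_days",
    "ll_amount",
    "ll_delay_days",
    "magnitude_band",
    "choice",
]


@dataclass
class AgentParams:
    """Parameters of one (synthetic or estimated) decision maker.

    ``ln_k`` is either a scalar or a mapping from condition label (frame or
    magnitude band) to the condition-specific log discount rate. ``beta``
    and ``delta`` are only used by the quasi-hyperbolic family.
    """

    ln_k: float | Mapping[str, float]
    tau: float
    beta: float = 1.0
    delta: float | None = None

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not (0.0 < self.beta <= 1.0):
            raise ValueError("beta must lie in (0, 1]")
        if self.delta is not None and not (0.0 < self.delta <= 1.0):
            raise ValueError("delta must lie in (0, 1]")

    def k_for(self, condition: str | None = None) -> float:
        if isinstance(self.ln_k, Mapping):
            if condition is None or condition not in self.ln_k:
                raise KeyError(
                    f"no ln_k for condition {condition!r}; have {sorted(self.ln_k)}"
                )
            return float(np.exp(self.ln_k[condition]))
        return float(np.exp(self.ln_k))


def discount_value(amount, delay_days, k, family: str, beta: float = 1.0, delta=None):
    """Present subjective value of ``amount`` received after ``delay_days``.

    Vectorized over all numeric arguments. For the quasi-hyperbolic family
    the convention is discrete: V = A at D = 0, else A * beta * delta**D;
    when ``delta`` is omitted it is tied to k via delta = exp(-k).
    """
    amount = np.asarray(amount, dtype=float)
    delay = np.asarray(delay_days, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.any(delay < 0):
        raise ValueError("delay_days must be non-negative")
    if family != "quasi_hyperbolic" and np.any(k < 0):
        raise ValueError("discount rate k must be non-negative")
    if family == "hyperbolic":
        return amount / (1.0 + k * delay)
    if family == "exponential":
        return amount * np.exp(-k * delay)
    if family == "quasi_hyperbolic":
        if delta is None:
            delta_pow = np.exp(-k * delay)
        else:
            delta = np.asarray(delta, dtype=float)
            if np.any((delta <= 0) | (delta > 1)):
                raise ValueError("delta must lie in (0, 1]")
            delta_pow = delta**delay
        return np.where(delay == 0, amount, amount * beta * delta_pow)
    raise ValueError(f"unknown discount family {family!r}")


def subjective_value(
    amount: float,
    delay_days: float,
    params: AgentParams,
    family: str,
    condition: str | None = None,
) -> float:
    """Subjective value under an agent's parameters (scalar convenience)."""
    if amount <= 0:
        raise ValueError("amount must be positive")
    k = params.k_for(condition) if family != "quasi_hyperbolic" or params.delta is None else 0.0
    if family == "quasi_hyperbolic" and params.delta is not None:
        return float(
            discount_value(amount, delay_days, 0.0, family, params.beta, params.delta)
        )
    return float(discount_value(amount, delay_days, k, family, params.beta))


def _item_condition(item: ChoiceItem, params: AgentParams) -> str | None:
    if isinstance(params.ln_k, Mapping):
        if item.frame in params.ln_k:
            return item.frame
        if item.magnitude_band in params.ln_k:
            return item.magnitude_band
        raise KeyError(
            f"agent has no ln_k for frame {item.frame!r} or band {item.magnitude_band!r}"
        )
    return None


def choice_probability(item: ChoiceItem, params: AgentParams, family: str) -> float:
    """Probability of choosing the larger-later option under the softmax rule."""
    cond = _item_condition(item, params)
    v_ll = subjective_value(item.ll_amount, item.ll_delay_days, params, family, cond)
    v_ss = subjective_value(item.ss_amount, item.ss_delay_days, params, family, cond)
    x = params.tau * (v_ll - v_ss)
    # numerically safe logistic
    return float(np.exp(-np.logaddexp(0.0, -x)))


def validate_choice_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long choice-table schema; returns the table unchanged."""
    missing = [c for c in CHOICE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"choice table missing columns: {missing}")
    bad = ~table["choice"].isin([0, 1])
    if bad.any():
        rows = table.index[bad].tolist()[:10]
        raise ValueError(f"choice must be 0/1; offending rows: {rows}")
    dup = table.duplicated(subset=["participant_id", "item_id", "frame"])
    if dup.any():
        rows = table.index[dup].tolist()[:10]
        raise ValueError(f"duplicate participant x item x frame rows: {rows}")
    return table


@dataclass
class PosteriorFit:
    """MCMC draws from the hierarchical choice model.

    Group arrays have shape (chains, draws, ...); participant arrays
    (chains, draws, n_participants[, n_conditions]).
    """

    family: str
    condition_var: str
    conditions: list[str]
    participants: list
    mu: np.ndarray          # (K, S, C) group mean ln k per condition
    sd: np.ndarray          # (K, S, C) group SD
    corr: np.ndarray        # (K, S, C, C) condition correlation matrix
    mu_tau: np.ndarray      # (K, S) group mean of ln tau
    sd_tau: np.ndarray      # (K, S)
    ln_k: np.ndarray        # (K, S, n, C)
    ln_tau: np.ndarray      # (K, S, n)
    diagnostics: dict
    seed: int | None
    logit_beta: np.ndarray | None = None     # quasi-hyperbolic only (K, S, n)
    mu_beta: np.ndarray | None = None
    _data: object = field(default=None, repr=False)
    _loglik: np.ndarray | None = field(default=None, repr=False)

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", False))

    @property
    def n_draws(self) -> int:
        return self.mu.shape[0] * self.mu.shape[1]

    def frame_effect_draws(self) -> np.ndarray:
        """Posterior draws of mu_lnk[delay] - mu_lnk[date] (flattened)."""
        if set(self.conditions) != {"delay", "date"}:
            raise ValueError("frame effect requires a frame-conditioned fit")
        i = self.conditions.index("delay")
        j = self.conditions.index("date")
        return (self.mu[..., i] - self.mu[..., j]).ravel()

    def log_likelihood(self) -> np.ndarray:
        """Pointwise log-likelihood matrix, shape (total draws, n observations)."""
        if self._loglik is None:
            from ._sampler import pointwise_loglik

            self._loglik = pointwise_loglik(self)
        return self._loglik

    def observation_participants(self) -> np.ndarray:
        """Participant index (into ``self.participants``) per observation."""
        return self._data.p_idx

    def summary(self) -> pd.DataFrame:
        """Posterior summary of group-level parameters with diagnostics."""
        import arviz as az

        rows = []
        named = {}
        for c_i, c in enumerate(self.conditions):
            named[f"mu_lnk[{c}]"] = self.mu[..., c_i]
            named[f"sd_lnk[{c}]"] = self.sd[..., c_i]
        named["mu_lntau"] = self.mu_tau
        named["sd_lntau"] = self.sd_tau
        for name, draws in named.items():
            flat = draws.ravel()
            rows.append(
                {
                    "parameter": name,
                    "mean": float(flat.mean()),
                    "sd": float(flat.std(ddof=1)),
                    "q2.5": float(np.percentile(flat, 2.5)),
                    "q97.5": float(np.percentile(flat, 97.5)),
                    "rhat": float(az.rhat(draws)),
                    "ess": float(az.ess(draws)),
                }
            )
        return pd.DataFrame(rows)


def fit_hierarchical(
    data: pd.DataFrame,
    family: str = "hyperbolic",
    condition_var: str = "frame",
    mcmc_opts: Mapping | None = None,
    seed: int | None = None,
) -> PosteriorFit:
    """Fit the hierarchical choice model by adaptive Metropolis-within-Gibbs.

    ``data`` is a long choice table (see ``CHOICE_COLUMNS``). Every
    participant must have observations in every level of ``condition_var``.
    Sampler options (``chains``, ``warmup``, ``draws``) default to
    4 x 1000 + 1000.
    """
    from . import _sampler

    if family not in FAMILIES:
        raise ValueError(f"unknown discount family {family!r}")
    if condition_var not in ("frame", "magnitude_band"):
        raise ValueError("condition_var must be 'frame' or 'magnitude_band'")
    validate_choice_table(data)
    obs = _sampler.prepare_obs(data, condition_var)
    opts = dict(chains=4, warmup=1000, draws=1000)
    if mcmc_opts:
        opts.update(mcmc_opts)
    return _sampler.run(obs, family=family, seed=seed, **opts)


def point_estimates(fit: PosteriorFit) -> pd.DataFrame:
    """Participant-level posterior-mean estimates derived from a fit.

    Returns one row per participant with ``ln_k_<condition>`` columns and,
    when the conditions allow it, the date/delay effect
    ``dde = ln_k_delay - ln_k_date``, the magnitude effect
    ``me = ln_k_small - ln_k_large``, and per-participant WAIC.
    """
    from .model_eval import participant_waic

    means = fit.ln_k.reshape(-1, *fit.ln_k.shape[2:]).mean(axis=0)  # (n, C)
    out = pd.DataFrame({"participant_id": fit.participants})
    for c_i, c in enumerate(fit.conditions):
        out[f"ln_k_{c}"] = means[:, c_i]
    out["tau"] = np.exp(fit.ln_tau.reshape(-1, fit.ln_tau.shape[2])).mean(axis=0)
    if {"delay", "date"} <= set(fit.conditions):
        out["dde"] = out["ln_k_delay"] - out["ln_k_date"]
    if {"small", "large"} <= set(fit.conditions):
        out["me"] = out["ln_k_small"] - out["ln_k_large"]
    out["waic"] = participant_waic(fit.log_likelihood(), fit.observation_participants())
    return out
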