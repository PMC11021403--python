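"""Predictive-accuracy machinery: PSIS-LOO, elpd comparison, WAIC.

All functions operate on a pointwise log-likelihood matrix of shape
(posterior draws, observations). Pareto-smoothed importance sampling uses
the standard PSIS recipe (generalized Pareto fit to the largest importance
ratios); observations with tail-shape k > 0.7 are flagged but not refit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

PARETO_K_WARN = 0.7


@dataclass
class ElpdResult:
    """Expected log pointwise predictive density with per-observation detail."""

    elpd_estimate: float
    se: float
    pointwise: np.ndarray
    pareto_k: np.ndarray
    method: str = "psis_loo"

    @property
    def n_flagged(self) -> int:
        return int(np.sum(self.pareto_k > PARETO_K_WARN))

    @property
    def n_points(self) -> int:
        return self.pointwise.shape[0]


def _check_loglik(loglik: np.ndarray) -> np.ndarray:
    loglik = np.asarray(loglik, dtype=float)
    if loglik.ndim != 2:
        raise ValueError("log-likelihood must be a draws x observations matrix")
    if not np.all(np.isfinite(loglik)):
        raise ValueError("log-likelihood contains non-finite entries")
    return loglik


def psis_loo(loglik: np.ndarray, groups: np.ndarray | None = None) -> ElpdResult:
    """PSIS leave-one-out elpd.

    ``groups`` optionally maps observations to higher-level units
    (e.g. participants); when given, the pointwise unit is the group
    (leave-one-group-out), obtained by summing log-likelihoods within
    groups before importance weighting.
    """
    from arviz.stats import psislw

    loglik = _check_loglik(loglik)
    if loglik.shape[0] < 100:
        raise ValueError("need at least 100 posterior draws for PSIS-LOO")
    if groups is not None:
        groups = np.asarray(groups)
        uniq = np.unique(groups)
        loglik = np.column_stack([loglik[:, groups == g].sum(axis=1) for g in uniq])
    # importance log-ratios for LOO are -loglik; psislw expects samples last
    lw, k = psislw(-loglik.T, reff=1.0)
    pointwise = logsumexp(lw.T + loglik, axis=0)
    elpd = float(pointwise.sum())
    se = float(np.sqrt(pointwise.size * np.var(pointwise, ddof=1)))
    return ElpdResult(elpd, se, pointwise, np.asarray(k, dtype=float))


@dataclass
class ElpdComparison:
    elpd_diff: float
    se_diff: float
    decision: str

    @property
    def distinguishable(self) -> bool:
        return self.decision == "distinguishable"


def compare_elpd(a: ElpdResult, b: ElpdResult) -> ElpdComparison:
    """Pairwise elpd difference (a - b) with the two-SE decision rule.

    The SE of the difference is computed from the paired pointwise
    differences, which requires both results to cover the same observations
    in the same order.
    """
    if a.n_points != b.n_points:
        raise ValueError(
            f"mismatched observation sets: {a.n_points} vs {b.n_points} points"
        )
    d = a.pointwise - b.pointwise
    diff = float(d.sum())
    se = float(np.sqrt(d.size * np.var(d, ddof=1)))
    decision = (
        "distinguishable" if diff != 0.0 and abs(diff) >= 2.0 * se else "indistinguishable"
    )
    return ElpdComparison(diff, se, decision)


def waic_pointwise(loglik: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-observation lppd and effective-parameter penalty."""
    loglik = _check_loglik(loglik)
    s = loglik.shape[0]
    lppd = logsumexp(loglik, axis=0) - np.log(s)
    p_waic = np.var(loglik, axis=0, ddof=1)
    return lppd, p_waic


def participant_waic(loglik: np.ndarray, participant_index: np.ndarray) -> np.ndarray:
    """Per-participant WAIC (deviance scale; lower = better fit).

    WAIC_i = -2 * sum_{j in i} (lppd_j - p_waic_j), summing the pointwise
    terms over participant i's observations, so participant WAICs add up to
    the whole-dataset WAIC.
    """
    participant_index = np.asarray(participant_index)
    loglik = _check_loglik(loglik)
    if participant_index.shape[0] != loglik.shape[1]:
        raise ValueError("participant_index length must match observations")
    lppd, p_waic = waic_pointwise(loglik)
    contrib = -2.0 * (lppd - p_waic)
    n = int(participant_index.max()) + 1
    counts = np.bincount(participant_index, minlength=n)
    if (counts == 0).any():
        missing = np.flatnonzero(counts == 0).tolist()
        raise ValueError(f"participants with zero observations: {missing}")
    return np.bincount(participant_index, weights=contrib, minlength=n)


def waic(loglik: np.ndarray) -> float:
    """Whole-dataset WAIC on the deviance scale."""
    lppd, p_waic = waic_pointwise(loglik)
    return float(-2.0 * np.sum(lppd - p_waic))
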