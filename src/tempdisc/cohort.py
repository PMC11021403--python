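"""Synthetic study cohorts with the structure the analyses assume.

Generates (i) hyperbolic (or exponential / quasi-hyperbolic) agents whose
log discount rates carry a within-person time-framing effect and a reward-
magnitude effect and correlate weakly with latent transdiagnostic factor
scores, (ii) softmax binary choices on a two-frame item set, (iii) ordinal
questionnaire responses from a 3-factor oblique measurement model with
positively skewed thresholds, and (iv) covariates (age, gender, cognitive
ability) plus attention-check failures.

Defaults emulate the descriptive statistics of a large online discounting
study: group mean ln k about -4.8 (SD 1.8) in the delay frame, a date/delay
effect of about 0.43, a magnitude effect near 1.0, 176 questionnaire items
over eight instruments loading on anxious-depression (AD), inattention/
impulsivity/overactivity (IIO) and compulsivity/intrusive-thought (CIT)
factors, factor-discounting correlations of about 0.10, and an 8.5%
attention-check failure rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .discounting import AgentParams, discount_value
from .items import ChoiceItem, generate_item_set

FACTORS = ["AD", "IIO", "CIT"]

#: per-band deviations of ln k from its frame-level mean (sum ~ zero);
#: small minus large gives the magnitude effect, declining monotonically
#: with reward size (shape from the paired small-medium and medium-large
#: contrasts typical of large magnitude-effect studies)
DEFAULT_BAND_SHAPE = {"small": 0.53, "medium": -0.09, "large": -0.44}

DEFAULT_FACTOR_CORR = np.array(
    [
        [1.00, 0.45, 0.55],
        [0.45, 1.00, 0.45],
        [0.55, 0.45, 1.00],
    ]
)

#: scale name -> (n items, factor, n ordinal categories, primary-loading range)
DEFAULT_SCALES: dict[str, tuple[int, str, int, tuple[float, float]]] = {
    "dass": (21, "AD", 4, (0.45, 0.75)),
    "stai_t": (20, "AD", 4, (0.50, 0.75)),
    "oci_r": (18, "CIT", 5, (0.45, 0.75)),
    "olife": (33, "CIT", 2, (0.35, 0.60)),
    "tfeq_ue": (9, "IIO", 4, (0.40, 0.65)),
    "tfeq_cr": (6, "CIT", 4, (0.30, 0.55)),
    "tfeq_ee": (3, "AD", 4, (0.40, 0.65)),
    "aq": (28, "CIT", 4, (0.25, 0.50)),
    "asrs": (18, "IIO", 5, (0.45, 0.75)),
    "upps": (20, "IIO", 4, (0.40, 0.70)),
}


@dataclass
class CohortConfig:
    """Generator settings; defaults are the emulated study conditions."""

    n_participants: int = 731
    n_items: int = 27
    k_range: tuple[float, float] = (0.0016, 0.25)
    family: str = "hyperbolic"
    mu_lnk: float = -4.8
    sd_lnk: float = 1.8
    frame_effect: float = 0.43           # E[ln k delay - ln k date]
    dde_sd: float = 0.60                 # person-level SD of the frame effect
    magnitude_effect: float = 0.98       # E[ln k small - ln k large]
    me_sd: float = 0.60                  # person-level SD of the magnitude effect
    mu_lntau: float = -0.7
    sd_lntau: float = 0.35
    qh_beta_mean: float = 0.85           # quasi-hyperbolic agents only
    factor_lnk_r: tuple[float, float, float] = (0.10, 0.10, 0.04)
    factor_dde_r: tuple[float, float, float] = (0.0, 0.10, 0.0)
    fraction_fail: float = 68.0 / 800.0
    age_mean: float = 37.6
    age_sd: float = 11.4
    gender_probs: tuple[float, float, float] = (0.492, 0.480, 0.028)
    cognitive_mean: float = 8.29
    cognitive_sd: float = 3.54

    def __post_init__(self) -> None:
        problems = []
        if self.n_participants < 1:
            problems.append("n_participants must be >= 1")
        if self.n_items % 3:
            problems.append("n_items must be divisible by the 3 bands")
        if not (0 < self.k_range[0] <= self.k_range[1]):
            problems.append("k_range must be a positive ordered interval")
        if not (0 <= self.fraction_fail < 1):
            problems.append("fraction_fail must lie in [0, 1)")
        if abs(sum(self.gender_probs) - 1.0) > 1e-6:
            problems.append("gender_probs must sum to 1")
        if any(abs(r) >= 1 for r in self.factor_lnk_r):
            problems.append("factor_lnk_r entries must lie in (-1, 1)")
        if problems:
            raise ValueError("invalid cohort config: " + "; ".join(problems))

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        valid = set(cls.__dataclass_fields__)
        unknown = sorted(set(d) - valid)
        if unknown:
            raise ValueError(f"unknown cohort config keys: {unknown}")
        d = dict(d)
        for key in ("k_range", "factor_lnk_r", "factor_dde_r", "gender_probs"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


# ----------------------------------------------------------------- agents

def _corr_weights(target_r: np.ndarray, phi: np.ndarray) -> tuple[np.ndarray, float]:
    """Weights a with corr(a'F + u e, F_j) = r_j for correlated factors F."""
    a = np.linalg.solve(phi, target_r)
    expl = float(target_r @ a)
    if expl >= 1:
        raise ValueError("requested factor correlations are jointly infeasible")
    return a, float(np.sqrt(1.0 - expl))


def simulate_agents(
    config: CohortConfig,
    factor_scores: np.ndarray | None = None,
    factor_corr: np.ndarray | None = None,
    seed: int | None = None,
) -> list[AgentParams]:
    """Draw agents with frame-specific ln k correlated with factor scores."""
    rng = np.random.default_rng(seed)
    n = config.n_participants
    if factor_scores is None:
        base_std = rng.standard_normal(n)
        dde_std = rng.standard_normal(n)
    else:
        phi = DEFAULT_FACTOR_CORR if factor_corr is None else factor_corr
        a, u = _corr_weights(np.asarray(config.factor_lnk_r, dtype=float), phi)
        base_std = factor_scores @ a + u * rng.standard_normal(n)
        a2, u2 = _corr_weights(np.asarray(config.factor_dde_r, dtype=float), phi)
        dde_std = factor_scores @ a2 + u2 * rng.standard_normal(n)
    lnk_delay = config.mu_lnk + config.sd_lnk * base_std
    dde = config.frame_effect + config.dde_sd * dde_std
    tau = np.exp(rng.normal(config.mu_lntau, config.sd_lntau, n))
    agents = []
    for i in range(n):
        agents.append(
            AgentParams(
                ln_k={"delay": float(lnk_delay[i]), "date": float(lnk_delay[i] - dde[i])},
                tau=float(tau[i]),
                beta=config.qh_beta_mean if config.family == "quasi_hyperbolic" else 1.0,
            )
        )
    return agents


def band_offsets(config: CohortConfig) -> dict[str, float]:
    """Zero-mean per-band ln k deviations scaled to the configured effect."""
    shape = DEFAULT_BAND_SHAPE
    scale = config.magnitude_effect / (shape["small"] - shape["large"])
    return {b: v * scale for b, v in shape.items()}


def simulate_choices(
    items: Sequence[ChoiceItem],
    agents: Sequence[AgentParams],
    frame_effect: float = 0.0,
    seed: int | None = None,
    family: str = "hyperbolic",
    band_offsets: Mapping[str, float] | None = None,
    participant_ids: Sequence | None = None,
) -> pd.DataFrame:
    """Bernoulli choices for every agent x item under the softmax rule.

    Agents with frame-keyed ln k use their own condition parameters; agents
    with a scalar ln k use ``ln_k - frame_effect`` in the date frame.
    ``band_offsets`` adds per-magnitude-band shifts to ln k. Returns the
    long choice table.
    """
    rng = np.random.default_rng(seed)
    n_a, n_i = len(agents), len(items)
    lnk = np.empty((n_a, 2))  # columns: delay, date
    tau = np.empty(n_a)
    beta = np.empty(n_a)
    for i, ag in enumerate(agents):
        if isinstance(ag.ln_k, Mapping):
            missing = {"delay", "date"} - set(ag.ln_k)
            if missing:
                raise KeyError(
                    f"agent {i} missing ln_k for condition(s) {sorted(missing)}"
                )
            lnk[i] = (ag.ln_k["delay"], ag.ln_k["date"])
        else:
            lnk[i] = (ag.ln_k, ag.ln_k - frame_effect)
        tau[i] = ag.tau
        beta[i] = ag.beta
    f_idx = np.array([0 if it.frame == "delay" else 1 for it in items])
    # band offsets may be scalars or per-agent arrays (person-level
    # magnitude-effect variability)
    offs = np.zeros((n_a, n_i))
    if band_offsets is not None:
        for j, it in enumerate(items):
            offs[:, j] = np.asarray(band_offsets[it.magnitude_band])
    a_ss = np.array([it.ss_amount for it in items])
    d_ss = np.array([it.ss_delay_days for it in items], dtype=float)
    a_ll = np.array([it.ll_amount for it in items])
    d_ll = np.array([it.ll_delay_days for it in items], dtype=float)

    k = np.exp(lnk[:, f_idx] + offs)                     # (n_a, n_i)
    v_ll = discount_value(a_ll[None, :], d_ll[None, :], k, family, beta[:, None])
    v_ss = discount_value(a_ss[None, :], d_ss[None, :], k, family, beta[:, None])
    p_ll = 1.0 / (1.0 + np.exp(-tau[:, None] * (v_ll - v_ss)))
    y = (rng.random((n_a, n_i)) < p_ll).astype(int)

    if participant_ids is None:
        participant_ids = [f"p{i + 1:04d}" for i in range(n_a)]
    rows = pd.DataFrame(
        {
            "participant_id": np.repeat(participant_ids, n_i),
            "item_id": np.tile([it.item_id for it in items], n_a),
            "frame": np.tile([it.frame for it in items], n_a),
            "ss_amount": np.tile(a_ss, n_a),
            "ss_delay_days": np.tile(d_ss.astype(int), n_a),
            "ll_amount": np.tile(a_ll, n_a),
            "ll_delay_days": np.tile(d_ll.astype(int), n_a),
            "magnitude_band": np.tile([it.magnitude_band for it in items], n_a),
            "choice": y.ravel(),
        }
    )
    return rows


# ----------------------------------------------------------- questionnaires

def default_questionnaire_spec(seed: int = 0) -> dict:
    """Loadings, thresholds and codebook for the default 176-item battery."""
    rng = np.random.default_rng(seed)
    items, loadings, thresholds, scale_of = [], [], [], []
    base_thr = {
        2: np.array([0.8]),
        4: np.array([-0.2, 0.9, 1.8]),
        5: np.array([-0.3, 0.5, 1.2, 2.0]),
    }
    f_of = {f: i for i, f in enumerate(FACTORS)}
    for scale, (n_it, factor, n_cat, load_rng) in DEFAULT_SCALES.items():
        for j in range(n_it):
            lam = np.empty(3)
            primary = rng.uniform(*load_rng)
            for f in range(3):
                lam[f] = primary if f == f_of[factor] else rng.uniform(-0.05, 0.15)
            items.append(f"{scale}_{j + 1:02d}")
            loadings.append(lam)
            thresholds.append(base_thr[n_cat] + rng.normal(0, 0.15, n_cat - 1))
            scale_of.append(scale)
    return {
        "items": items,
        "loadings": np.array(loadings),
        "thresholds": thresholds,
        "factor_corr": DEFAULT_FACTOR_CORR.copy(),
        "codebook": pd.DataFrame(
            {
                "item": items,
                "scale": scale_of,
                "factor": [
                    DEFAULT_SCALES[s][1] for s in scale_of
                ],
                "n_categories": [DEFAULT_SCALES[s][2] for s in scale_of],
            }
        ),
    }


def simulate_questionnaires(
    n: int,
    loadings: np.ndarray,
    factor_corr: np.ndarray,
    thresholds: Sequence[np.ndarray],
    seed: int | None = None,
    factor_scores: np.ndarray | None = None,
    item_names: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Ordinal item responses from an oblique common-factor model.

    Latent item value = loadings . factor + unique normal noise with unique
    variance 1 - communality; responses are the latent values discretized at
    the per-item thresholds (strictly increasing). Returns (responses, true
    factor scores).
    """
    loadings = np.asarray(loadings, dtype=float)
    factor_corr = np.asarray(factor_corr, dtype=float)
    p, nf = loadings.shape
    if factor_corr.shape != (nf, nf) or not np.allclose(factor_corr, factor_corr.T):
        raise ValueError("factor_corr must be symmetric with matching size")
    if np.linalg.eigvalsh(factor_corr).min() <= 0:
        raise ValueError("factor_corr must be positive definite")
    for t in thresholds:
        t = np.asarray(t)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("thresholds must be strictly increasing per item")
    comm = np.einsum("pf,fg,pg->p", loadings, factor_corr, loadings)
    if np.any(comm > 1.0 + 1e-9):
        bad = np.flatnonzero(comm > 1.0 + 1e-9).tolist()
        raise ValueError(f"communality > 1 (Heywood input) for items {bad}")
    rng = np.random.default_rng(seed)
    if factor_scores is None:
        L = np.linalg.cholesky(factor_corr)
        factor_scores = rng.standard_normal((n, nf)) @ L.T
    latent = factor_scores @ loadings.T + rng.standard_normal((n, p)) * np.sqrt(
        np.maximum(1.0 - comm, 0.0)
    )
    resp = np.empty((n, p), dtype=int)
    for j in range(p):
        resp[:, j] = np.searchsorted(np.asarray(thresholds[j]), latent[:, j])
    names = list(item_names) if item_names is not None else [f"item_{j+1:03d}" for j in range(p)]
    return pd.DataFrame(resp, columns=names), factor_scores


# ----------------------------------------------------------------- cohort

def generate_cohort(config: CohortConfig | Mapping | None = None, seed: int | None = None) -> dict:
    """Complete synthetic study: choices, cohort table, codebook, truth.

    Returns a dict with keys ``choices`` (long choice table), ``cohort``
    (covariates + item responses + attention flag), ``codebook``, ``items``,
    ``agents``, and ``truth`` (true factor scores and agent parameters).
    """
    if config is None:
        config = CohortConfig()
    elif isinstance(config, Mapping):
        config = CohortConfig.from_dict(config)
    rng = np.random.default_rng(seed)
    n = config.n_participants
    qspec = default_questionnaire_spec(seed=0)

    items = generate_item_set(
        config.n_items, k_range=config.k_range, seed=int(rng.integers(2**31))
    )
    responses, F = simulate_questionnaires(
        n,
        qspec["loadings"],
        qspec["factor_corr"],
        qspec["thresholds"],
        seed=int(rng.integers(2**31)),
        item_names=qspec["items"],
    )
    agents = simulate_agents(
        config, factor_scores=F, factor_corr=qspec["factor_corr"],
        seed=int(rng.integers(2**31)),
    )
    ids = [f"p{i + 1:04d}" for i in range(n)]
    # person-level magnitude-effect variability: the small-large gap gets a
    # zero-mean person deviation of SD me_sd, split between the outer bands
    base_offs = band_offsets(config)
    delta = rng.normal(0.0, config.me_sd, n)
    person_offs = {
        "small": base_offs["small"] + delta / 2.0,
        "medium": np.full(n, base_offs["medium"]),
        "large": base_offs["large"] - delta / 2.0,
    }
    choices = simulate_choices(
        items,
        agents,
        seed=int(rng.integers(2**31)),
        family=config.family,
        band_offsets=person_offs,
        participant_ids=ids,
    )

    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 18, 65).round(0)
    gender = rng.choice(["female", "male", "diverse"], size=n, p=config.gender_probs)
    cog = np.clip(
        np.round(rng.normal(config.cognitive_mean, config.cognitive_sd, n)), 0, 16
    ).astype(int)
    fail = rng.random(n) < config.fraction_fail

    cohort = pd.DataFrame(
        {
            "participant_id": ids,
            "age": age,
            "gender": gender,
            "cognitive_ability": cog,
            "attention_check_fail": fail,
        }
    )
    cohort = pd.concat([cohort, responses.set_index(cohort.index)], axis=1)
    truth = pd.DataFrame(F, columns=FACTORS)
    truth["participant_id"] = ids
    truth["ln_k_delay"] = [a.ln_k["delay"] for a in agents]
    truth["ln_k_date"] = [a.ln_k["date"] for a in agents]
    truth["tau"] = [a.tau for a in agents]
    return {
        "config": config,
        "choices": choices,
        "cohort": cohort,
        "codebook": qspec["codebook"],
        "items": items,
        "agents": agents,
        "truth": truth,
    }
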