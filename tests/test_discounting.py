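import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tempdisc import (
    AgentParams,
    ChoiceItem,
    choice_probability,
    fit_hierarchical,
    point_estimates,
    subjective_value,
)
from tempdisc.discounting import discount_value, validate_choice_table
from tempdisc._sampler import obs_loglik, prepare_obs


def test_subjective_value_zero_delay_all_families():
    p = AgentParams(ln_k=-3.0, tau=1.0, beta=0.8, delta=0.95)
    for fam in ("hyperbolic", "exponential", "quasi_hyperbolic"):
        assert subjective_value(25.0, 0, p, fam) == 25.0


def test_hyperbolic_halving_at_kd_one():
    p = AgentParams(ln_k=float(np.log(1 / 19)), tau=1.0)
    assert subjective_value(25.0, 19, p, "hyperbolic") == pytest.approx(12.5)


def test_quasi_hyperbolic_by_hand():
    p = AgentParams(ln_k=0.0, tau=1.0, beta=0.8, delta=1.0)
    assert subjective_value(10.0, 5, p, "quasi_hyperbolic") == pytest.approx(8.0)


def test_value_input_validation():
    p = AgentParams(ln_k=-3.0, tau=1.0)
    with pytest.raises(ValueError):
        subjective_value(25.0, -1, p, "hyperbolic")
    with pytest.raises(ValueError):
        discount_value(25.0, 5, -0.1, "hyperbolic")
    with pytest.raises(ValueError):
        subjective_value(25.0, 5, p, "power_law")


def test_choice_probability_indifference_and_logistic_algebra():
    item = ChoiceItem("x", 14.0, 0, 25.0, 19, "small", "delay")
    k_star = (25 / 14 - 1) / 19
    p_ind = AgentParams(ln_k=float(np.log(k_star)), tau=1.0)
    assert choice_probability(item, p_ind, "hyperbolic") == pytest.approx(0.5)
    # tau=1, V_LL - V_SS = ln 3  ->  P = 0.75
    item2 = ChoiceItem("y", 10.0, 0, 10.0 + np.log(3.0), 1, "small", "delay")
    p0 = AgentParams(ln_k=-30.0, tau=1.0)  # k ~ 0: no discounting
    assert choice_probability(item2, p0, "hyperbolic") == pytest.approx(0.75, abs=1e-6)
    # deterministic limit
    p_inf = AgentParams(ln_k=-30.0, tau=1e9)
    assert choice_probability(item, p_inf, "hyperbolic") == pytest.approx(1.0)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000))
def test_likelihood_symmetry_under_relabeling(seed):
    """Swapping SS/LL roles and flipping choices leaves the log-likelihood fixed."""
    rng = np.random.default_rng(seed)
    n_obs = 30
    base = pd.DataFrame(
        {
            "participant_id": ["p1"] * n_obs,
            "item_id": [f"i{j}" for j in range(n_obs)],
            "frame": ["delay", "date"] * (n_obs // 2),
            "ss_amount": rng.uniform(5, 30, n_obs),
            "ss_delay_days": 0,
            "ll_amount": rng.uniform(35, 80, n_obs),
            "ll_delay_days": rng.integers(5, 200, n_obs),
            "magnitude_band": "small",
            "choice": rng.integers(0, 2, n_obs),
        }
    )
    swapped = base.copy()
    swapped[["ss_amount", "ll_amount"]] = base[["ll_amount", "ss_amount"]].to_numpy()
    swapped[["ss_delay_days", "ll_delay_days"]] = base[
        ["ll_delay_days", "ss_delay_days"]
    ].to_numpy()
    swapped["choice"] = 1 - base["choice"]
    lnk = np.full((1, 1, 2), -3.5)
    ltau = np.full((1, 1), -0.5)
    ll_a = obs_loglik(lnk, ltau, None, prepare_obs(base, "frame"), "hyperbolic")
    ll_b = obs_loglik(lnk, ltau, None, prepare_obs(swapped, "frame"), "hyperbolic")
    assert ll_a.sum() == pytest.approx(ll_b.sum(), rel=1e-12)


def test_validate_choice_table_errors(small_cohort):
    table = small_cohort["choices"].copy()
    bad = table.copy()
    bad.loc[3, "choice"] = 2
    with pytest.raises(ValueError, match=r"\[3\]"):
        validate_choice_table(bad)
    dup = pd.concat([table, table.iloc[[0]]], ignore_index=True)
    with pytest.raises(ValueError, match="duplicate"):
        validate_choice_table(dup)


def test_fit_requires_complete_condition_cells(small_cohort):
    table = small_cohort["choices"]
    broken = table[
        ~((table["participant_id"] == "p0001") & (table["frame"] == "date"))
    ]
    with pytest.raises(ValueError, match="p0001.*date"):
        fit_hierarchical(broken, mcmc_opts={"chains": 1, "warmup": 10, "draws": 10})


def test_fit_recovers_group_parameters(small_fit, small_cohort):
    assert small_fit.diagnostics["max_rhat"] < 1.1
    mu = small_fit.mu.reshape(-1, 2).mean(axis=0)
    truth_delay = np.mean([a.ln_k["delay"] for a in small_cohort["agents"]])
    i = small_fit.conditions.index("delay")
    assert mu[i] == pytest.approx(truth_delay, abs=0.45)
    fe = small_fit.frame_effect_draws().mean()
    assert fe == pytest.approx(0.4, abs=0.25)


def test_point_estimate_order_matches_truth_for_extreme_agents(small_fit, small_cohort):
    est = point_estimates(small_fit).set_index("participant_id")
    truth = {f"p{i + 1:04d}": a.ln_k["delay"] for i, a in enumerate(small_cohort["agents"])}
    ids = sorted(truth, key=truth.get)
    steepest, shallowest = ids[-1], ids[0]
    assert est.loc[steepest, "ln_k_delay"] > est.loc[shallowest, "ln_k_delay"]


def test_point_estimates_dde_arithmetic(small_fit):
    est = point_estimates(small_fit)
    assert np.allclose(est["dde"], est["ln_k_delay"] - est["ln_k_date"])
    assert np.all(np.isfinite(est["waic"]))


def test_all_ll_participant_shrinks_without_error(item_set):
    """A degenerate all-larger-later responder gets a finite, shrunken estimate."""
    rng = np.random.default_rng(0)
    rows = []
    for pid, lnk in [("deg", None)] + [(f"n{j}", -4.5 + rng.normal(0, 1)) for j in range(15)]:
        for it in item_set:
            if lnk is None:
                choice = 1  # always larger-later
            else:
                k = np.exp(lnk)
                v = it.ll_amount / (1 + k * it.ll_delay_days) - it.ss_amount
                choice = int(rng.random() < 1 / (1 + np.exp(-0.7 * v)))
            rows.append(
                dict(participant_id=pid, item_id=it.item_id, frame=it.frame,
                     ss_amount=it.ss_amount, ss_delay_days=0, ll_amount=it.ll_amount,
                     ll_delay_days=it.ll_delay_days, magnitude_band=it.magnitude_band,
                     choice=choice)
            )
    fit = fit_hierarchical(
        pd.DataFrame(rows), mcmc_opts={"chains": 2, "warmup": 300, "draws": 200}, seed=1
    )
    est = point_estimates(fit).set_index("participant_id")
    group = fit.mu.reshape(-1, 2).mean(axis=0).mean()
    # shrunken below the group mean (steep-k side is excluded by all-LL data)
    assert est.loc["deg", "ln_k_delay"] < group
    assert np.isfinite(est.loc["deg", "ln_k_delay"])


def test_prior_predictive_choices_non_degenerate(item_set):
    """Group-prior draws produce neither all-SS nor all-LL choice patterns."""
    rng = np.random.default_rng(99)
    from tempdisc import simulate_choices

    p_ll = []
    for _ in range(40):
        mu = rng.normal(-4.0, 3.0)
        sd = abs(rng.normal(0.0, 2.0))
        mu_t = rng.normal(0.0, 1.0)
        agents = [
            AgentParams(ln_k=float(rng.normal(mu, sd)), tau=float(np.exp(mu_t)))
            for _ in range(5)
        ]
        ch = simulate_choices(item_set, agents, seed=int(rng.integers(2**31)))
        p_ll.append(ch["choice"].mean())
    assert 0.05 < np.mean(p_ll) < 0.95
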