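import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tempdisc import (
    AgentParams,
    CohortConfig,
    generate_cohort,
    generate_item_set,
    polychoric_ml,
    simulate_agents,
    simulate_choices,
    simulate_questionnaires,
)
from tempdisc.cohort import DEFAULT_FACTOR_CORR, default_questionnaire_spec


def test_choices_reproducible_and_schema(item_set):
    cfg = CohortConfig(n_participants=10, magnitude_effect=0.0)
    agents = simulate_agents(cfg, seed=1)
    a = simulate_choices(item_set, agents, seed=9)
    b = simulate_choices(item_set, agents, seed=9)
    pd.testing.assert_frame_equal(a, b)
    assert len(a) == 10 * 54
    assert set(a["choice"]) <= {0, 1}


def test_deterministic_preference_at_high_tau(item_set):
    # agent far shallower than every indifference point, near-infinite tau
    agent = AgentParams(ln_k=np.log(1e-5), tau=1e6)
    choices = simulate_choices(item_set, [agent], seed=0)
    assert choices["choice"].mean() == 1.0


def test_null_frame_effect_balanced(item_set):
    cfg = CohortConfig(
        n_participants=150, frame_effect=0.0, dde_sd=0.0, magnitude_effect=0.0
    )
    agents = simulate_agents(cfg, seed=5)
    choices = simulate_choices(item_set, agents, seed=6)
    tab = pd.crosstab(choices["frame"], choices["choice"])
    _, p, *_ = stats.chi2_contingency(tab)
    assert p > 0.01


def test_missing_condition_parameter_names_participant(item_set):
    bad = AgentParams(ln_k={"delay": -4.0}, tau=1.0)
    with pytest.raises(KeyError, match="agent 0.*date"):
        simulate_choices(item_set, [bad], seed=0)


def test_frame_effect_enters_through_lnk():
    cfg = CohortConfig(n_participants=400, frame_effect=0.4, dde_sd=0.5)
    agents = simulate_agents(cfg, seed=2)
    dde = np.array([a.ln_k["delay"] - a.ln_k["date"] for a in agents])
    assert dde.mean() == pytest.approx(0.4, abs=0.1)


def test_questionnaire_null_loadings_independent():
    n = 5000
    loadings = np.zeros((6, 3))
    thr = [np.array([-0.5, 0.5])] * 6
    resp, F = simulate_questionnaires(n, loadings, np.eye(3), thr, seed=3)
    for j in range(6):
        for f in range(3):
            r = np.corrcoef(resp.iloc[:, j], F[:, f])[0, 1]
            assert abs(r) < 0.05


def test_questionnaire_perfect_indicator():
    n = 3000
    loadings = np.array([[1.0]])
    thr = [np.array([-1.0, 0.0, 1.0])]
    resp, F = simulate_questionnaires(n, loadings, np.eye(1), thr, seed=4)
    from tempdisc import polyserial_ml

    rho = polyserial_ml(F[:, 0], resp.iloc[:, 0].to_numpy())
    assert rho > 0.97


def test_questionnaire_roundtrip_polychoric():
    """Polychoric correlations reproduce loadings.Phi.loadings' off-diagonals."""
    rng = np.random.default_rng(8)
    p = 10
    phi = np.array([[1.0, 0.4], [0.4, 1.0]])
    loadings = np.zeros((p, 2))
    loadings[:5, 0] = rng.uniform(0.5, 0.8, 5)
    loadings[5:, 1] = rng.uniform(0.5, 0.8, 5)
    thr = [np.array([-0.6, 0.4, 1.2]) for _ in range(p)]
    resp, _ = simulate_questionnaires(2000, loadings, phi, thr, seed=9)
    implied = loadings @ phi @ loadings.T
    for i in range(0, p, 2):
        for j in range(i + 1, p, 3):
            est = polychoric_ml(resp.iloc[:, i], resp.iloc[:, j])
            assert est == pytest.approx(implied[i, j], abs=0.06)


def test_questionnaire_input_validation():
    with pytest.raises(ValueError, match="Heywood"):
        simulate_questionnaires(50, np.array([[0.9, 0.9]]), np.eye(2),
                                [np.array([0.0])], seed=0)
    with pytest.raises(ValueError, match="increasing"):
        simulate_questionnaires(50, np.array([[0.5]]), np.eye(1),
                                [np.array([1.0, 0.0])], seed=0)


def test_recovered_factor_correlations():
    q = default_questionnaire_spec(0)
    resp, F = simulate_questionnaires(
        2000, q["loadings"], q["factor_corr"], q["thresholds"], seed=10
    )
    emp = np.corrcoef(F.T)
    assert np.allclose(emp, DEFAULT_FACTOR_CORR, atol=0.05)


def test_generate_cohort_structure_and_flags():
    sim = generate_cohort({"n_participants": 800, "fraction_fail": 68 / 800}, seed=12)
    cohort = sim["cohort"]
    assert len(cohort) == 800
    frac = cohort["attention_check_fail"].mean()
    assert frac == pytest.approx(68 / 800, abs=0.03)
    assert cohort.filter(like="dass_").shape[1] == 21
    assert sim["codebook"].shape[0] == 176
    assert set(cohort["gender"]) <= {"female", "male", "diverse"}
    assert cohort["cognitive_ability"].between(0, 16).all()


def test_cohort_lnk_factor_correlation():
    sim = generate_cohort(
        {"n_participants": 4000, "factor_lnk_r": (0.10, 0.0, 0.0)}, seed=13
    )
    truth = sim["truth"]
    r_ad = np.corrcoef(truth["AD"], truth["ln_k_delay"])[0, 1]
    r_iio = np.corrcoef(truth["IIO"], truth["ln_k_delay"])[0, 1]
    assert r_ad == pytest.approx(0.10, abs=0.05)
    # IIO correlates with AD (factor corr), so only a weak indirect link remains
    assert abs(r_iio) < 0.10


def test_config_validation_lists_offending_keys():
    with pytest.raises(ValueError, match="unknown cohort config keys.*n_people"):
        CohortConfig.from_dict({"n_people": 10})
    with pytest.raises(ValueError, match="fraction_fail"):
        CohortConfig(fraction_fail=1.5)
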