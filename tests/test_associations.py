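import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tempdisc import (
    breusch_pagan,
    exclude_outliers,
    holm_correct,
    pearson_with_holm,
    power_n_correlation,
    robust_ols,
)
from tempdisc.associations import correlation_test_power, holm_across_outcomes


# ---------------------------------------------------------------- outliers

def test_constant_vector_keeps_all():
    with pytest.warns(UserWarning, match="zero SD"):
        mask = exclude_outliers(np.ones(20))
    assert mask.all()


def test_constructed_outlier_excluded():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(100)
    x = np.append(x, x.mean() + 10 * x.std(ddof=1))
    mask = exclude_outliers(x)
    assert not mask[-1]
    assert mask[:-1].sum() >= 99  # at most chance exclusions among the normals


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000))
def test_outlier_mask_idempotent_under_full_sample_moments(seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(60) * rng.uniform(0.5, 3.0)
    mask = exclude_outliers(x)
    m, s = x.mean(), x.std(ddof=1)
    again = np.abs(x[mask] - m) <= 3 * s
    assert again.all()


# -------------------------------------------------------------------- holm

def test_holm_examples():
    assert np.allclose(holm_correct([0.01, 0.04]), [0.02, 0.04])
    assert np.allclose(holm_correct([0.03, 0.03]), [0.06, 0.06])
    assert np.allclose(holm_correct([0.2]), [0.2])
    with pytest.raises(ValueError):
        holm_correct([0.5, 1.2])


def brute_force_holm(p):
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        out[i] = min(running, 1.0)
    return out


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
def test_holm_matches_brute_force_and_dominates_input(pvals):
    p = np.array(pvals)
    adj = holm_correct(p)
    assert np.allclose(adj, brute_force_holm(p))
    assert (adj >= p - 1e-15).all()


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(0, 5000))
def test_holm_permutation_equivariant(seed):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0, 1, 8)
    perm = rng.permutation(8)
    assert np.allclose(holm_correct(p)[perm], holm_correct(p[perm]))


# ------------------------------------------------------------ correlations

def test_pearson_with_holm_identity_pair():
    rng = np.random.default_rng(1)
    x = rng.standard_normal(60)
    td = pd.DataFrame({"lnk_delay": x, "lnk_date": x})
    scales = pd.DataFrame({"s": x})
    out = pearson_with_holm(td, scales)
    assert np.allclose(out["r"], 1.0)
    assert (out["p_c"] >= out["p"] - 1e-15).all()


def test_pearson_fisher_interval_contains_truth():
    rng = np.random.default_rng(2)
    rho, n = 0.1, 731
    hits = 0
    for _ in range(40):
        z = rng.standard_normal((n, 2))
        y = rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1]
        td = pd.DataFrame({"lnk_delay": z[:, 0]})
        out = pearson_with_holm(td, pd.DataFrame({"s": y}))
        r = out["r"].iloc[0]
        hits += 0.03 <= r <= 0.17  # central ~95% band at rho=0.1, n=731
    assert hits >= 33


# -------------------------------------------------------------- robust OLS

def test_intercept_only_recovers_mean():
    rng = np.random.default_rng(3)
    y = rng.normal(2.5, 1.0, 50)
    res = robust_ols(y, pd.DataFrame(index=range(50)), standardize=False)
    assert res.table.loc[res.table["term"] == "const", "beta"].iloc[0] == pytest.approx(
        y.mean()
    )


def test_single_standardized_regressor_equals_pearson_r():
    rng = np.random.default_rng(4)
    x = rng.standard_normal(200)
    y = 0.4 * x + rng.standard_normal(200)
    res = robust_ols(y, pd.DataFrame({"x": x}), standardize=True)
    r = np.corrcoef(x, y)[0, 1]
    beta = res.table.loc[res.table["term"] == "x", "beta"].iloc[0]
    assert beta == pytest.approx(r, abs=1e-10)
    # CI consistent with the robust SE
    row = res.table[res.table["term"] == "x"].iloc[0]
    assert row["ci_high"] - row["beta"] == pytest.approx(1.96 * row["se"], rel=0.01)


def test_robust_close_to_classical_when_homoskedastic():
    import statsmodels.api as sm

    rng = np.random.default_rng(5)
    x = rng.standard_normal((5000, 2))
    y = x @ [0.3, -0.2] + rng.standard_normal(5000)
    X = pd.DataFrame(x, columns=["a", "b"])
    res = robust_ols(y, X, hc_type="HC3")
    classical = sm.OLS(
        (y - y.mean()) / y.std(ddof=1), sm.add_constant((x - x.mean(0)) / x.std(0, ddof=1))
    ).fit()
    classical_se = np.asarray(classical.bse)
    for i, term in enumerate(["a", "b"]):
        se_r = res.table.loc[res.table["term"] == term, "se"].iloc[0]
        assert se_r == pytest.approx(classical_se[i + 1], rel=0.05)


def test_rank_deficiency_names_collinear_columns():
    rng = np.random.default_rng(6)
    x = rng.standard_normal(100)
    X = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.standard_normal(100)})
    with pytest.raises(ValueError, match="collinear"):
        robust_ols(rng.standard_normal(100), X)


def test_holm_across_outcomes_adds_pc():
    rng = np.random.default_rng(7)
    x = rng.standard_normal(120)
    X = pd.DataFrame({"x": x})
    fits = [
        robust_ols(0.2 * x + rng.standard_normal(120), X, outcome=o)
        for o in ("delay", "date")
    ]
    holm_across_outcomes(fits)
    for f in fits:
        assert (f.table["p_c"] >= f.table["p"] - 1e-15).all()


# ----------------------------------------------------------- breusch-pagan

def test_bp_constant_residuals_statistic_zero():
    X = np.column_stack([np.ones(30), np.arange(30.0)])
    stat, p = breusch_pagan(np.full(30, 0.5), X)
    assert stat == 0.0
    with pytest.raises(ValueError, match="degenerate"):
        breusch_pagan(np.zeros(30), X)


def test_bp_detects_heteroskedasticity():
    rng = np.random.default_rng(8)
    x = rng.uniform(0.5, 3.0, 1000)
    e = rng.standard_normal(1000) * x
    X = np.column_stack([np.ones(1000), x])
    beta, *_ = np.linalg.lstsq(X, e, rcond=None)
    stat, p = breusch_pagan(e - X @ beta, X)
    assert p < 0.001


def test_bp_agrees_with_statsmodels_koenker():
    import statsmodels.api as sm
    from statsmodels.stats.diagnostic import het_breuschpagan

    rng = np.random.default_rng(9)
    x = rng.standard_normal((300, 2))
    y = x @ [0.5, -0.3] + rng.standard_normal(300)
    X = sm.add_constant(x)
    resid = sm.OLS(y, X).fit().resid
    stat, p = breusch_pagan(resid, X)
    lm, lm_p, _, _ = het_breuschpagan(resid, X, robust=True)
    assert stat == pytest.approx(lm, rel=1e-8)
    assert p == pytest.approx(lm_p, rel=1e-8)


# ------------------------------------------------------------------- power

def test_power_monotone_in_rho_and_boundaries():
    ns = [power_n_correlation(r) for r in (0.1, 0.2, 0.3)]
    assert ns[0] > ns[1] > ns[2]
    with pytest.raises(ValueError):
        power_n_correlation(rho=0.0)
    with pytest.raises(RuntimeError):
        power_n_correlation(rho=1e-4, n_cap=10_000)


def test_exact_power_matches_simulation():
    n, rho = 80, 0.3
    exact = correlation_test_power(n, rho)
    rng = np.random.default_rng(10)
    hits = 0
    reps = 3000
    for _ in range(reps):
        z = rng.standard_normal((n, 2))
        y = rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1]
        r = np.corrcoef(z[:, 0], y)[0, 1]
        t = r * np.sqrt((n - 2) / (1 - r**2))
        from scipy.stats import t as tdist

        hits += 2 * tdist.sf(abs(t), n - 2) < 0.05
    assert hits / reps == pytest.approx(exact, abs=0.03)
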