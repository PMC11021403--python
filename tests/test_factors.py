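import numpy as np
import pandas as pd
import pytest

from tempdisc import (
    bootstrap_loading_cis,
    cng_factor_count,
    factor_scores,
    fit_ml_efa,
    hetcor_matrix,
    polychoric_ml,
    polyserial_ml,
    simulate_questionnaires,
    tucker_congruence,
)
from tempdisc.factors import (
    HetCorMatrix,
    _cell_probs,
    _ordinal_thresholds,
    _slope,
    smooth_to_psd,
)


# ------------------------------------------------------------- bvn cdf

def test_bvn_cdf_matches_scipy():
    from scipy.stats import multivariate_normal

    from tempdisc._bvn import bvn_cdf

    rng = np.random.default_rng(13)
    for rho in (-0.99, -0.6, -0.1, 0.3, 0.9, 0.95):
        h = rng.normal(0, 1.5, 8)
        k = rng.normal(0, 1.5, 8)
        ref = [
            multivariate_normal.cdf([a, b], cov=[[1, rho], [rho, 1]])
            for a, b in zip(h, k)
        ]
        assert np.allclose(bvn_cdf(h, k, rho), ref, atol=1e-10)
    # infinite thresholds
    assert bvn_cdf(np.inf, 0.0, 0.5) == 0.5
    assert bvn_cdf(-np.inf, 1.0, 0.5) == 0.0
    assert bvn_cdf(np.inf, np.inf, -0.3) == 1.0


# ------------------------------------------------------------- polychoric

def test_polychoric_independence():
    x = np.repeat([0, 0, 1, 1], 25)
    y = np.tile([0, 1], 50)
    assert polychoric_ml(x, y) == pytest.approx(0.0, abs=1e-4)


def test_polychoric_perfect_concordance_capped():
    x = np.repeat([0, 1], 30)
    assert polychoric_ml(x, x.copy()) > 0.999


def test_polychoric_matches_grid_search_oracle():
    """Two-step ML agrees with brute-force grid search over the likelihood."""
    rng = np.random.default_rng(14)
    for _ in range(6):
        rho = rng.uniform(-0.85, 0.85)
        L = np.linalg.cholesky([[1, rho], [rho, 1]])
        z = rng.standard_normal((300, 2)) @ L.T
        cx = np.sort(rng.normal(0, 1, rng.integers(1, 5)))
        cy = np.sort(rng.normal(0, 1, rng.integers(1, 5)))
        x = np.digitize(z[:, 0], cx)
        y = np.digitize(z[:, 1], cy)
        xc = pd.factorize(x, sort=True)[0]
        yc = pd.factorize(y, sort=True)[0]
        nx, ny = xc.max() + 1, yc.max() + 1
        tx = _ordinal_thresholds(xc, nx)
        ty = _ordinal_thresholds(yc, ny)
        counts = np.bincount(xc * ny + yc, minlength=nx * ny).reshape(nx, ny)
        grid = np.linspace(-0.999, 0.999, 1999)
        ll = [
            np.sum(counts * np.log(np.maximum(_cell_probs(tx, ty, r), 1e-12)))
            for r in grid
        ]
        oracle = grid[int(np.argmax(ll))]
        est = polychoric_ml(x, y)

        def nll(r):
            return -np.sum(counts * np.log(np.maximum(_cell_probs(tx, ty, r), 1e-12)))

        # agreement in rho, or in likelihood where the surface plateaus
        assert abs(est - oracle) <= 0.01 or nll(est) <= nll(oracle) + 1e-6


def test_polychoric_input_validation():
    with pytest.raises(ValueError, match="categories"):
        polychoric_ml(np.zeros(50), np.tile([0, 1], 25))
    with pytest.raises(ValueError, match="n >= 20"):
        polychoric_ml(np.array([0, 1] * 5), np.array([0, 1] * 5))


def test_polyserial_recovers_latent_correlation():
    rng = np.random.default_rng(15)
    rho = 0.55
    L = np.linalg.cholesky([[1, rho], [rho, 1]])
    z = rng.standard_normal((3000, 2)) @ L.T
    y = np.digitize(z[:, 1], [-0.5, 0.7])
    assert polyserial_ml(z[:, 0], y) == pytest.approx(rho, abs=0.05)


# ----------------------------------------------------------------- hetcor

def test_hetcor_collapses_to_pearson_for_continuous():
    rng = np.random.default_rng(16)
    tab = pd.DataFrame(rng.normal(0, 1, (200, 4)), columns=list("abcd"))
    het = hetcor_matrix(tab, {c: "continuous" for c in tab.columns})
    assert np.allclose(het.matrix, np.corrcoef(tab.to_numpy().T))
    assert (het.pair_type == "pearson").all()
    assert np.allclose(np.diag(het.matrix), 1.0)


def test_hetcor_invariance_to_order_and_relabeling():
    rng = np.random.default_rng(17)
    z = rng.standard_normal((400, 2))
    z[:, 1] = 0.6 * z[:, 0] + 0.8 * z[:, 1]
    tab = pd.DataFrame(
        {"a": np.digitize(z[:, 0], [-0.5, 0.5]), "b": np.digitize(z[:, 1], [0.0])}
    )
    types = {"a": "ordinal", "b": "ordinal"}
    base = hetcor_matrix(tab, types).matrix[0, 1]
    shuffled = hetcor_matrix(
        tab.sample(frac=1.0, random_state=1).reset_index(drop=True), types
    ).matrix[0, 1]
    relabeled = tab.copy()
    relabeled["a"] = relabeled["a"].map({0: 10, 1: 55, 2: 300})  # increasing map
    relab = hetcor_matrix(relabeled, types).matrix[0, 1]
    assert base == pytest.approx(shuffled, abs=1e-12)
    assert base == pytest.approx(relab, abs=1e-12)


def test_hetcor_mixed_types_and_missing_pair():
    rng = np.random.default_rng(18)
    tab = pd.DataFrame(
        {
            "cont": rng.normal(0, 1, 100),
            "ord": rng.integers(0, 3, 100),
        }
    )
    het = hetcor_matrix(tab, {"cont": "continuous", "ord": "ordinal"})
    assert het.pair_type[0, 1] == "polyserial"
    tab["ord"] = np.where(np.isnan(tab["cont"]), tab["ord"], np.nan)
    with pytest.raises(ValueError, match="all-missing pair"):
        hetcor_matrix(tab, {"cont": "continuous", "ord": "ordinal"})
    with pytest.raises(ValueError, match="declared type"):
        hetcor_matrix(tab, {"cont": "continuous"})


def test_smoothing_flag_and_psd():
    R = np.array([[1.0, 0.95, -0.9], [0.95, 1.0, 0.8], [-0.9, 0.8, 1.0]])
    S, applied = smooth_to_psd(R)
    assert applied
    assert np.linalg.eigvalsh(S).min() >= 0
    assert np.allclose(np.diag(S), 1.0)


# -------------------------------------------------------------------- CNG

def brute_force_cng(e):
    e = np.asarray(e, dtype=float)
    vals = {}
    for t in range(3, e.size - 2):
        vals[t] = _slope(e[t : t + 3]) - _slope(e[t - 3 : t])
    best = max(vals.values())
    return min(t for t, v in vals.items() if v >= best - 1e-12)


def test_cng_elbow_example():
    assert cng_factor_count([10, 6, 3, 1, 0.9, 0.8, 0.7, 0.6]) == 3


def test_cng_matches_brute_force_on_random_sequences():
    rng = np.random.default_rng(19)
    for _ in range(25):
        e = np.sort(rng.exponential(1.0, rng.integers(6, 30)))[::-1]
        assert cng_factor_count(e) == brute_force_cng(e)


def test_cng_linear_decay_tie_and_errors():
    e = np.linspace(10, 1, 12)
    assert cng_factor_count(e) == 3  # constant CNG: smallest admissible count
    with pytest.raises(ValueError):
        cng_factor_count([3, 2, 1, 0.5, 0.2])


# -------------------------------------------------------------------- EFA

def _simple_structure(p_per_factor, nf, loading, rng):
    p = p_per_factor * nf
    L = np.zeros((p, nf))
    for f in range(nf):
        L[f * p_per_factor : (f + 1) * p_per_factor, f] = loading
    return L


def test_efa_recovers_orthogonal_structure():
    rng = np.random.default_rng(20)
    L = _simple_structure(8, 2, 0.7, rng)
    thr = [np.array([-0.8, 0.0, 0.8])] * 16
    resp, _ = simulate_questionnaires(2000, L, np.eye(2), thr, seed=21)
    het = hetcor_matrix(resp, {c: "ordinal" for c in resp.columns})
    sol = fit_ml_efa(het, 2)
    cong = tucker_congruence(L, sol.loadings.to_numpy())
    from scipy.optimize import linear_sum_assignment

    r, c = linear_sum_assignment(-np.abs(cong))
    assert (np.abs(cong[r, c]) >= 0.95).all()
    # orthogonal generating model: factor correlation near identity
    off = sol.factor_corr[np.triu_indices(2, 1)]
    assert np.all(np.abs(off) < 0.1)
    assert np.all(sol.communalities <= 1.0 + 1e-9)


def test_efa_recovers_oblique_factor_correlations():
    rng = np.random.default_rng(22)
    phi = np.array([[1.0, 0.4, 0.3], [0.4, 1.0, 0.35], [0.3, 0.35, 1.0]])
    L = _simple_structure(8, 3, 0.7, rng)
    thr = [np.array([-0.6, 0.4, 1.2])] * 24
    resp, _ = simulate_questionnaires(2000, L, phi, thr, seed=23)
    het = hetcor_matrix(resp, {c: "ordinal" for c in resp.columns})
    sol = fit_ml_efa(het, 3)
    cong = tucker_congruence(L, sol.loadings.to_numpy())
    from scipy.optimize import linear_sum_assignment

    r, c = linear_sum_assignment(-np.abs(cong))
    phi_est = sol.factor_corr[np.ix_(c, c)]
    assert np.allclose(phi_est, phi, atol=0.1)


def test_efa_validation():
    R = np.eye(8)
    with pytest.raises(ValueError, match="n_factors"):
        fit_ml_efa(R, 0)
    with pytest.raises(ValueError, match="items/2"):
        fit_ml_efa(R, 4)


# ----------------------------------------------------------------- scores

def test_single_factor_scores_proportional_to_sum_score():
    rng = np.random.default_rng(24)
    L = np.full((12, 1), 0.65)
    thr = [np.array([-0.7, 0.2, 1.0])] * 12
    resp, _ = simulate_questionnaires(1500, L, np.eye(1), thr, seed=25)
    het = hetcor_matrix(resp, {c: "ordinal" for c in resp.columns})
    sol = fit_ml_efa(het, 1)
    sc = factor_scores(sol, resp)
    sums = resp.sum(axis=1)
    assert abs(np.corrcoef(sc.iloc[:, 0], sums)[0, 1]) > 0.99
    assert sc.iloc[:, 0].mean() == pytest.approx(0.0, abs=1e-9)
    assert sc.iloc[:, 0].std(ddof=1) == pytest.approx(1.0, abs=1e-9)


def test_factor_scores_reweight_missing_with_warning():
    rng = np.random.default_rng(26)
    L = np.full((10, 1), 0.7)
    thr = [np.array([-0.5, 0.5])] * 10
    resp, _ = simulate_questionnaires(500, L, np.eye(1), thr, seed=27)
    het = hetcor_matrix(resp, {c: "ordinal" for c in resp.columns})
    sol = fit_ml_efa(het, 1)
    holed = resp.astype(float)
    holed.iloc[0, :4] = np.nan
    with pytest.warns(UserWarning, match="available items"):
        sc = factor_scores(sol, holed)
    assert np.isfinite(sc.iloc[0, 0])


# -------------------------------------------------------------- bootstrap

def _tiny_battery(seed=28, n=250):
    rng = np.random.default_rng(seed)
    L = _simple_structure(4, 2, 0.7, rng)
    thr = [np.array([-0.5, 0.5])] * 8
    resp, _ = simulate_questionnaires(n, L, np.eye(2), thr, seed=seed + 1)
    return resp, {c: "ordinal" for c in resp.columns}


def test_bootstrap_degenerate_resampler_gives_zero_width():
    resp, types = _tiny_battery()
    n = len(resp)
    cis = bootstrap_loading_cis(
        resp, types, 2, n_boot=12, seed=0, _resampler=lambda b: np.arange(n)
    )
    lo = cis.filter(like="_lo").to_numpy()
    hi = cis.filter(like="_hi").to_numpy()
    assert np.allclose(lo, hi, atol=1e-12)


def test_bootstrap_ci_width_shrinks_with_n():
    widths = []
    for n in (150, 600):
        resp, types = _tiny_battery(seed=30, n=n)
        cis = bootstrap_loading_cis(resp, types, 2, n_boot=100, seed=1)
        w = (cis.filter(like="_hi").to_numpy() - cis.filter(like="_lo").to_numpy()).mean()
        widths.append(w)
    assert widths[1] < widths[0]
    # roughly 1/sqrt(n): a factor-2 n ratio gives ~sqrt(4)=2x narrower
    assert widths[0] / widths[1] == pytest.approx(2.0, rel=0.5)


def test_bootstrap_requires_enough_replicates():
    resp, types = _tiny_battery()
    with pytest.raises(ValueError, match="n_boot"):
        bootstrap_loading_cis(resp, types, 2, n_boot=10)
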