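"""Transdiagnostic dimension extraction from mixed-scale item responses.

Pipeline: heterogeneous correlation matrix (Pearson for continuous pairs,
polyserial for mixed, polychoric for ordinal pairs, all by two-step maximum
likelihood under the latent bivariate-normal model) -> Cattell-Nelson-
Gorsuch scree test for the factor count -> maximum-likelihood factor
extraction -> oblimin (direct quartimin) rotation by gradient projection ->
Thurstone regression factor scores -> bootstrap confidence intervals for
the pattern loadings with congruence-based factor alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr, ndtri

from ._bvn import bvn_cdf

RHO_CAP = 1.0 - 1e-6
_TINY = 1e-12


# ----------------------------------------------------------- correlations

def _ordinal_thresholds(codes: np.ndarray, n_cat: int) -> np.ndarray:
    """Normal-quantile thresholds from marginal cumulative proportions."""
    counts = np.bincount(codes, minlength=n_cat)
    cum = np.cumsum(counts)[:-1] / codes.size
    cum = np.clip(cum, 1e-10, 1 - 1e-10)
    return np.concatenate(([-np.inf], ndtri(cum), [np.inf]))


def _cell_probs(tau_x: np.ndarray, tau_y: np.ndarray, rho: float) -> np.ndarray:
    grid = bvn_cdf(tau_x[:, None], tau_y[None, :], rho)
    return np.diff(np.diff(grid, axis=0), axis=1)


def polychoric_ml(x, y) -> float:
    """Two-step ML polychoric correlation between two ordinal vectors.

    Thresholds are fixed at the normal quantiles of the marginal cumulative
    proportions; rho then maximizes the bivariate-normal cell-probability
    likelihood. The estimate is capped at +/-(1 - 1e-6).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    ok = ~(pd.isna(x) | pd.isna(y))
    x, y = x[ok], y[ok]
    if x.size < 20:
        raise ValueError("polychoric correlation needs n >= 20 complete pairs")
    xc, xu = pd.factorize(x, sort=True)
    yc, yu = pd.factorize(y, sort=True)
    if len(xu) < 2 or len(yu) < 2:
        raise ValueError("each variable needs at least two observed categories")
    counts = np.bincount(xc * len(yu) + yc, minlength=len(xu) * len(yu)).reshape(
        len(xu), len(yu)
    )
    tau_x = _ordinal_thresholds(xc, len(xu))
    tau_y = _ordinal_thresholds(yc, len(yu))
    return _polychoric_from_table(counts, tau_x, tau_y)


def _polychoric_from_table(counts, tau_x, tau_y) -> float:
    def nll(rho):
        p = _cell_probs(tau_x, tau_y, rho)
        return -np.sum(counts * np.log(np.maximum(p, _TINY)))

    res = optimize.minimize_scalar(
        nll, bounds=(-RHO_CAP, RHO_CAP), method="bounded",
        options={"xatol": 1e-5},
    )
    return float(np.clip(res.x, -RHO_CAP, RHO_CAP))


def polyserial_ml(x_cont, y_ord) -> float:
    """Two-step ML polyserial correlation (continuous x, ordinal y)."""
    x = np.asarray(x_cont, dtype=float)
    y = np.asarray(y_ord)
    ok = ~(np.isnan(x) | pd.isna(y))
    x, y = x[ok], y[ok]
    if x.size < 20:
        raise ValueError("polyserial correlation needs n >= 20 complete pairs")
    yc, yu = pd.factorize(y, sort=True)
    if len(yu) < 2:
        raise ValueError("ordinal variable needs at least two observed categories")
    if np.std(x) == 0:
        raise ValueError("continuous variable has zero variance")
    z = (x - x.mean()) / x.std()
    tau = _ordinal_thresholds(yc, len(yu))
    hi = tau[yc + 1]
    lo = tau[yc]

    def nll(rho):
        s = np.sqrt(1.0 - rho * rho)
        p = ndtr((hi - rho * z) / s) - ndtr((lo - rho * z) / s)
        return -np.sum(np.log(np.maximum(p, _TINY)))

    res = optimize.minimize_scalar(
        nll, bounds=(-RHO_CAP, RHO_CAP), method="bounded", options={"xatol": 1e-5}
    )
    return float(np.clip(res.x, -RHO_CAP, RHO_CAP))


@dataclass
class HetCorMatrix:
    """Heterogeneous correlation matrix with per-pair estimator labels."""

    matrix: np.ndarray
    variables: list[str]
    pair_type: np.ndarray            # object array: pearson/polyserial/polychoric
    smoothing_applied: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.variables, columns=self.variables)

    @property
    def eigenvalues(self) -> np.ndarray:
        return np.sort(np.linalg.eigvalsh(self.matrix))[::-1]


def smooth_to_psd(R: np.ndarray, eps: float = 1e-6) -> tuple[np.ndarray, bool]:
    """Clip negative eigenvalues and rescale to unit diagonal."""
    w, V = np.linalg.eigh(R)
    if w.min() >= 0:
        return R, False
    w = np.maximum(w, eps)
    S = (V * w) @ V.T
    d = np.sqrt(np.diag(S))
    S = S / np.outer(d, d)
    np.fill_diagonal(S, 1.0)
    return S, True


def hetcor_matrix(table: pd.DataFrame, var_types: dict[str, str]) -> HetCorMatrix:
    """Pairwise-complete heterogeneous correlations over mixed variables.

    ``var_types`` maps each column to 'continuous' or 'ordinal'. The result
    is smoothed to the nearest positive semi-definite matrix (eigenvalue
    clipping) when needed, with ``smoothing_applied`` set.
    """
    cols = list(table.columns)
    for c in cols:
        if var_types.get(c) not in ("continuous", "ordinal"):
            raise ValueError(f"variable {c!r} missing a declared type")
    p = len(cols)
    R = np.eye(p)
    ptype = np.empty((p, p), dtype=object)
    ptype[np.diag_indices(p)] = "pearson"
    data = {c: table[c].to_numpy() for c in cols}
    for i in range(p):
        for j in range(i + 1, p):
            xi, xj = data[cols[i]], data[cols[j]]
            ok = ~(pd.isna(xi) | pd.isna(xj))
            if not ok.any():
                raise ValueError(f"all-missing pair: ({cols[i]!r}, {cols[j]!r})")
            ti, tj = var_types[cols[i]], var_types[cols[j]]
            if ti == "continuous" and tj == "continuous":
                r = float(np.corrcoef(xi[ok].astype(float), xj[ok].astype(float))[0, 1])
                kind = "pearson"
            elif ti == "ordinal" and tj == "ordinal":
                r = polychoric_ml(xi[ok], xj[ok])
                kind = "polychoric"
            elif ti == "continuous":
                r = polyserial_ml(xi[ok], xj[ok])
                kind = "polyserial"
            else:
                r = polyserial_ml(xj[ok], xi[ok])
                kind = "polyserial"
            R[i, j] = R[j, i] = r
            ptype[i, j] = ptype[j, i] = kind
    R, smoothed = smooth_to_psd(R)
    return HetCorMatrix(R, cols, ptype, smoothed)


# ----------------------------------------------------------------- scree

def _slope(y: np.ndarray) -> float:
    x = np.arange(y.size, dtype=float)
    x = x - x.mean()
    return float(np.sum(x * (y - y.mean())) / np.sum(x * x))


def cng_factor_count(eigenvalues: np.ndarray) -> int:
    """Cattell-Nelson-Gorsuch scree test.

    For each admissible split t, straight lines are fit to the eigenvalue
    triplets ending at t and starting at t+1; the factor count is the t with
    the maximal increase in scree slope (the sharpest elbow), ties broken to
    the smallest t.
    """
    e = np.asarray(eigenvalues, dtype=float)
    if e.ndim != 1 or e.size < 6:
        raise ValueError("CNG needs at least 6 eigenvalues")
    best_t, best_v = None, -np.inf
    for t in range(3, e.size - 2):          # t = factor count, 1-based
        s_before = _slope(e[t - 3 : t])
        s_after = _slope(e[t : t + 3])
        v = s_after - s_before
        if v > best_v + 1e-12:
            best_t, best_v = t, v
    return int(best_t)


# ------------------------------------------------------------------- EFA

@dataclass
class FactorSolution:
    eigenvalues: np.ndarray
    n_factors: int
    loadings: pd.DataFrame               # oblimin pattern matrix
    factor_corr: np.ndarray
    uniquenesses: np.ndarray
    corr: HetCorMatrix = field(repr=False)
    labels: list[str] = field(default_factory=list)
    factor_scores: pd.DataFrame | None = None
    loading_ci: pd.DataFrame | None = None

    @property
    def communalities(self) -> np.ndarray:
        return 1.0 - self.uniquenesses

    @property
    def structure(self) -> np.ndarray:
        return self.loadings.to_numpy() @ self.factor_corr


def _ml_objective(psi, R, nf):
    d = 1.0 / np.sqrt(psi)
    Rs = R * np.outer(d, d)
    w = np.linalg.eigvalsh(Rs)[::-1]
    e = w[nf:]
    return float(np.sum(e - np.log(e)) - (len(psi) - nf))


def _ml_gradient(psi, R, nf):
    d = 1.0 / np.sqrt(psi)
    Rs = R * np.outer(d, d)
    w, V = np.linalg.eigh(Rs)
    w, V = w[::-1], V[:, ::-1]
    lam = np.sqrt(np.maximum(w[:nf] - 1.0, 0.0))
    load = V[:, :nf] * lam
    load = load / d[:, None]
    g = load @ load.T + np.diag(psi) - R
    return np.diag(g) / psi**2


def _ml_extract(R: np.ndarray, nf: int, max_iter: int = 1000):
    """ML uniquenesses by L-BFGS-B; canonical (unrotated) loadings."""
    p = R.shape[0]
    smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    psi0 = np.clip(1.0 - smc, 0.05, 0.95)
    res = None
    for start in (psi0, np.full(p, 0.5)):
        res = optimize.minimize(
            _ml_objective,
            start,
            args=(R, nf),
            jac=_ml_gradient,
            method="L-BFGS-B",
            bounds=[(0.005, 1.0)] * p,
            options={"maxiter": max_iter},
        )
        if res.success or res.status == 1:  # maxiter: accept current best
            break
    if not (res.success or res.status == 1):
        raise RuntimeError(f"ML factor extraction did not converge: {res.message}")
    psi = res.x
    d = 1.0 / np.sqrt(psi)
    Rs = R * np.outer(d, d)
    w, V = np.linalg.eigh(Rs)
    w, V = w[::-1], V[:, ::-1]
    lam = np.sqrt(np.maximum(w[:nf] - 1.0, 0.0))
    load = (V[:, :nf] * lam) / d[:, None]
    return load, psi


def _oblimin_vgq(L: np.ndarray, gamma: float):
    p, nf = L.shape
    L2 = L**2
    N = np.ones((nf, nf)) - np.eye(nf)
    if gamma == 0.0:
        X = L2 @ N
    else:
        C = np.full((p, p), gamma / p)
        X = (np.eye(p) - C) @ L2 @ N
    return float(np.sum(L2 * X) / 4.0), L * X


def _gpa_oblique(A: np.ndarray, T0: np.ndarray, gamma: float, max_iter=500, tol=1e-8):
    T = T0.copy()
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _oblimin_vgq(L, gamma)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    for _ in range(max_iter):
        Gp = G - T * (T * G).sum(axis=0)
        s = np.sqrt(np.sum(Gp**2))
        if s < tol:
            break
        al *= 2.0
        for _ in range(20):
            X = T - al * Gp
            v = 1.0 / np.sqrt((X**2).sum(axis=0))
            Tt = X * v
            Ti = np.linalg.inv(Tt)
            Lt = A @ Ti.T
            ft, Gqt = _oblimin_vgq(Lt, gamma)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        T, f, L = Tt, ft, Lt
        G = -(L.T @ Gqt @ Ti).T
    Phi = T.T @ T
    return L, Phi, f


def oblimin_rotate(
    A: np.ndarray, gamma: float = 0.0, n_starts: int = 10, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Oblimin rotation (gamma=0: direct quartimin) by gradient projection.

    Runs from the identity plus random orthonormal starts and keeps the
    lowest-criterion solution. Returns (pattern, factor correlation) with
    columns ordered by explained variance and signs set so the majority of
    salient loadings are positive.
    """
    nf = A.shape[1]
    if nf == 1:
        L = A.copy()
        sgn = 1.0 if (L[np.abs(L[:, 0]) > 0.3, 0].sum() >= 0) else -1.0
        return L * sgn, np.eye(1)
    rng = np.random.default_rng(seed)
    best = None
    starts = [np.eye(nf)]
    for _ in range(n_starts - 1):
        Q, _r = np.linalg.qr(rng.standard_normal((nf, nf)))
        starts.append(Q)
    for T0 in starts:
        try:
            L, Phi, f = _gpa_oblique(A, T0, gamma)
        except np.linalg.LinAlgError:
            continue
        if best is None or f < best[2] - 1e-10:
            best = (L, Phi, f)
    if best is None:
        raise RuntimeError("oblimin rotation failed from all starts")
    L, Phi, _ = best
    # order columns by explained variance (sum of pattern*structure)
    S = L @ Phi
    ev = np.sum(L * S, axis=0)
    order = np.argsort(ev)[::-1]
    L, Phi = L[:, order], Phi[np.ix_(order, order)]
    # sign convention
    for j in range(nf):
        sal = np.abs(L[:, j]) > 0.3
        ref = L[sal, j].sum() if sal.any() else L[:, j].sum()
        if ref < 0:
            L[:, j] *= -1
            Phi[j, :] *= -1
            Phi[:, j] *= -1
    return L, Phi


def fit_ml_efa(
    corr: HetCorMatrix | np.ndarray,
    n_factors: int,
    rotation: str = "oblimin",
    gamma: float = 0.0,
    labels: list[str] | None = None,
) -> FactorSolution:
    """Maximum-likelihood EFA with oblimin rotation on a correlation matrix."""
    if not isinstance(corr, HetCorMatrix):
        R = np.asarray(corr, dtype=float)
        corr = HetCorMatrix(R, [f"v{i}" for i in range(R.shape[0])],
                            np.full(R.shape, "pearson", dtype=object))
    R = corr.matrix
    p = R.shape[0]
    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")
    if n_factors >= p / 2:
        raise ValueError("n_factors must be smaller than items/2")
    if rotation != "oblimin":
        raise ValueError("only oblimin rotation is supported")
    A, psi = _ml_extract(R, n_factors)
    L, Phi = oblimin_rotate(A, gamma=gamma)
    if labels is None:
        labels = [f"F{j + 1}" for j in range(n_factors)]
    loadings = pd.DataFrame(L, index=corr.variables, columns=labels)
    return FactorSolution(
        eigenvalues=corr.eigenvalues,
        n_factors=n_factors,
        loadings=loadings,
        factor_corr=Phi,
        uniquenesses=psi,
        corr=corr,
        labels=list(labels),
    )


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-by-column Tucker congruence matrix between two loading sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    num = a.T @ b
    den = np.sqrt(np.outer((a**2).sum(axis=0), (b**2).sum(axis=0)))
    return num / den


def factor_scores(solution: FactorSolution, table: pd.DataFrame) -> pd.DataFrame:
    """Thurstone regression factor scores, standardized to mean 0 / SD 1.

    Weights are W = R^-1 * (pattern @ factor_corr) computed from the
    heterogeneous correlation matrix. Participants with missing items are
    scored on their available items with the weight mass rescaled, and a
    warning is emitted.
    """
    vars_ = solution.corr.variables
    if list(table.columns) != vars_:
        table = table[vars_]
    X = table.to_numpy(dtype=float)
    mean = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant item: cannot standardize for scoring")
    Z = (X - mean) / sd
    W = np.linalg.solve(solution.corr.matrix, solution.structure)
    miss = np.isnan(Z)
    if miss.any():
        warnings.warn("missing item responses: scoring on available items with reweighting")
        Zf = np.where(miss, 0.0, Z)
        scores = Zf @ W
        total = np.abs(W).sum(axis=0)
        avail = (~miss).astype(float) @ np.abs(W)
        scores = scores * (total / np.maximum(avail, 1e-12))
    else:
        scores = Z @ W
    scores = (scores - scores.mean(axis=0)) / scores.std(axis=0, ddof=1)
    return pd.DataFrame(scores, index=table.index, columns=solution.labels)


def bootstrap_loading_cis(
    table: pd.DataFrame,
    var_types: dict[str, str],
    n_factors: int,
    n_boot: int = 1000,
    seed: int | None = None,
    reference: FactorSolution | None = None,
    _resampler=None,
) -> pd.DataFrame:
    """Percentile 95% CIs for oblimin pattern loadings by case resampling.

    Each replicate refits the heterogeneous correlation matrix and the EFA;
    replicate factors are matched to the full-sample solution by Tucker
    congruence (with sign alignment) before pooling. Non-converging
    replicates are dropped; more than 10% dropped is an error.
    """
    from scipy.optimize import linear_sum_assignment

    if n_boot < 100 and _resampler is None:
        raise ValueError("n_boot must be >= 100")
    if reference is None:
        reference = fit_ml_efa(hetcor_matrix(table, var_types), n_factors)
    ref_L = reference.loadings.to_numpy()
    rng = np.random.default_rng(seed)
    n = len(table)
    reps = []
    dropped = 0
    for b in range(n_boot):
        idx = _resampler(b) if _resampler is not None else rng.integers(0, n, n)
        sub = table.iloc[idx].reset_index(drop=True)
        try:
            sol = fit_ml_efa(hetcor_matrix(sub, var_types), n_factors)
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            dropped += 1
            continue
        L = sol.loadings.to_numpy()
        cong = tucker_congruence(ref_L, L)
        _rows, cols = linear_sum_assignment(-np.abs(cong))
        L = L[:, cols]
        signs = np.sign(np.diag(tucker_congruence(ref_L, L)))
        signs[signs == 0] = 1.0
        reps.append(L * signs)
    if dropped > 0.1 * n_boot:
        raise RuntimeError(f"{dropped}/{n_boot} bootstrap replicates failed")
    stack = np.stack(reps)
    lo = np.percentile(stack, 2.5, axis=0)
    hi = np.percentile(stack, 97.5, axis=0)
    out = {}
    for j, lab in enumerate(reference.labels):
        out[f"{lab}_lo"] = lo[:, j]
        out[f"{lab}_hi"] = hi[:, j]
    return pd.DataFrame(out, index=reference.loadings.index)
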