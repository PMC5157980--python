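"""Mixed linear models: REML variance components and SNP-BLUP effects.

The base model is y = X beta + sum_c g_c + e with g_c ~ N(0, K_c sigma2_g(c))
and e ~ N(0, I sigma2_e), where K_c = Z_c Z_c^T / M_c over standardized
genotypes.  Equivalently every SNP effect in component c is a random draw
from N(0, sigma2_u(c)) with sigma2_g(c) = M_c sigma2_u(c); SNP heritability
is h2 = sum_c sigma2_g(c) / (sum_c sigma2_g(c) + sigma2_e).

Fitting strategy:

* one genomic component: a single eigendecomposition of K reduces REML to a
  1-D optimization over the variance ratio (exact, no iteration risk);
* several components: average-information (AI) REML with EM fallback steps
  whenever an AI proposal leaves the parameter space, and a variance floor
  of 1e-8 x var(y);
* several traits: the shared-kinship multivariate model is rotated through
  the eigenbasis of K, which factorizes the restricted likelihood into n
  small TxT blocks; the genetic and residual covariance matrices are then
  maximized directly through their Cholesky factors.

Standard errors come from the inverse average-information matrix (univariate)
or the numerical observed-information matrix (multivariate), with delta-method
propagation to h2 and genetic correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class VarianceComponentEstimate:
    """REML fit of one or more genomic variance components."""

    sigma2_g: dict                 # component -> genomic variance M_c * sigma2_u(c)
    sigma2_e: float
    h2: float
    se_sigma2_g: dict
    se_sigma2_e: float
    se_h2: float
    beta: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    trace: list = field(default_factory=list)
    param_cov: np.ndarray | None = None   # cov of (sigma2_g..., sigma2_e)

    @property
    def total_sigma2_g(self) -> float:
        return float(sum(self.sigma2_g.values()))


@dataclass
class SNPEffectSet:
    """Per-variant standardized-scale BLUP effects with training stats."""

    table: pd.DataFrame  # columns: id, a1, effect, mean, sd, component
    description: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.table["effect"]).all():
            raise ValueError("non-finite SNP effects")

    @property
    def effects(self) -> np.ndarray:
        return self.table["effect"].to_numpy()


def _as_matrix(k):
    return np.asarray(getattr(k, "values", k), dtype=float)


def _design(X, n):
    if X is None:
        return np.ones((n, 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n:
        X = X.T
    if not (X.std(axis=0) == 0).any():  # ensure an intercept column
        X = np.column_stack([np.ones(n), X])
    return X


# ---------------------------------------------------------------------------
# Single-component REML (exact eigendecomposition path)
# ---------------------------------------------------------------------------

def _reml_single(y, X, K, tol):
    n, p = X.shape
    d, U = np.linalg.eigh(K)
    d = np.maximum(d, 0.0)
    ys = U.T @ y
    Xs = U.T @ X

    def profile(log_delta):
        """REML log-likelihood profiled over sigma2_e at ratio delta."""
        delta = np.exp(log_delta)
        w = delta * d + 1.0
        Xw = Xs / w[:, None]
        C = Xs.T @ Xw
        beta = np.linalg.solve(C, Xw.T @ ys)
        r = ys - Xs @ beta
        rss = float(r @ (r / w))
        s2e = rss / (n - p)
        ll = -0.5 * ((n - p) * np.log(s2e) + np.log(w).sum()
                     + np.linalg.slogdet(C)[1] + (n - p)
                     + (n - p) * _LOG2PI)
        return ll, beta, s2e

    res = optimize.minimize_scalar(lambda t: -profile(t)[0],
                                   bounds=(-14.0, 14.0), method="bounded",
                                   options={"xatol": 1e-10})
    ll, beta, s2e = profile(res.x)
    delta = float(np.exp(res.x))
    s2g = delta * s2e

    # average-information matrix at the optimum, parameters (s2g, s2e)
    v = s2g * d + s2e
    Xv = Xs / v[:, None]
    C = Xs.T @ Xv
    Cinv = np.linalg.inv(C)
    r = ys - Xs @ beta
    q = r / v                      # rotated P y
    t_vecs = [d * q, q]            # K P y and I P y, rotated

    def apply_p(t):
        vt = t / v
        return vt - Xv @ (Cinv @ (Xs.T @ vt))

    ai = np.empty((2, 2))
    pts = [apply_p(t) for t in t_vecs]
    for i in range(2):
        for j in range(2):
            ai[i, j] = 0.5 * float(t_vecs[i] @ pts[j])
    cov = _safe_inverse(ai)
    return (s2g, s2e, beta, ll, cov, True, int(res.nfev),
            [{"loglik": ll, "sigma2": [s2g, s2e]}])


def _safe_inverse(a):
    try:
        return np.linalg.inv(a)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(a)


# ---------------------------------------------------------------------------
# Multi-component AI-REML
# ---------------------------------------------------------------------------

def _reml_ai(y, X, Ks, tol, max_iter):
    n, p = X.shape
    c = len(Ks)
    vary = float(np.var(y))
    floor = 1e-8 * vary
    theta = np.full(c + 1, vary / (c + 1))
    trace_rec = []
    ll_old = -np.inf
    converged = False

    for it in range(max_iter):
        V = theta[c] * np.eye(n)
        for i in range(c):
            V += theta[i] * Ks[i]
        L = cho_factor(V, lower=True)
        Vinv = cho_solve(L, np.eye(n))
        VinvX = Vinv @ X
        C = X.T @ VinvX
        Cinv = _safe_inverse(C)
        beta = Cinv @ (VinvX.T @ y)
        Py = Vinv @ (y - X @ beta)
        logdetV = 2.0 * np.log(np.diag(L[0])).sum()
        ll = -0.5 * (logdetV + np.linalg.slogdet(C)[1]
                     + float((y - X @ beta) @ Py) + (n - p) * _LOG2PI)

        mats = Ks + [np.eye(n)]
        u = [m @ Py for m in mats]
        Pu = [Vinv @ ui - VinvX @ (Cinv @ (VinvX.T @ ui)) for ui in u]
        ai = 0.5 * np.array([[ui @ Puj for Puj in Pu] for ui in u])
        # tr(P K_c) without forming n^3 products: tr(AB) = sum(A * B^T)
        PK_tr = [float((Vinv * m).sum()
                       - (Cinv * (VinvX.T @ (m @ VinvX))).sum())
                 for m in mats]
        score = np.array([-0.5 * (PK_tr[i] - Py @ u[i]) for i in range(c + 1)])

        trace_rec.append({"loglik": float(ll), "sigma2": theta.tolist()})
        if abs(ll - ll_old) < tol and it > 0:
            converged = True
            break
        ll_old = ll

        if it == 0:
            proposal = None  # first step always EM (stabilizes AI)
        else:
            try:
                proposal = theta + np.linalg.solve(ai, score)
                if (proposal < floor).any():
                    # clamp offending components at the floor and take the
                    # AI step on the remaining free ones
                    bad = proposal < floor
                    free = np.flatnonzero(~bad)
                    proposal = theta.copy()
                    proposal[bad] = floor
                    if len(free):
                        sub = np.linalg.solve(ai[np.ix_(free, free)],
                                              score[free])
                        proposal[free] = theta[free] + sub
                    if (proposal < floor).any():
                        proposal = None
            except np.linalg.LinAlgError:
                proposal = None
        if proposal is None:
            # EM fallback step, per component
            proposal = theta + theta ** 2 * np.array(
                [(Py @ u[i] - PK_tr[i]) / n for i in range(c + 1)])
            proposal = np.maximum(proposal, floor)
        theta = proposal

    cov = _safe_inverse(ai)
    return theta[:c], theta[c], beta, float(ll), cov, converged, it + 1, trace_rec


def reml_fit(y, X=None, kinships=None, *, tol: float = 1e-6,
             max_iter: int = 100) -> VarianceComponentEstimate:
    """REML estimation of genomic variance components.

    ``kinships`` is one kinship matrix or an ordered mapping
    component name -> matrix (K_c = Z_c Z_c^T / M_c).  Rows with missing
    phenotype or covariates are dropped from y, X and every K.  A fit that
    hits ``max_iter`` is returned flagged, never silently.
    """
    y = np.asarray(y, dtype=float).ravel()
    n_all = len(y)
    if kinships is None:
        raise ValueError("at least one kinship matrix required")
    if not isinstance(kinships, dict):
        kinships = {"all": kinships}
    names = list(kinships)
    Ks = [_as_matrix(kinships[nm]) for nm in names]
    for K in Ks:
        if K.shape != (n_all, n_all):
            raise ValueError("kinship dimensions do not match phenotype")
        sym_err = np.abs(K - K.T).max()
        if sym_err > 1e-8:
            raise ValueError("kinship matrix is not symmetric")

    X = _design(X, n_all)
    ok = np.isfinite(y) & np.isfinite(X).all(axis=1)
    if not ok.all():
        y, X = y[ok], X[ok]
        Ks = [K[np.ix_(ok, ok)] for K in Ks]

    if len(Ks) == 1:
        mineig = np.linalg.eigvalsh(Ks[0]).min()
        if mineig < -1e-6 * max(1.0, np.abs(Ks[0]).max()):
            raise ValueError("kinship matrix is not PSD within tolerance")
        s2g, s2e, beta, ll, cov, conv, it, tr = _reml_single(y, X, Ks[0], tol)
        sg = np.array([s2g])
    else:
        sg, s2e, beta, ll, cov, conv, it, tr = _reml_ai(y, X, Ks, tol, max_iter)
        sg = np.asarray(sg)
        if not conv:
            warnings.warn("AI-REML did not converge within max_iter; "
                          "estimate flagged", RuntimeWarning)

    total = float(sg.sum() + s2e)
    h2 = float(sg.sum() / total)
    # delta-method SEs from the (sigma2_g..., sigma2_e) covariance
    grad = np.append(np.full(len(sg), s2e), -sg.sum()) / total ** 2
    se_h2 = float(np.sqrt(max(0.0, grad @ cov @ grad)))
    ses = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return VarianceComponentEstimate(
        sigma2_g={nm: float(v) for nm, v in zip(names, sg)},
        sigma2_e=float(s2e), h2=h2,
        se_sigma2_g={nm: float(v) for nm, v in zip(names, ses[:-1])},
        se_sigma2_e=float(ses[-1]), se_h2=se_h2,
        beta=beta, loglik=float(ll), converged=bool(conv), n_iter=it,
        trace=tr, param_cov=cov)


# ---------------------------------------------------------------------------
# SNP-BLUP back-solve
# ---------------------------------------------------------------------------

def snp_blup(z, X, y, estimate: VarianceComponentEstimate, stats=None,
             kinships=None, description: str = "snp_blup") -> SNPEffectSet:
    """Back-solve standardized-scale SNP effects from a fitted model.

    ``z`` is one standardized matrix or a mapping component -> matrix
    aligned with ``estimate.sigma2_g``; ``stats`` the matching
    StandardizationStats (same layout).  Effects are
    a_c = sigma2_u(c) Z_c^T V^{-1} (y - X beta) with
    sigma2_u(c) = sigma2_g(c) / M_c and V = sum_c sigma2_u(c) Z_c Z_c^T
    + sigma2_e I.  Passing precomputed ``kinships`` (component -> K_c =
    Z_c Z_c^T / M_c) skips rebuilding the covariance from Z.
    """
    if not isinstance(z, dict):
        z = {next(iter(estimate.sigma2_g)): z}
    if stats is not None and not isinstance(stats, dict):
        stats = {next(iter(estimate.sigma2_g)): stats}
    if kinships is not None and not isinstance(kinships, dict):
        kinships = {next(iter(estimate.sigma2_g)): kinships}
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    X = _design(X, n)
    ok = np.isfinite(y) & np.isfinite(X).all(axis=1)
    y, X = y[ok], X[ok]

    V = estimate.sigma2_e * np.eye(len(y))
    s2u = {}
    for name, Zc in z.items():
        mc = np.asarray(Zc).shape[1]
        s2u[name] = estimate.sigma2_g[name] / mc
        if kinships is not None:
            Kc = _as_matrix(kinships[name])[np.ix_(ok, ok)]
            V += estimate.sigma2_g[name] * Kc
        else:
            Zc = np.asarray(Zc, dtype=float)[ok]
            V += s2u[name] * (Zc @ Zc.T)
    L = cho_factor(V, lower=True)
    VinvX = cho_solve(L, X)
    beta = np.linalg.solve(X.T @ VinvX, VinvX.T @ y)
    w = cho_solve(L, y - X @ beta)

    frames = []
    for name, Zc in z.items():
        Zc = np.asarray(Zc, dtype=float)[ok]
        eff = s2u[name] * (Zc.T @ w)
        if stats is not None:
            tab = stats[name].table[["id", "a1", "mean", "sd"]].copy()
        else:
            tab = pd.DataFrame({"id": [f"{name}_{j}" for j in range(Zc.shape[1])],
                                "a1": "A", "mean": 0.0, "sd": 1.0})
        tab["effect"] = eff
        tab["component"] = name
        frames.append(tab[["id", "a1", "effect", "mean", "sd", "component"]])
    return SNPEffectSet(pd.concat(frames, ignore_index=True), description)


# ---------------------------------------------------------------------------
# Component assignments
# ---------------------------------------------------------------------------

def effect_outlier_groups(effects) -> np.ndarray:
    """Split SNPs into {main, tail} by marginal effect size.

    Tail = estimates more than 3 SDs from the mean effect across all SNPs
    (two-sided); the rest stay in the main distribution.  Degenerate SD=0
    puts everything in main, with a warning.
    """
    a = np.asarray(getattr(effects, "beta", effects), dtype=float).ravel()
    mu, sd = a.mean(), a.std()
    labels = np.full(a.shape, "main", dtype=object)
    if sd == 0:
        warnings.warn("zero SD of marginal effects; no tail group formed")
        return labels
    labels[np.abs(a - mu) > 3.0 * sd] = "tail"
    return labels


MAF_GROUP_BOUNDS = {"common": (0.05, 0.5), "low_freq": (0.01, 0.05),
                    "rare": (0.001, 0.01)}


def maf_groups(mafs) -> np.ndarray:
    """Assign variants to MAF strata with strict boundary inequalities.

    common: MAF > 0.05; low_freq: 0.01 < MAF < 0.05; rare:
    0.001 < MAF < 0.01.  Variants exactly at a boundary or with
    MAF <= 0.001 are 'unassigned' (reported via warning).
    """
    m = np.asarray(mafs, dtype=float)
    if (m < 0).any() or (m > 0.5).any():
        raise ValueError("MAF values must lie in [0, 0.5]")
    labels = np.full(m.shape, "unassigned", dtype=object)
    labels[m > 0.05] = "common"
    labels[(m > 0.01) & (m < 0.05)] = "low_freq"
    labels[(m > 0.001) & (m < 0.01)] = "rare"
    n_un = int((labels == "unassigned").sum())
    if n_un:
        warnings.warn(f"{n_un} variants unassigned under strict MAF boundaries")
    return labels


# ---------------------------------------------------------------------------
# Multivariate REML
# ---------------------------------------------------------------------------

@dataclass
class MultivariateEstimate:
    """Multivariate REML fit: TxT genetic and residual covariance matrices."""

    traits: list
    sigma_g: np.ndarray            # genomic covariance (M * SNP-effect cov)
    sigma_e: np.ndarray
    genetic_correlation: np.ndarray
    environmental_correlation: np.ndarray
    se_genetic_correlation: np.ndarray
    h2: np.ndarray
    beta: np.ndarray               # (p x T)
    loglik: float
    converged: bool
    _eig: tuple | None = None      # (d, U) of the kinship, for back-solving


def _chol_from_packed(v, t):
    L = np.zeros((t, t))
    L[np.tril_indices(t)] = v
    return L


def reml_fit_multivariate(Y, X=None, kinship=None, *, tol: float = 1e-8,
                          max_iter: int = 500,
                          traits=None) -> MultivariateEstimate:
    """Multivariate REML for T traits sharing one kinship matrix.

    Samples with any missing trait or covariate are dropped listwise.  The
    kinship eigenbasis factorizes the likelihood into TxT blocks, which is
    maximized over Cholesky factors of the genetic and residual covariance
    matrices (PSD by construction).  Genetic correlations get delta-method
    SEs from the numerically observed information.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[1] < 2:
        raise ValueError("multivariate fit needs an n x T matrix with T >= 2; "
                         "use reml_fit for a single trait")
    n_all, t = Y.shape
    traits = list(traits) if traits is not None else [f"trait{i}" for i in range(t)]
    K = _as_matrix(kinship)
    X = _design(X, n_all)
    ok = np.isfinite(Y).all(axis=1) & np.isfinite(X).all(axis=1)
    Y, X = Y[ok], X[ok]
    K = K[np.ix_(ok, ok)]
    n, p = X.shape

    d, U = np.linalg.eigh(K)
    d = np.maximum(d, 0.0)
    Yt = U.T @ Y
    Xt = U.T @ X

    tri = np.tril_indices(t)
    covY = np.cov(Y.T)

    def unpack(params):
        Lg = _chol_from_packed(params[:len(tri[0])], t)
        Le = _chol_from_packed(params[len(tri[0]):], t)
        return Lg @ Lg.T, Le @ Le.T + 1e-10 * np.trace(covY) / t * np.eye(t)

    def negll_from_cov(Sg, Se):
        V = d[:, None, None] * Sg[None] + Se[None]        # (n, t, t)
        sign, logdet = np.linalg.slogdet(V)
        if (sign <= 0).any():
            return np.inf, None
        Vinv = np.linalg.inv(V)
        C = np.einsum("ni,nj,nab->iajb", Xt, Xt, Vinv).reshape(p * t, p * t)
        rhs = np.einsum("ni,nab,nb->ia", Xt, Vinv, Yt).reshape(p * t)
        try:
            B = np.linalg.solve(C, rhs).reshape(p, t)
        except np.linalg.LinAlgError:
            return np.inf, None
        R = Yt - Xt @ B
        quad = float(np.einsum("na,nab,nb->", R, Vinv, R))
        ll = -0.5 * (logdet.sum() + np.linalg.slogdet(C)[1] + quad
                     + (n - p) * t * _LOG2PI)
        return -ll, B

    def negll(params):
        Sg, Se = unpack(params)
        return negll_from_cov(Sg, Se)[0]

    L0g = np.linalg.cholesky(0.5 * covY + 1e-6 * np.eye(t))
    L0e = np.linalg.cholesky(0.5 * covY + 1e-6 * np.eye(t))
    x0 = np.concatenate([L0g[tri], L0e[tri]])
    res = optimize.minimize(negll, x0, method="L-BFGS-B",
                            options={"maxiter": max_iter, "ftol": tol,
                                     "gtol": 1e-10})
    Sg, Se = unpack(res.x)
    nll, B = negll_from_cov(Sg, Se)

    dg = np.sqrt(np.diag(Sg))
    de = np.sqrt(np.diag(Se))
    rg = Sg / np.outer(dg, dg)
    re = Se / np.outer(de, de)
    h2 = np.diag(Sg) / (np.diag(Sg) + np.diag(Se))

    se_rg = _rg_standard_errors(Sg, Se, negll_from_cov, t, tri)

    return MultivariateEstimate(
        traits=traits, sigma_g=Sg, sigma_e=Se,
        genetic_correlation=rg, environmental_correlation=re,
        se_genetic_correlation=se_rg, h2=h2, beta=B,
        loglik=float(-nll), converged=bool(res.success), _eig=(d, U))


def _rg_standard_errors(Sg, Se, negll_from_cov, t, tri):
    """Delta-method SEs for genetic correlations via numerical information."""
    def theta_to_cov(theta):
        Sg2, Se2 = np.zeros((t, t)), np.zeros((t, t))
        k = len(tri[0])
        Sg2[tri] = theta[:k]
        Sg2 += np.tril(Sg2, -1).T
        Se2[tri] = theta[k:]
        Se2 += np.tril(Se2, -1).T
        return Sg2, Se2

    theta0 = np.concatenate([Sg[tri], Se[tri]])
    scale = np.maximum(np.abs(theta0), 1e-3 * np.abs(theta0).max())
    h = 1e-4 * scale

    def f(theta):
        return negll_from_cov(*theta_to_cov(theta))[0]

    k = len(theta0)
    H = np.empty((k, k))
    f0 = f(theta0)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpp = f(theta0 + ei + ej)
            fpm = f(theta0 + ei - ej)
            fmp = f(theta0 - ei + ej)
            fmm = f(theta0 - ei - ej)
            with np.errstate(invalid="ignore"):
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    # boundary optima (e.g. rg -> 1) can make probe points infeasible;
    # zero curvature there lets the pseudo-inverse report a wide SE instead
    H[~np.isfinite(H)] = 0.0
    cov = _safe_inverse(H)

    se = np.zeros((t, t))
    kk = len(tri[0])
    for a in range(t):
        for b in range(a + 1, t):
            # rg = s_ab / sqrt(s_aa s_bb); gradient wrt packed Sg entries
            s_aa, s_bb, s_ab = Sg[a, a], Sg[b, b], Sg[a, b]
            denom = np.sqrt(s_aa * s_bb)
            grad = np.zeros(k)
            for idx, (r, c) in enumerate(zip(*tri)):
                if (r, c) == (b, a) or (r, c) == (a, b):
                    grad[idx] = 1.0 / denom
                elif (r, c) == (a, a):
                    grad[idx] = -0.5 * s_ab / (denom * s_aa)
                elif (r, c) == (b, b):
                    grad[idx] = -0.5 * s_ab / (denom * s_bb)
            var = float(grad @ cov @ grad)
            se[a, b] = se[b, a] = np.sqrt(max(var, 0.0))
    return se


def snp_blup_multivariate(z, X, Y, estimate: MultivariateEstimate,
                          stats=None) -> dict:
    """Back-solve per-trait SNP effects from a multivariate fit.

    Returns trait -> SNPEffectSet.  Effects for SNP j are
    Sigma_u (Z^T V^{-1} (y - X B))_j with Sigma_u = Sigma_g / M, computed
    in the kinship eigenbasis stored on the estimate.
    """
    Z = np.asarray(z, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n_all, t = Y.shape
    X = _design(X, n_all)
    ok = np.isfinite(Y).all(axis=1) & np.isfinite(X).all(axis=1)
    Z, Y, X = Z[ok], Y[ok], X[ok]
    d, U = estimate._eig
    if U.shape[0] != Z.shape[0]:
        raise ValueError("estimate eigenbasis does not match sample count")
    m = Z.shape[1]
    Su = estimate.sigma_g / m

    Yt, Xt = U.T @ Y, U.T @ X
    # the big rotation dominates runtime; float32 precision is far below
    # the statistical noise in the effects
    Zt = (U.astype(np.float32).T @ Z.astype(np.float32)).astype(np.float64)
    V = d[:, None, None] * estimate.sigma_g[None] + estimate.sigma_e[None]
    Vinv = np.linalg.inv(V)
    R = Yt - Xt @ estimate.beta
    W = np.einsum("nab,nb->na", Vinv, R)      # V^{-1} residual, rotated
    A = (Zt.T @ W) @ Su                        # (m x t) standardized effects

    out = {}
    for ti, trait in enumerate(estimate.traits):
        if stats is not None:
            tab = stats.table[["id", "a1", "mean", "sd"]].copy()
        else:
            tab = pd.DataFrame({"id": [f"snp{j}" for j in range(m)],
                                "a1": "A", "mean": 0.0, "sd": 1.0})
        tab["effect"] = A[:, ti]
        tab["component"] = "all"
        out[trait] = SNPEffectSet(
            tab[["id", "a1", "effect", "mean", "sd", "component"]],
            description=f"multivariate blup, trait {trait}")
    return out
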