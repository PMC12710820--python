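"""Independence, Gaussian and t copulas for count data.

The Gaussian copula C_R(u) = Phi_R(Phi^-1(u_1), ..., Phi^-1(u_d)) is
parametrized by a correlation matrix R. Three estimators of R are
provided for discrete margins:

* ``sample`` ("counts"): sample correlation of normal scores of the
  midpoints (u- + u+)/2 of the pseudo-observation rectangles;
* ``jittered``: sample correlation of normal scores of one
  distributional-transform draw;
* ``ml``: pairwise composite maximum likelihood, where each rho_ij
  maximizes the discrete bivariate likelihood built from rectangle
  probabilities of the bivariate normal.

The t copula C_{nu,R} adds tail dependence; it is fit in two stages:
R by Kendall-tau inversion R_ij = sin(pi tau_ij / 2), then the degrees
of freedom nu by profiling the jittered-data log-likelihood over
[1, 100]. The independence copula is the no-dependence baseline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats
from statsmodels.stats.correlation_tools import corr_nearest

from .ingest import CountMatrix
from .margins import MarginModel, jitter, pseudo_observations

logger = logging.getLogger(__name__)

_EIG_FLOOR = 1e-8
NU_MIN, NU_MAX = 1.0, 100.0


# ---------------------------------------------------------------------------
# correlation-matrix plumbing

@dataclass
class CorrelationMatrix:
    """Symmetric PSD matrix with unit diagonal and eigenvalues >= 1e-8."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.min(np.linalg.eigvalsh(v)) < _EIG_FLOOR / 2:
            raise ValueError("correlation matrix is not positive definite")
        self.values = (v + v.T) / 2

    @property
    def d(self) -> int:
        return self.values.shape[0]


def nearest_correlation(M: np.ndarray) -> CorrelationMatrix:
    """Project a symmetric matrix to the nearest valid correlation matrix.

    Uses alternating projections with an eigenvalue floor; a matrix that
    is already valid is returned unchanged (up to symmetrization).
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1] or not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("input must be a symmetric square matrix")
    sym = (M + M.T) / 2
    np.fill_diagonal(sym, 1.0)
    if np.min(np.linalg.eigvalsh(sym)) >= _EIG_FLOOR and np.max(np.abs(sym)) <= 1 + 1e-12:
        return CorrelationMatrix(np.clip(sym, -1, 1))
    sym = np.clip(sym, -1, 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fixed = corr_nearest(sym, threshold=_EIG_FLOOR, n_fact=1000)
    fixed = np.clip((fixed + fixed.T) / 2, -1, 1)
    np.fill_diagonal(fixed, 1.0)
    w, V = np.linalg.eigh(fixed)
    if w.min() < _EIG_FLOOR:
        w = np.maximum(w, _EIG_FLOOR)
        fixed = (V * w) @ V.T
        scale = np.sqrt(np.diag(fixed))
        fixed = fixed / np.outer(scale, scale)
        np.fill_diagonal(fixed, 1.0)
        fixed = (fixed + fixed.T) / 2
    return CorrelationMatrix(fixed)


@dataclass
class IndependenceCopula:
    d: int

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("dimension must be >= 1")


@dataclass
class GaussianCopula:
    R: CorrelationMatrix
    estimator_tag: str = "sample"

    @property
    def d(self) -> int:
        return self.R.d


@dataclass
class TCopula:
    R: CorrelationMatrix
    nu: float = 10.0
    estimator_tag: str = field(default="two_stage_ml")

    def __post_init__(self) -> None:
        # [NU_MIN, NU_MAX] bounds apply to fitting; sampling allows any nu > 0
        if self.nu <= 0:
            raise ValueError("nu must be positive")

    @property
    def d(self) -> int:
        return self.R.d


# ---------------------------------------------------------------------------
# bivariate normal CDF (Owen's T), used by the ML estimator and CDF oracle

def bvn_cdf(h, k, rho: float) -> np.ndarray:
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Owen's (1956) reduction to two Owen T terms; handles infinite bounds
    and the boundary correlations rho = +-1 exactly.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k = np.broadcast_arrays(h, k)
    if abs(rho) >= 1 - 1e-14:
        if rho > 0:
            return stats.norm.cdf(np.minimum(h, k))
        return np.maximum(0.0, stats.norm.cdf(h) + stats.norm.cdf(k) - 1.0)

    out = np.empty(h.shape, dtype=float)
    neg_inf = np.isneginf(h) | np.isneginf(k)
    h_inf = np.isposinf(h)
    k_inf = np.isposinf(k)
    out[neg_inf] = 0.0
    out[h_inf & ~neg_inf] = stats.norm.cdf(k[h_inf & ~neg_inf])
    out[k_inf & ~neg_inf & ~h_inf] = stats.norm.cdf(h[k_inf & ~neg_inf & ~h_inf])

    fin = ~(neg_inf | h_inf | k_inf)
    hf, kf = h[fin], k[fin]
    s = np.sqrt(1.0 - rho * rho)

    def _t_term(a, b):
        # T(a, (b - rho a)/(a s)) with the a -> 0 limit T -> sign(b)/4
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = (b - rho * a) / (a * s)
        t = special.owens_t(a, np.where(np.isfinite(slope), slope, 0.0))
        zero_a = a == 0
        if np.any(zero_a):
            t = np.where(zero_a, np.sign(b) * 0.25, t)
        return t

    both_zero = (hf == 0) & (kf == 0)
    res = (
        0.5 * (stats.norm.cdf(hf) + stats.norm.cdf(kf))
        - _t_term(hf, kf)
        - _t_term(kf, hf)
        - np.where((hf * kf > 0) | ((hf * kf == 0) & (hf + kf >= 0)), 0.0, 0.5)
    )
    res = np.where(both_zero, 0.25 + np.arcsin(rho) / (2 * np.pi), res)
    out[fin] = res
    return np.clip(out, 0.0, 1.0)


def gaussian_copula_cdf(gc: GaussianCopula, u: np.ndarray) -> float:
    """C_R(u) for d <= 3, via the (numerical) multivariate normal CDF."""
    u = np.asarray(u, dtype=float)
    d = u.size
    if d != gc.d:
        raise ValueError(f"point has dimension {d}, copula has {gc.d}")
    if d > 3:
        raise NotImplementedError("gaussian_copula_cdf supports d <= 3 only")
    if np.any(u <= 0) or np.any(u >= 1):
        raise ValueError("u must lie strictly in (0,1)^d")
    z = stats.norm.ppf(u)
    if d == 1:
        return float(u[0])
    if d == 2:
        return float(bvn_cdf(z[0], z[1], gc.R.values[0, 1]))
    return float(stats.multivariate_normal(mean=np.zeros(3), cov=gc.R.values).cdf(z))


# ---------------------------------------------------------------------------
# Gaussian estimators

def _normal_scores_corr(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sample correlation of score columns; constant columns get rho = 0."""
    constant = z.std(axis=0) < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(z, rowvar=False)
    corr = np.where(np.isfinite(corr), corr, 0.0)
    np.fill_diagonal(corr, 1.0)
    return corr, constant


def fit_gaussian_sample(
    cm: CountMatrix,
    margins: list[MarginModel],
    variant: str = "counts",
    rng_seed: int = 0,
) -> GaussianCopula:
    """Sample-correlation Gaussian copula estimators.

    ``variant="counts"`` takes normal scores of the rectangle midpoints
    (u- + u+)/2; ``variant="jittered"`` takes normal scores of one seeded
    distributional-transform draw.
    """
    if cm.n_genes < 2:
        raise ValueError("need at least 2 genes")
    if variant == "counts":
        u = pseudo_observations(cm, margins).mid
        tag = "sample"
    elif variant == "jittered":
        u = jitter(cm, margins, rng_seed)
        tag = "jittered"
    else:
        raise ValueError(f"unknown variant {variant!r}")
    z = stats.norm.ppf(np.clip(u, 1e-12, 1 - 1e-12))
    corr, constant = _normal_scores_corr(z)
    if constant.any():
        names = [cm.gene_ids[i] for i in np.flatnonzero(constant)]
        logger.warning("constant gene(s) %s: correlations set to 0", names)
    return GaussianCopula(R=nearest_correlation(corr), estimator_tag=tag)


def _pair_rectangles(u_minus: np.ndarray, u_plus: np.ndarray, i: int, j: int):
    """Unique z-scale rectangles for genes (i, j) with multiplicities."""
    rect = np.column_stack(
        [u_minus[:, i], u_plus[:, i], u_minus[:, j], u_plus[:, j]]
    )
    uniq, counts = np.unique(rect, axis=0, return_counts=True)
    with np.errstate(divide="ignore"):
        z = stats.norm.ppf(uniq)  # u=0 maps to -inf, handled by bvn_cdf
    return z, counts


def _pair_neg_loglik(rho: float, z: np.ndarray, w: np.ndarray) -> float:
    p = (
        bvn_cdf(z[:, 1], z[:, 3], rho)
        - bvn_cdf(z[:, 0], z[:, 3], rho)
        - bvn_cdf(z[:, 1], z[:, 2], rho)
        + bvn_cdf(z[:, 0], z[:, 2], rho)
    )
    return -float(np.dot(w, np.log(np.maximum(p, 1e-300))))


def fit_gaussian_ml(
    cm: CountMatrix,
    margins: list[MarginModel],
    max_iter: int = 100,
    tol: float = 1e-5,
) -> GaussianCopula:
    """Pairwise composite-ML Gaussian copula for discrete margins.

    For each gene pair, rho maximizes the sum over cells of the log
    probability that the latent bivariate normal falls in the rectangle
    (Phi^-1(u-), Phi^-1(u+)] x (Phi^-1(v-), Phi^-1(v+)]. Pairs whose
    optimization fails fall back to the sample estimate.
    """
    if cm.n_genes < 2:
        raise ValueError("need at least 2 genes")
    po = pseudo_observations(cm, margins)
    fallback = fit_gaussian_sample(cm, margins, variant="counts").R.values
    m = cm.n_genes
    R = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            z, w = _pair_rectangles(po.u_minus, po.u_plus, i, j)
            try:
                res = optimize.minimize_scalar(
                    _pair_neg_loglik,
                    args=(z, w),
                    bounds=(-0.999, 0.999),
                    method="bounded",
                    options={"xatol": tol, "maxiter": max_iter},
                )
                if not res.success or not np.isfinite(res.fun):
                    raise RuntimeError(res.message)
                R[i, j] = R[j, i] = res.x
            except Exception as exc:  # pragma: no cover - defensive
                logger.warning(
                    "ML fit failed for pair (%s, %s): %s; using sample estimate",
                    cm.gene_ids[i], cm.gene_ids[j], exc,
                )
                R[i, j] = R[j, i] = fallback[i, j]
    return GaussianCopula(R=nearest_correlation(R), estimator_tag="ml")


# ---------------------------------------------------------------------------
# t copula

def kendall_tau_inversion(tau: np.ndarray) -> np.ndarray:
    """Elliptical-copula relation R = sin(pi tau / 2), entrywise."""
    tau = np.asarray(tau, dtype=float)
    if np.any(np.abs(tau) > 1):
        raise ValueError("Kendall tau entries must lie in [-1, 1]")
    return np.sin(np.pi * tau / 2.0)


def kendall_tau_matrix(u: np.ndarray) -> np.ndarray:
    """Pairwise Kendall tau-b of the columns of u."""
    m = u.shape[1]
    tau = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            t = stats.kendalltau(u[:, i], u[:, j]).statistic
            tau[i, j] = tau[j, i] = 0.0 if np.isnan(t) else t
    return tau


def t_copula_loglik(u: np.ndarray, R: np.ndarray, nu: float) -> float:
    """Log-likelihood of continuous copula-scale data under a t copula."""
    x = stats.t.ppf(np.clip(u, 1e-12, 1 - 1e-12), df=nu)
    joint = stats.multivariate_t(loc=np.zeros(R.shape[0]), shape=R, df=nu).logpdf(x)
    margs = stats.t.logpdf(x, df=nu).sum(axis=1)
    return float(np.sum(joint - margs))


def fit_t(
    cm: CountMatrix,
    margins: list[MarginModel],
    nu_grid_or_bounds=(NU_MIN, NU_MAX),
    rng_seed: int = 0,
) -> TCopula:
    """Two-stage ML t copula fit on counts.

    Stage 1 estimates R by Kendall-tau inversion on jittered pseudo-data;
    stage 2 profiles the jittered-data log-likelihood over nu with R held
    fixed (bounded search, tolerance 1e-3, or an explicit grid).
    """
    if cm.n_genes < 2:
        raise ValueError("t copula requires at least 2 genes")
    u = jitter(cm, margins, rng_seed)
    tau = kendall_tau_matrix(u)
    R = nearest_correlation(kendall_tau_inversion(tau))

    grid = np.asarray(nu_grid_or_bounds, dtype=float)
    if grid.size == 2:
        lo, hi = float(grid[0]), float(grid[1])
        res = optimize.minimize_scalar(
            lambda nu: -t_copula_loglik(u, R.values, nu),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-3},
        )
        nu_hat = float(res.x)
    else:
        lls = [t_copula_loglik(u, R.values, nu) for nu in grid]
        nu_hat = float(grid[int(np.argmax(lls))])
    return TCopula(R=R, nu=nu_hat)


# ---------------------------------------------------------------------------
# samplers

def _correlated_normals(R: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(R)
        L = V * np.sqrt(np.maximum(w, 0.0))
    return rng.standard_normal((n, R.shape[0])) @ L.T


def sample_gaussian(gc: GaussianCopula, n: int, rng_seed: int) -> np.ndarray:
    """n draws from the Gaussian copula: Phi applied to Z ~ N(0, R)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    z = _correlated_normals(gc.R.values, n, rng)
    return stats.norm.cdf(z)


def sample_t(tc: TCopula, n: int, rng_seed: int) -> np.ndarray:
    """n draws from the t copula: t_nu CDF of Z sqrt(nu / W), W ~ chi2_nu."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    z = _correlated_normals(tc.R.values, n, rng)
    w = rng.chisquare(tc.nu, size=n)
    x = z * np.sqrt(tc.nu / w)[:, None]
    return stats.t.cdf(x, df=tc.nu)


def sample_independence(d: int, n: int, rng_seed: int) -> np.ndarray:
    """n iid Uniform(0,1)^d draws (the independence copula)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return np.random.default_rng(rng_seed).uniform(size=(n, d))
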