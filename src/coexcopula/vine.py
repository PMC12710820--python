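"""Vine (pair-copula construction) models.

A d-dimensional copula density is factorized into d(d-1)/2 bivariate
"pair" copulas arranged in a hierarchy of trees: tree 1 is a spanning
tree on the variables, and each later tree's nodes are the previous
tree's edges, joined only where they share a node (the proximity
condition). The simplified construction drops the dependence of
conditional pair copulas on the conditioning values.

Structure selection follows Dissmann's greedy algorithm: each tree is a
maximum spanning tree on absolute Kendall tau of the current
(conditional) pseudo-data, with deterministic lexicographic tie-breaks.
Pair families are independence, gaussian, clayton, gumbel and frank,
with 90/180/270-degree rotations for the asymmetric families; each edge
is chosen by AIC after a Kendall-tau independence pre-test.

Both continuous pseudo-data (jittered margins) and discrete rectangle
pseudo-observations are supported: in discrete mode every conditional
margin carries the pair (F(x-), F(x)) and parameter estimation uses
four-point rectangle likelihoods of the pair CDF.

Sampling is by inverse Rosenblatt transform on the R-vine matrix
representation of the fitted structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .elliptical import bvn_cdf

logger = logging.getLogger(__name__)

_EPS = 1e-12
_EXP_CAP = 700.0  # cap on exponents inside clayton/gumbel power transforms

PAIR_FAMILIES = ("independence", "gaussian", "clayton", "gumbel", "frank")
THETA_BOUNDS = {
    "gaussian": (-0.999, 0.999),
    "clayton": (1e-3, 28.0),
    "gumbel": (1.0 + 1e-6, 17.0),
    "frank": (-35.0, 35.0),
}


@dataclass
class PairCopula:
    """One bivariate copula: family, rotation (degrees) and parameter."""

    family: str
    rotation: int = 0
    theta: float | None = None

    def __post_init__(self) -> None:
        if self.family not in PAIR_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.rotation not in (0, 90, 180, 270):
            raise ValueError("rotation must be one of 0, 90, 180, 270")
        if self.rotation in (90, 270) and self.family not in ("clayton", "gumbel"):
            raise ValueError("90/270 rotations only apply to clayton/gumbel")
        if self.family == "independence":
            if self.theta is not None:
                raise ValueError("independence copula has no parameter")
            return
        if self.theta is None:
            raise ValueError(f"{self.family} copula needs a parameter")
        th = float(self.theta)
        if self.family == "gaussian" and not -1 < th < 1:
            raise ValueError("gaussian theta must be in (-1, 1)")
        if self.family == "clayton" and th <= 0:
            raise ValueError("clayton theta must be > 0")
        if self.family == "gumbel" and th < 1:
            raise ValueError("gumbel theta must be >= 1")
        if self.family == "frank" and th == 0:
            raise ValueError("frank theta must be nonzero")


# ---------------------------------------------------------------------------
# base-family (rotation 0) CDF / pdf / h-function / inverse h

def _clip01(u):
    return np.clip(np.asarray(u, dtype=float), _EPS, 1.0 - _EPS)


def _pow_neg(u, theta):
    # u^(-theta) with a capped exponent to avoid overflow at extreme u
    return np.exp(np.minimum(-theta * np.log(u), _EXP_CAP))


def _cdf0(family: str, u, v, th: float):
    if family == "independence":
        return u * v
    if family == "gaussian":
        return bvn_cdf(stats.norm.ppf(u), stats.norm.ppf(v), th)
    if family == "clayton":
        t = _pow_neg(u, th) + _pow_neg(v, th) - 1.0
        return np.power(t, -1.0 / th)
    if family == "gumbel":
        x, y = (-np.log(u)) ** th, (-np.log(v)) ** th
        return np.exp(-np.power(x + y, 1.0 / th))
    if family == "frank":
        a, b, c = np.expm1(-th * u), np.expm1(-th * v), np.expm1(-th)
        return -np.log1p(a * b / c) / th
    raise AssertionError(family)


def _pdf0(family: str, u, v, th: float):
    if family == "independence":
        return np.ones_like(np.asarray(u, dtype=float))
    if family == "gaussian":
        x, y = stats.norm.ppf(u), stats.norm.ppf(v)
        s = 1.0 - th * th
        expo = -(th * th * (x * x + y * y) - 2 * th * x * y) / (2 * s)
        return np.exp(expo) / np.sqrt(s)
    if family == "clayton":
        t = _pow_neg(u, th) + _pow_neg(v, th) - 1.0
        return (1.0 + th) * _pow_neg(u * v, th + 1.0) * np.power(t, -1.0 / th - 2.0)
    if family == "gumbel":
        lu, lv = -np.log(u), -np.log(v)
        x, y = lu**th, lv**th
        A = np.power(x + y, 1.0 / th)
        return (
            np.exp(-A)
            / (u * v)
            * (lu * lv) ** (th - 1.0)
            * np.power(x + y, 1.0 / th - 2.0)
            * (A + th - 1.0)
        )
    if family == "frank":
        et = np.exp(-th)
        eu, ev = np.exp(-th * u), np.exp(-th * v)
        denom = (1.0 - et) - (1.0 - eu) * (1.0 - ev)
        return th * (1.0 - et) * eu * ev / denom**2
    raise AssertionError(family)


def _h0(family: str, u, v, th: float):
    """Conditional CDF of the first argument given the second, h(u|v)."""
    if family == "independence":
        return np.asarray(u, dtype=float)
    if family == "gaussian":
        s = np.sqrt(1.0 - th * th)
        return stats.norm.cdf((stats.norm.ppf(u) - th * stats.norm.ppf(v)) / s)
    if family == "clayton":
        t = _pow_neg(u, th) + _pow_neg(v, th) - 1.0
        return _pow_neg(v, th + 1.0) * np.power(t, -1.0 - 1.0 / th)
    if family == "gumbel":
        lu, lv = -np.log(u), -np.log(v)
        x, y = lu**th, lv**th
        A = np.power(x + y, 1.0 / th)
        return np.exp(-A) * np.power(x + y, 1.0 / th - 1.0) * lv ** (th - 1.0) / v
    if family == "frank":
        a, b, c = np.expm1(-th * u), np.expm1(-th * v), np.expm1(-th)
        return np.exp(-th * v) * a / (c + a * b)
    raise AssertionError(family)


def _hinv0(family: str, w, v, th: float):
    """Inverse of _h0 in its first argument."""
    w = _clip01(w)
    v = _clip01(v)
    if family == "independence":
        return w
    if family == "gaussian":
        s = np.sqrt(1.0 - th * th)
        return stats.norm.cdf(stats.norm.ppf(w) * s + th * stats.norm.ppf(v))
    if family == "clayton":
        inner = np.exp(
            np.minimum(
                (-th / (th + 1.0)) * (np.log(w) + (th + 1.0) * np.log(v)), _EXP_CAP
            )
        )
        t = inner - _pow_neg(v, th) + 1.0
        return np.power(np.maximum(t, 1.0), -1.0 / th)
    if family == "gumbel":
        # no closed form: monotone bisection in u
        lo = np.full(np.shape(w), _EPS)
        hi = np.full(np.shape(w), 1.0 - _EPS)
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            too_low = _h0(family, mid, v, th) < w
            lo = np.where(too_low, mid, lo)
            hi = np.where(too_low, hi, mid)
        return 0.5 * (lo + hi)
    if family == "frank":
        b, c = np.expm1(-th * v), np.expm1(-th)
        a = w * c / (np.exp(-th * v) - w * b)
        return _clip01(-np.log1p(a) / th)
    raise AssertionError(family)


def _swap(pc: PairCopula) -> PairCopula:
    """The copula of (V, U): 90 and 270 rotations trade places."""
    if pc.rotation == 90:
        return replace(pc, rotation=270)
    if pc.rotation == 270:
        return replace(pc, rotation=90)
    return pc


def pair_cdf(pc: PairCopula, u, v):
    """C(u, v) of the (possibly rotated) pair copula."""
    u, v = _clip01(u), _clip01(v)
    th = 0.0 if pc.theta is None else float(pc.theta)
    f = pc.family
    if pc.rotation == 0:
        out = _cdf0(f, u, v, th)
    elif pc.rotation == 90:
        out = v - _cdf0(f, 1.0 - u, v, th)
    elif pc.rotation == 180:
        out = u + v - 1.0 + _cdf0(f, 1.0 - u, 1.0 - v, th)
    else:
        out = u - _cdf0(f, u, 1.0 - v, th)
    return np.clip(out, 0.0, 1.0)


def pair_pdf(pc: PairCopula, u, v):
    """Copula density c(u, v)."""
    u, v = _clip01(u), _clip01(v)
    th = 0.0 if pc.theta is None else float(pc.theta)
    f = pc.family
    if pc.rotation == 0:
        return _pdf0(f, u, v, th)
    if pc.rotation == 90:
        return _pdf0(f, 1.0 - u, v, th)
    if pc.rotation == 180:
        return _pdf0(f, 1.0 - u, 1.0 - v, th)
    return _pdf0(f, u, 1.0 - v, th)


def h_function(pc: PairCopula, u, v):
    """h(u|v) = dC(u,v)/dv, the conditional CDF of U given V = v."""
    u, v = _clip01(u), _clip01(v)
    th = 0.0 if pc.theta is None else float(pc.theta)
    f = pc.family
    if pc.rotation == 0:
        out = _h0(f, u, v, th)
    elif pc.rotation == 90:
        out = 1.0 - _h0(f, 1.0 - u, v, th)
    elif pc.rotation == 180:
        out = 1.0 - _h0(f, 1.0 - u, 1.0 - v, th)
    else:
        out = _h0(f, u, 1.0 - v, th)
    return np.clip(out, _EPS, 1.0 - _EPS)


def h_inverse(pc: PairCopula, w, v):
    """Inverse of ``h_function`` in its first argument."""
    w, v = _clip01(w), _clip01(v)
    th = 0.0 if pc.theta is None else float(pc.theta)
    f = pc.family
    if pc.rotation == 0:
        out = _hinv0(f, w, v, th)
    elif pc.rotation == 90:
        out = 1.0 - _hinv0(f, 1.0 - w, v, th)
    elif pc.rotation == 180:
        out = 1.0 - _hinv0(f, 1.0 - w, 1.0 - v, th)
    else:
        out = _hinv0(f, w, 1.0 - v, th)
    return np.clip(out, _EPS, 1.0 - _EPS)


def h_function_2(pc: PairCopula, v, u):
    """Conditional CDF of the second argument given the first, dC/du."""
    return h_function(_swap(pc), v, u)


def h_inverse_2(pc: PairCopula, w, u):
    return h_inverse(_swap(pc), w, u)


# ---------------------------------------------------------------------------
# pair fitting

def _theta_from_tau(family: str, tau: float) -> float:
    t = abs(tau)
    lo, hi = THETA_BOUNDS[family]
    if family == "gaussian":
        return float(np.clip(np.sin(np.pi * tau / 2.0), lo, hi))
    if family == "clayton":
        return float(np.clip(2.0 * t / max(1.0 - t, 1e-6), lo, hi))
    if family == "gumbel":
        return float(np.clip(1.0 / max(1.0 - t, 1e-6), lo, hi))
    if family == "frank":  # crude monotone seed; ML refines it
        return float(np.clip(np.sign(tau) * max(t, 0.01) * 12.0, lo, hi))
    raise AssertionError(family)


def _neg_loglik_cont(th, family, rotation, u, v):
    pc = PairCopula(family, rotation, float(th))
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        ll = np.log(np.maximum(pair_pdf(pc, u, v), 1e-300))
    return -float(np.sum(ll))


def _neg_loglik_rect(th, family, rotation, um, up, vm, vp):
    pc = PairCopula(family, rotation, float(th))
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        p = (
            pair_cdf(pc, up, vp)
            - pair_cdf(pc, um, vp)
            - pair_cdf(pc, up, vm)
            + pair_cdf(pc, um, vm)
        )
    return -float(np.sum(np.log(np.maximum(p, 1e-300))))


def kendall_independence_pvalue(u: np.ndarray, v: np.ndarray) -> float:
    """Two-sided asymptotic Kendall-tau test of independence."""
    res = stats.kendalltau(u, v)
    p = res.pvalue
    return 1.0 if np.isnan(p) else float(p)


def fit_pair(
    u: np.ndarray,
    v: np.ndarray,
    family_set: tuple[str, ...] = PAIR_FAMILIES,
    mode: str = "continuous",
    alpha_indep: float = 0.05,
) -> PairCopula:
    """Select and fit one pair copula by AIC.

    ``u`` and ``v`` are copula-scale vectors in continuous mode, or
    (n, 2) arrays of (F(x-), F(x)) rectangle endpoints in discrete mode.
    Independence is returned outright when the Kendall-tau test of the
    (mid-)pseudo-observations is non-significant at ``alpha_indep``.
    Rotations 0/180 are tried for positive dependence and 90/270 for
    negative dependence of the asymmetric families.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("u and v must have matching shapes")
    if mode == "discrete":
        if u.ndim != 2 or u.shape[1] != 2:
            raise ValueError("discrete mode expects (n, 2) endpoint arrays")
        um, up = u[:, 0], u[:, 1]
        vm, vp = v[:, 0], v[:, 1]
        u_mid, v_mid = (um + up) / 2.0, (vm + vp) / 2.0
    elif mode == "continuous":
        if u.ndim != 1:
            raise ValueError("continuous mode expects 1-D arrays")
        u_mid, v_mid = u, v
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n = u_mid.size
    if n < 30:
        raise ValueError("need at least 30 observations to fit a pair copula")

    tau = stats.kendalltau(u_mid, v_mid).statistic
    tau = 0.0 if np.isnan(tau) else float(tau)
    if "independence" in family_set and kendall_independence_pvalue(u_mid, v_mid) > alpha_indep:
        return PairCopula("independence")

    candidates: list[tuple[str, int]] = []
    for fam in family_set:
        if fam == "independence":
            continue
        if fam in ("clayton", "gumbel"):
            rots = (0, 180) if tau >= 0 else (90, 270)
            candidates += [(fam, r) for r in rots]
        else:
            candidates.append((fam, 0))

    best: tuple[float, PairCopula] | None = None
    for fam, rot in candidates:
        lo, hi = THETA_BOUNDS[fam]
        if fam == "frank":
            # keep the optimizer away from the removable singularity at 0
            lo, hi = (0.01, hi) if tau >= 0 else (lo, -0.01)
        args = (
            (fam, rot, u_mid, v_mid)
            if mode == "continuous"
            else (fam, rot, um, up, vm, vp)
        )
        fun = _neg_loglik_cont if mode == "continuous" else _neg_loglik_rect
        try:
            res = optimize.minimize_scalar(
                fun, args=args, bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-4},
            )
            if not np.isfinite(res.fun):
                continue
            aic = 2.0 + 2.0 * res.fun
            if best is None or aic < best[0]:
                best = (aic, PairCopula(fam, rot, float(res.x)))
        except Exception as exc:  # pragma: no cover - defensive
            logger.debug("fit failed for %s rot %d: %s", fam, rot, exc)
    if best is None:
        logger.warning("all pair fits degenerate; falling back to independence")
        return PairCopula("independence")
    return best[1]


# ---------------------------------------------------------------------------
# structure selection

def _max_spanning_tree(
    n_nodes: int,
    weights: dict[tuple[int, int], float],
    allowed: set[tuple[int, int]] | None = None,
) -> list[tuple[int, int]]:
    """Kruskal maximum spanning tree with lexicographic tie-breaks."""
    pairs = sorted(
        (p for p in weights if allowed is None or p in allowed),
        key=lambda p: (-weights[p], p[0], p[1]),
    )
    parent = list(range(n_nodes))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    chosen: list[tuple[int, int]] = []
    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            chosen.append((a, b))
        if len(chosen) == n_nodes - 1:
            break
    return chosen


def select_structure(tau: np.ndarray) -> list[tuple[int, int]]:
    """First vine tree: maximum spanning tree on |Kendall tau|."""
    tau = np.asarray(tau, dtype=float)
    if tau.ndim != 2 or tau.shape[0] != tau.shape[1]:
        raise ValueError("tau must be square")
    if not np.allclose(tau, tau.T, atol=1e-10):
        raise ValueError("tau must be symmetric")
    d = tau.shape[0]
    weights = {(i, j): abs(tau[i, j]) for i in range(d) for j in range(i + 1, d)}
    return sorted(_max_spanning_tree(d, weights))


# ---------------------------------------------------------------------------
# the vine itself

@dataclass
class VineEdge:
    """One fitted pair copula with its conditioned pair and conditioning set.

    ``conditioned`` is stored sorted; the pair copula's first argument is
    the conditional margin of ``conditioned[0]``.
    """

    conditioned: tuple[int, int]
    conditioning: frozenset[int]
    pc: PairCopula


@dataclass
class VineCopula:
    d: int
    trees: list[list[VineEdge]] = field(default_factory=list)
    trunc_level: int | None = None

    def __post_init__(self) -> None:
        if self.d < 2:
            raise ValueError("vine needs d >= 2")
        if len(self.trees) != self.d - 1:
            raise ValueError(f"need {self.d - 1} trees, got {len(self.trees)}")
        for t, tree in enumerate(self.trees):
            if len(tree) != self.d - 1 - t:
                raise ValueError(f"tree {t} must have {self.d - 1 - t} edges")
            for e in tree:
                if len(e.conditioning) != t:
                    raise ValueError("conditioning-set size must equal tree level")


def make_vine(d: int, edges: list[tuple[int, int, frozenset, PairCopula]]) -> VineCopula:
    """Build a VineCopula from (a, b, conditioning, pair-copula) tuples."""
    trees: list[list[VineEdge]] = [[] for _ in range(d - 1)]
    for a, b, D, pc in edges:
        a, b = sorted((int(a), int(b)))
        trees[len(D)].append(VineEdge((a, b), frozenset(D), pc))
    for tree in trees:
        tree.sort(key=lambda e: (e.conditioned, tuple(sorted(e.conditioning))))
    return VineCopula(d=d, trees=trees)


def _cond_push(pc: PairCopula, a_pair, b_pair, which: str):
    """Endpoints of F(a | D u {b}) from the endpoint pairs of a and b.

    ``which`` selects the conditioned direction: "first" conditions the
    pair copula's first argument on its second, "second" the reverse.
    For a genuinely discrete conditioning variable the conditional CDF is
    the difference quotient of the pair CDF across the b-rectangle.
    """
    am, ap = a_pair
    bm, bp = b_pair
    h1 = h_function if which == "first" else h_function_2
    gap = bp - bm
    discrete = gap > 1e-9
    if which == "second":
        def C(x, y):
            return pair_cdf(pc, y, x)
    else:
        def C(x, y):
            return pair_cdf(pc, x, y)
    with np.errstate(divide="ignore", invalid="ignore"):
        plus_d = (C(ap, bp) - C(ap, bm)) / np.where(discrete, gap, 1.0)
        minus_d = (C(am, bp) - C(am, bm)) / np.where(discrete, gap, 1.0)
    plus = np.where(discrete, plus_d, h1(pc, ap, bp))
    minus = np.where(discrete, minus_d, h1(pc, am, bp))
    plus = np.clip(plus, _EPS, 1.0 - _EPS)
    minus = np.clip(minus, 0.0, plus)
    return minus, plus


def fit_vine(
    data,
    family_set: tuple[str, ...] = PAIR_FAMILIES,
    trunc_level: int | None = None,
    alpha_indep: float = 0.05,
) -> VineCopula:
    """Sequential Dissmann fit of a simplified regular vine.

    ``data`` is either an (n, d) matrix of continuous copula-scale values
    or a :class:`~coexcopula.margins.PseudoObs` for discrete counts. Each
    tree is a maximum spanning tree on |Kendall tau| of the current
    conditional pseudo-data (subject to proximity), each edge is fit with
    :func:`fit_pair`, and conditional margins are pushed through the
    h-functions. Trees beyond ``trunc_level`` keep their structure but
    carry independence pair copulas.
    """
    from .margins import PseudoObs

    if isinstance(data, PseudoObs):
        minus, plus = data.u_minus, data.u_plus
        mode = "discrete"
    else:
        arr = np.asarray(data, dtype=float)
        if arr.ndim != 2:
            raise ValueError("data must be 2-D")
        minus = plus = arr
        mode = "continuous"
    n, d = plus.shape
    if d < 2:
        raise ValueError("vine needs d >= 2")
    if n < 30:
        raise ValueError("need at least 30 observations")
    max_t = d - 1 if trunc_level is None else min(trunc_level, d - 1)

    # conditional margins keyed by (variable, conditioning set)
    cache: dict[tuple[int, frozenset], tuple[np.ndarray, np.ndarray]] = {
        (i, frozenset()): (minus[:, i], plus[:, i]) for i in range(d)
    }
    # nodes of the current tree: (conditioned pair or single var, conditioning)
    nodes: list[tuple[frozenset, frozenset]] = [
        (frozenset([i]), frozenset()) for i in range(d)
    ]
    trees: list[list[VineEdge]] = []
    for t in range(d - 1):
        n_nodes = len(nodes)
        # candidate edges between nodes obeying proximity
        cand: dict[tuple[int, int], tuple[int, int, frozenset]] = {}
        for i in range(n_nodes):
            for j in range(i + 1, n_nodes):
                set_i = nodes[i][0] | nodes[i][1]
                set_j = nodes[j][0] | nodes[j][1]
                if t == 0:
                    ok = True
                else:
                    ok = len(set_i & set_j) == t  # share a node of tree t-1
                if not ok:
                    continue
                sym = sorted(set_i ^ set_j)
                if len(sym) != 2:
                    continue
                cand[(i, j)] = (sym[0], sym[1], set_i & set_j)
        weights = {}
        for key, (a, b, D) in cand.items():
            ua = cache[(a, D)]
            ub = cache[(b, D)]
            tau = stats.kendalltau(
                (ua[0] + ua[1]) / 2.0, (ub[0] + ub[1]) / 2.0
            ).statistic
            weights[key] = 0.0 if np.isnan(tau) else abs(float(tau))
        mst = _max_spanning_tree(n_nodes, weights, allowed=set(cand))
        tree_edges: list[VineEdge] = []
        new_nodes: list[tuple[frozenset, frozenset]] = []
        for ni, nj in sorted(mst):
            a, b, D = cand[(ni, nj)]
            am, ap = cache[(a, D)]
            bm, bp = cache[(b, D)]
            if t < max_t:
                if mode == "discrete":
                    pc = fit_pair(
                        np.column_stack([am, ap]),
                        np.column_stack([bm, bp]),
                        family_set,
                        mode="discrete",
                        alpha_indep=alpha_indep,
                    )
                else:
                    pc = fit_pair(ap, bp, family_set, mode="continuous",
                                  alpha_indep=alpha_indep)
            else:
                pc = PairCopula("independence")
            edge = VineEdge((a, b), frozenset(D), pc)
            tree_edges.append(edge)
            D_ab = frozenset(D | {b})
            D_ba = frozenset(D | {a})
            cache[(a, D_ab)] = _cond_push(pc, (am, ap), (bm, bp), "first")
            cache[(b, D_ba)] = _cond_push(pc, (bm, bp), (am, ap), "second")
            new_nodes.append((frozenset([a, b]), frozenset(D)))
        trees.append(tree_edges)
        nodes = new_nodes
    return VineCopula(d=d, trees=trees, trunc_level=trunc_level)


def vine_loglik(vc: VineCopula, data_u: np.ndarray) -> float:
    """Copula-scale log-likelihood of continuous data under the vine."""
    u = np.asarray(data_u, dtype=float)
    if u.ndim != 2 or u.shape[1] != vc.d:
        raise ValueError(f"data must be (n, {vc.d})")
    cache: dict[tuple[int, frozenset], np.ndarray] = {
        (i, frozenset()): _clip01(u[:, i]) for i in range(vc.d)
    }
    total = 0.0
    for tree in vc.trees:
        for e in tree:
            a, b = e.conditioned
            ua = cache[(a, e.conditioning)]
            ub = cache[(b, e.conditioning)]
            if e.pc.family != "independence":
                with np.errstate(divide="ignore", over="ignore"):
                    total += float(
                        np.sum(np.log(np.maximum(pair_pdf(e.pc, ua, ub), 1e-300)))
                    )
            cache[(a, e.conditioning | {b})] = h_function(e.pc, ua, ub)
            cache[(b, e.conditioning | {a})] = h_function_2(e.pc, ub, ua)
    return total


# ---------------------------------------------------------------------------
# R-vine matrix representation and inverse-Rosenblatt sampling

def _rvine_matrix(vc: VineCopula):
    """Lower-triangular R-vine matrix plus oriented pair copulas per cell.

    Column j has the diagonal variable M[j,j]; the cell (i, j), i > j,
    carries the edge with conditioned pair {M[j,j], M[i,j]} and
    conditioning set {M[i+1,j], ..., M[d-1,j]} (tree d-1-i).
    """
    d = vc.d
    M = np.full((d, d), -1, dtype=int)
    cells: list[list[tuple[PairCopula, bool] | None]] = [
        [None] * d for _ in range(d)
    ]
    avail: list[list[VineEdge]] = [list(tree) for tree in vc.trees]
    for j in range(d - 1):
        top = d - 2 - j
        if len(avail[top]) != 1:
            raise ValueError("invalid vine structure: top tree not unique")
        e_top = avail[top][0]
        x = min(e_top.conditioned)
        M[j, j] = x
        row = j + 1
        for t in range(top, -1, -1):
            matches = [e for e in avail[t] if x in e.conditioned]
            if len(matches) != 1:
                raise ValueError("invalid vine structure: proximity violated")
            e = matches[0]
            other = e.conditioned[0] if e.conditioned[1] == x else e.conditioned[1]
            M[row, j] = other
            cells[row][j] = (e.pc, e.conditioned[0] == x)
            avail[t].remove(e)
            row += 1
    # last remaining variable
    used = set(M[j, j] for j in range(d - 1))
    M[d - 1, d - 1] = next(v for v in range(d) if v not in used)
    return M, cells


def sample_vine(vc: VineCopula, n: int, rng_seed: int) -> np.ndarray:
    """Draw n observations by inverse Rosenblatt along the R-vine matrix.

    Variables are sampled in the diagonal order of the R-vine matrix,
    rightmost column first. For the variable x of column j, the fresh
    uniform is interpreted as F(x | all previously sampled variables in
    the column) and pushed down to F(x | nothing) through the inverse
    h-functions of the column's pair copulas; the conditional CDFs of
    already-sampled variables needed along the way are cached by their
    (variable, conditioning set) meaning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    d = vc.d
    M, cells = _rvine_matrix(vc)
    rng = np.random.default_rng(rng_seed)
    w = rng.uniform(size=(n, d))
    vals: dict[tuple[int, frozenset], np.ndarray] = {}
    out = np.empty((n, d))
    for j in range(d - 1, -1, -1):
        x = int(M[j, j])
        cur = w[:, j]
        vals[(x, frozenset(int(M[r, j]) for r in range(j + 1, d)))] = cur
        for i in range(j + 1, d):
            y = int(M[i, j])
            below = frozenset(int(M[r, j]) for r in range(i + 1, d))
            z = vals[(y, below)]  # F(y | variables below row i)
            pc, first_is_diag = cells[i][j]
            if first_is_diag:  # pair copula args are (x, y)
                cur = h_inverse(pc, cur, z)
                vals[(y, below | {x})] = h_function_2(pc, z, cur)
            else:  # pair copula args are (y, x)
                cur = h_inverse_2(pc, cur, z)
                vals[(y, below | {x})] = h_function(pc, z, cur)
            vals[(x, below)] = cur
        out[:, x] = cur
    return out


# ---------------------------------------------------------------------------
# serialization

def vine_to_dict(vc: VineCopula) -> dict:
    return {
        "d": vc.d,
        "trunc_level": vc.trunc_level,
        "trees": [
            [
                {
                    "conditioned": list(e.conditioned),
                    "conditioning": sorted(e.conditioning),
                    "family": e.pc.family,
                    "rotation": e.pc.rotation,
                    "theta": e.pc.theta,
                }
                for e in tree
            ]
            for tree in vc.trees
        ],
    }


def vine_from_dict(doc: dict) -> VineCopula:
    trees = [
        [
            VineEdge(
                tuple(e["conditioned"]),
                frozenset(e["conditioning"]),
                PairCopula(e["family"], e["rotation"], e["theta"]),
            )
            for e in tree
        ]
        for tree in doc["trees"]
    ]
    return VineCopula(d=doc["d"], trees=trees, trunc_level=doc["trunc_level"])
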