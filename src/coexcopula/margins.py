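"""Empirical marginal models and the distributional transform.

Each gene's marginal distribution is modeled by its empirical step CDF.
Because counts are discrete, the latent copula-scale value of an
observation x is only known to lie in the interval (F(x-), F(x)]; the
pair of endpoints forms the pseudo-observations used by discrete copula
estimators, and the distributional transform U = F(x-) + V (F(x) - F(x-))
with V ~ Uniform(0,1) "jitters" the margin so that U is exactly uniform.

All copula-scale values are rescaled by n/(n+1) to keep them strictly
inside (0,1), so that normal and t quantile transforms stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ingest import CountMatrix


@dataclass
class MarginModel:
    """Empirical distribution function of one gene's counts.

    ``support`` holds the sorted unique observed counts and ``cdf`` the
    aligned cumulative probabilities; the last cdf value is exactly 1.
    """

    support: np.ndarray
    cdf: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=np.int64)
        self.cdf = np.asarray(self.cdf, dtype=float)
        if self.support.size == 0:
            raise ValueError("empty support")
        if np.any(np.diff(self.support) <= 0):
            raise ValueError("support must be strictly increasing")
        if np.any(np.diff(self.cdf) <= 0) or abs(self.cdf[-1] - 1.0) > 1e-12:
            raise ValueError("cdf must be strictly increasing and end at 1")
        if (self.support < 0).any():
            raise ValueError("support must be nonnegative")


@dataclass
class PseudoObs:
    """Rectangle-endpoint pseudo-observations for discrete copula fitting.

    ``u_plus[j, i]`` = rescaled F_i(x_ij) and ``u_minus[j, i]`` = rescaled
    F_i(x_ij-) for cell j and gene i; ``rescale`` is n/(n+1).
    """

    u_plus: np.ndarray
    u_minus: np.ndarray
    rescale: float

    @property
    def mid(self) -> np.ndarray:
        return 0.5 * (self.u_plus + self.u_minus)


def fit_margin(counts: np.ndarray) -> MarginModel:
    """Empirical margin: support = sorted unique counts, cdf by counting."""
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("cannot fit a margin to an empty vector")
    if counts.size < 2:
        raise ValueError("need at least 2 observations")
    support, freq = np.unique(counts, return_counts=True)
    cdf = np.cumsum(freq) / counts.size
    cdf[-1] = 1.0
    return MarginModel(support=support, cdf=cdf, n=int(counts.size))


def fit_margins(cm: CountMatrix) -> list[MarginModel]:
    """One empirical margin per gene of a count matrix."""
    return [fit_margin(row) for row in cm.counts]


def margin_cdf(mm: MarginModel, x) -> np.ndarray | float:
    """Right-continuous step CDF F(x)."""
    idx = np.searchsorted(mm.support, np.asarray(x), side="right")
    padded = np.concatenate([[0.0], mm.cdf])
    out = padded[idx]
    return out if np.ndim(x) else float(out)


def margin_cdf_minus(mm: MarginModel, x) -> np.ndarray | float:
    """Left limit F(x-): the cdf of the largest support value < x, else 0."""
    idx = np.searchsorted(mm.support, np.asarray(x), side="left")
    padded = np.concatenate([[0.0], mm.cdf])
    out = padded[idx]
    return out if np.ndim(x) else float(out)


def margin_quantile(mm: MarginModel, u) -> np.ndarray | int:
    """Generalized inverse inf{x in support : F(x) >= u}, for u in (0,1)."""
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr <= 0) or np.any(u_arr >= 1):
        raise ValueError("u must lie strictly in (0, 1)")
    idx = np.searchsorted(mm.cdf, u_arr, side="left")
    out = mm.support[idx]
    return out if np.ndim(u) else int(out)


def pseudo_observations(cm: CountMatrix, margins: list[MarginModel]) -> PseudoObs:
    """Cell x gene matrices of rescaled (F(x-), F(x)] rectangle endpoints."""
    if len(margins) != cm.n_genes:
        raise ValueError(
            f"{len(margins)} margins for {cm.n_genes} genes"
        )
    n = cm.n_cells
    rescale = n / (n + 1)
    u_plus = np.empty((n, cm.n_genes))
    u_minus = np.empty((n, cm.n_genes))
    for i, mm in enumerate(margins):
        x = cm.counts[i]
        u_plus[:, i] = rescale * margin_cdf(mm, x)
        u_minus[:, i] = rescale * margin_cdf_minus(mm, x)
    return PseudoObs(u_plus=u_plus, u_minus=u_minus, rescale=rescale)


def jitter(cm: CountMatrix, margins: list[MarginModel], rng_seed: int) -> np.ndarray:
    """Distributional transform of counts to the copula scale.

    For each observation x, draws V ~ Uniform(0,1) independently and
    returns the rescaled U = (n/(n+1)) (F(x-) + V (F(x) - F(x-))), which
    is strictly inside (0,1) and whose unrescaled version is exactly
    Uniform(0,1) when the margins are the true ones.
    """
    po = pseudo_observations(cm, margins)
    rng = np.random.default_rng(rng_seed)
    v = rng.uniform(size=po.u_plus.shape)
    u = po.u_minus + v * (po.u_plus - po.u_minus)
    # strictly inside (0,1): V=0 exactly never occurs with float uniforms,
    # but clip defensively at the smallest representable gap
    return np.clip(u, 1e-12, po.rescale * (1 - 1e-12))


def margins_to_tsv(mm: MarginModel) -> str:
    """Two-column (support, cdf) TSV serialization of one margin."""
    lines = ["support\tcdf"]
    lines += [f"{int(s)}\t{float(c)!r}" for s, c in zip(mm.support, mm.cdf)]
    return "\n".join(lines) + "\n"


def margins_from_tsv(text: str, n: int) -> MarginModel:
    rows = [ln.split("\t") for ln in text.strip().splitlines()[1:]]
    support = np.array([int(r[0]) for r in rows])
    cdf = np.array([float(r[1]) for r in rows])
    return MarginModel(support=support, cdf=cdf, n=n)
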