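"""Scoring synthetic data against reference data.

Three layers:

* gene-gene association matrices under six measures (Pearson, Spearman,
  Kendall, mutual information, biweight midcorrelation, distance
  correlation) and the Frobenius error between two such matrices;
* a fixed-reference PC embedding plus the Fasano-Franceschini
  permutation test, a multivariate Kolmogorov-Smirnov-type two-sample
  test based on quadrant occupancy around sample points;
* the benchmark harness: split cells in half, fit each copula family on
  the training half, sample replicate synthetic datasets, score each
  against the test half, then average first over replicates within a
  split and then over splits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ingest import CountMatrix
from .simulate import fit_joint, sample_joint

logger = logging.getLogger(__name__)

MEASURES = (
    "pearson",
    "spearman",
    "kendall",
    "mutual_information",
    "bicor",
    "distance_correlation",
)

_DCOR_CELL_CAP = 2000


@dataclass
class AssociationMatrix:
    measure: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("association matrix must be square")
        self.values = v


@dataclass
class EvalRecord:
    dataset_id: str
    family_tag: str
    split_index: int
    replicate_index: int
    metric_name: str
    value: float


@dataclass
class EmbeddingTestResult:
    d_stat: float
    p_value: float
    n_permutations: int


# ---------------------------------------------------------------------------
# association measures

def _zero_constant(corr: np.ndarray, constant: np.ndarray) -> np.ndarray:
    corr = np.where(np.isfinite(corr), corr, 0.0)
    if constant.any():
        corr[constant, :] = 0.0
        corr[:, constant] = 0.0
        logger.info("constant gene(s) found; correlations set to 0")
    np.fill_diagonal(corr, 1.0)
    return corr


def _bicor_matrix(x: np.ndarray) -> np.ndarray:
    """Biweight midcorrelation with tuning constant 9.

    Genes whose MAD is zero fall back to Pearson standardization for
    every pair they participate in (WGCNA's "individual" fallback).
    """
    m, n = x.shape
    transformed = np.empty_like(x, dtype=float)
    constant = np.zeros(m, dtype=bool)
    for i in range(m):
        xi = x[i].astype(float)
        med = np.median(xi)
        mad = np.median(np.abs(xi - med))
        if mad < 1e-12:
            sd = xi.std()
            if sd < 1e-12:
                constant[i] = True
                transformed[i] = 0.0
            else:
                transformed[i] = (xi - xi.mean()) / (sd * np.sqrt(n))
            continue
        u = (xi - med) / (9.0 * mad)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        num = (xi - med) * w
        transformed[i] = num / np.sqrt(np.sum(num**2))
    corr = transformed @ transformed.T
    return _zero_constant(np.clip(corr, -1, 1), constant)


def _mutual_information_matrix(x: np.ndarray) -> np.ndarray:
    """Equal-frequency binned MI (nats) with Miller-Madow bias correction."""
    m, n = x.shape
    n_bins = int(np.ceil(n ** (1.0 / 3.0)))
    binned = np.empty((m, n), dtype=np.int64)
    for i in range(m):
        ranks = stats.rankdata(x[i], method="average")
        binned[i] = np.minimum((ranks - 0.5) / n * n_bins, n_bins - 1).astype(int)
    mi = np.zeros((m, m))
    marg_entropy = np.empty(m)
    for i in range(m):
        counts = np.bincount(binned[i], minlength=n_bins)
        p = counts[counts > 0] / n
        marg_entropy[i] = -np.sum(p * np.log(p)) + (p.size - 1) / (2.0 * n)
    for i in range(m):
        mi[i, i] = marg_entropy[i]
        for j in range(i + 1, m):
            joint = np.zeros((n_bins, n_bins))
            np.add.at(joint, (binned[i], binned[j]), 1.0)
            pj = joint / n
            nz = pj > 0
            pi_ = pj.sum(axis=1)
            pjm = pj.sum(axis=0)
            outer = np.outer(pi_, pjm)
            plugin = np.sum(pj[nz] * np.log(pj[nz] / outer[nz]))
            k_joint = int(nz.sum())
            k_i = int((pi_ > 0).sum())
            k_j = int((pjm > 0).sum())
            # Miller-Madow: MI = H_i + H_j - H_ij with each entropy
            # corrected by (K-1)/(2n); the joint term dominates, so the
            # net adjustment is subtracted
            correction = (k_joint - k_i - k_j + 1) / (2.0 * n)
            mi[i, j] = mi[j, i] = max(plugin - correction, 0.0)
    return mi


def distance_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Classical distance correlation via double-centered distance matrices."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    a = np.abs(x[:, None] - x[None, :])
    b = np.abs(y[:, None] - y[None, :])
    A = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    B = b - b.mean(axis=0) - b.mean(axis=1)[:, None] + b.mean()
    dcov2 = (A * B).mean()
    dvarx = (A * A).mean()
    dvary = (B * B).mean()
    if dvarx <= 0 or dvary <= 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvarx * dvary)))


def _dcor_matrix(x: np.ndarray, rng_seed: int = 0) -> np.ndarray:
    m, n = x.shape
    if n > _DCOR_CELL_CAP:
        idx = np.sort(
            np.random.default_rng(rng_seed).choice(n, _DCOR_CELL_CAP, replace=False)
        )
        x = x[:, idx]
        logger.info("distance correlation: subsampled %d of %d cells", _DCOR_CELL_CAP, n)
    out = np.eye(m)
    constant = x.std(axis=1) < 1e-12
    for i in range(m):
        for j in range(i + 1, m):
            out[i, j] = out[j, i] = distance_correlation(x[i], x[j])
    return _zero_constant(out, constant)


def assoc_matrix(cm_or_matrix, measure: str, rng_seed: int = 0) -> AssociationMatrix:
    """Gene-gene association matrix of a count matrix under one measure."""
    if isinstance(cm_or_matrix, CountMatrix):
        x = cm_or_matrix.counts.astype(float)
    else:
        x = np.asarray(cm_or_matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D gene x cell matrix")
    m, n = x.shape
    if n < 8:
        raise ValueError("need at least 8 cells")
    constant = x.std(axis=1) < 1e-12
    if measure == "pearson":
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = _zero_constant(np.corrcoef(x), constant)
    elif measure == "spearman":
        ranks = np.vstack([stats.rankdata(r) for r in x])
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = _zero_constant(np.corrcoef(ranks), constant)
    elif measure == "kendall":
        vals = np.eye(m)
        for i in range(m):
            for j in range(i + 1, m):
                t = stats.kendalltau(x[i], x[j]).statistic
                vals[i, j] = vals[j, i] = 0.0 if np.isnan(t) else t
        vals = _zero_constant(vals, constant)
    elif measure == "mutual_information":
        vals = _mutual_information_matrix(x)
    elif measure == "bicor":
        vals = _bicor_matrix(x)
    elif measure == "distance_correlation":
        vals = _dcor_matrix(x, rng_seed=rng_seed)
    else:
        raise ValueError(f"unknown measure {measure!r}")
    return AssociationMatrix(measure=measure, values=vals)


def frobenius_error(Ms: AssociationMatrix, Mr: AssociationMatrix) -> float:
    """sqrt(sum_ij (Ms_ij - Mr_ij)^2), diagonal included."""
    if Ms.measure != Mr.measure:
        raise ValueError(f"measure mismatch: {Ms.measure} vs {Mr.measure}")
    if Ms.values.shape != Mr.values.shape:
        raise ValueError("dimension mismatch")
    return float(np.sqrt(np.sum((Ms.values - Mr.values) ** 2)))


# ---------------------------------------------------------------------------
# PC embedding + Fasano-Franceschini test

@dataclass
class PCALoadings:
    mean: np.ndarray
    components: np.ndarray  # (n_features, k)


def pca_embed(reference: np.ndarray, k: int) -> tuple[PCALoadings, np.ndarray]:
    """PCA of the reference (observations x features), loadings from it only."""
    X = np.asarray(reference, dtype=float)
    if X.ndim != 2:
        raise ValueError("reference must be 2-D")
    n, p = X.shape
    if k > min(n, p):
        raise ValueError(f"k={k} exceeds min(n, p)={min(n, p)}")
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds rank {rank}")
    load = PCALoadings(mean=mean, components=Vt[:k].T)
    return load, Xc @ load.components


def project(loadings: PCALoadings, other: np.ndarray) -> np.ndarray:
    """Project new observations with the reference centering and loadings."""
    X = np.asarray(other, dtype=float)
    return (X - loadings.mean) @ loadings.components


def _ff_statistic(labels_a: np.ndarray, quad: list[np.ndarray],
                  na: int, nb: int) -> float:
    a = labels_a.astype(float)
    b = 1.0 - a
    d_max = 0.0
    for q in quad:
        ca = a @ q  # occupancy counts per center
        cb = b @ q
        diff = np.abs(ca / na - cb / nb)
        # max over centers from each sample, averaged over the two directions
        da = diff[labels_a].max() if na else 0.0
        db = diff[~labels_a].max() if nb else 0.0
        d_max = max(d_max, 0.5 * (da + db))
    return d_max


def fasano_franceschini_test(
    A: np.ndarray,
    B: np.ndarray,
    n_permutations: int = 100,
    rng_seed: int = 0,
) -> EmbeddingTestResult:
    """Multivariate two-sample KS-type test with permutation p-value.

    The statistic is, for each sample point taken as origin, the maximum
    over the 2^k orthant quadrants of the difference in occupancy
    fractions between the two samples, maximized over origins separately
    for the two samples and averaged; significance is assessed by random
    relabeling with add-one smoothing.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    k = A.shape[1]
    if k != B.shape[1]:
        raise ValueError("samples must share dimension")
    if k not in (2, 3):
        raise NotImplementedError("supported dimensions are 2 and 3")
    na, nb = A.shape[0], B.shape[0]
    if na < 10 or nb < 10:
        raise ValueError("need at least 10 points per sample")
    pooled = np.vstack([A, B])
    N = na + nb
    # per-axis "less-or-equal to center" incidence, points x centers
    le = [pooled[:, d][:, None] <= pooled[:, d][None, :] for d in range(k)]
    gt = [~m for m in le]
    quad: list[np.ndarray] = []
    for bits in range(2**k):
        mask = np.ones((N, N), dtype=bool)
        for d in range(k):
            mask &= le[d] if (bits >> d) & 1 else gt[d]
        quad.append(mask.astype(np.float64))
    labels = np.zeros(N, dtype=bool)
    labels[:na] = True
    d_obs = _ff_statistic(labels, quad, na, nb)
    rng = np.random.default_rng(rng_seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(N)
        lab = np.zeros(N, dtype=bool)
        lab[perm[:na]] = True
        if _ff_statistic(lab, quad, na, nb) >= d_obs:
            count += 1
    p = (1.0 + count) / (1.0 + n_permutations)
    return EmbeddingTestResult(d_stat=float(d_obs), p_value=float(p),
                               n_permutations=n_permutations)


# ---------------------------------------------------------------------------
# benchmark harness

def _embedding_matrix(cm: CountMatrix) -> np.ndarray:
    # cells x genes log1p counts; library scaling is skipped so synthetic
    # cells with zero totals remain projectable
    return np.log1p(cm.counts.T.astype(float))


def run_benchmark(
    cm: CountMatrix,
    families: list[str],
    config: dict | None = None,
    dataset_id: str = "dataset",
    module_hook=None,
) -> list[EvalRecord]:
    """Split / fit / sample / score protocol over copula families.

    For every train-test split, each family is fit to the training half;
    ``n_replicates`` synthetic datasets the size of the test half are
    drawn per fit, and each is scored against the test half by Frobenius
    error per association measure and by the Fasano-Franceschini p-value
    of its projection into the test data's 2-PC space. ``module_hook``,
    if given, is called with (train, test, synthetic) count matrices and
    may return extra {metric_name: value} records.
    """
    from .ingest import make_splits

    cfg = dict(config or {})
    n_splits = int(cfg.get("n_splits", 5))
    n_replicates = int(cfg.get("n_replicates", 20))
    measures = cfg.get("measures", list(MEASURES))
    n_permutations = int(cfg.get("n_permutations", 100))
    seed = int(cfg.get("seed", 0))
    pc_k = int(cfg.get("pc_components", 2))
    fit_config = cfg.get("fit_config", {})

    plan = make_splits(cm, n_splits, seed)
    records: list[EvalRecord] = []
    for s, (train_idx, test_idx) in enumerate(plan.splits):
        train = cm.subset_cells(train_idx)
        test = cm.subset_cells(test_idx)
        ref_assoc = {mea: assoc_matrix(test, mea, rng_seed=seed) for mea in measures}
        ref_embed = _embedding_matrix(test)
        loadings, ref_scores = pca_embed(ref_embed, pc_k)
        for family in families:
            try:
                jm = fit_joint(train, family, config=fit_config,
                               rng_seed=seed * 1009 + s)
            except Exception as exc:
                logger.warning("fit of %s failed on split %d: %s", family, s, exc)
                continue
            for r in range(n_replicates):
                fam_tag = sum(ord(c) for c in family)
                rep_seed = (seed * 100003 + s * 1013 + r * 7 + fam_tag) % (2**31)
                syn = sample_joint(jm, test.n_cells, rep_seed)
                for mea in measures:
                    err = frobenius_error(
                        assoc_matrix(syn, mea, rng_seed=seed), ref_assoc[mea]
                    )
                    records.append(EvalRecord(dataset_id, family, s, r + 1,
                                              f"frobenius_{mea}", err))
                syn_scores = project(loadings, _embedding_matrix(syn))
                ff = fasano_franceschini_test(
                    syn_scores, ref_scores, n_permutations, rng_seed=rep_seed
                )
                records.append(EvalRecord(dataset_id, family, s, r + 1,
                                          "ff_pvalue", ff.p_value))
                if module_hook is not None:
                    extra = module_hook(train, test, syn) or {}
                    for name, val in extra.items():
                        records.append(EvalRecord(dataset_id, family, s, r + 1,
                                                  name, float(val)))
    return records


def records_to_frame(records: list[EvalRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def two_stage_means(records: list[EvalRecord]) -> pd.DataFrame:
    """Mean over replicates within a split, then over splits.

    One row per (dataset_id, family_tag, metric_name).
    """
    df = records_to_frame(records)
    per_split = (
        df.groupby(["dataset_id", "family_tag", "metric_name", "split_index"])["value"]
        .mean()
        .reset_index()
    )
    return (
        per_split.groupby(["dataset_id", "family_tag", "metric_name"])["value"]
        .mean()
        .reset_index()
    )


def compare_families(records: list[EvalRecord], metric: str) -> pd.DataFrame:
    """Pairwise Wilcoxon signed-rank tests on per-dataset paired means.

    Returns one row per family pair with the test statistic, raw and
    Benjamini-Hochberg adjusted p-values, and the matched-pairs
    rank-biserial effect size.
    """
    means = two_stage_means(records)
    means = means[means.metric_name == metric]
    table = means.pivot(index="dataset_id", columns="family_tag", values="value")
    families = sorted(table.columns)
    if len(families) < 2:
        raise ValueError("need at least 2 families")
    rows = []
    for i, fa in enumerate(families):
        for fb in families[i + 1:]:
            paired = table[[fa, fb]].dropna()
            if len(paired) < 6 and fa != fb:
                logger.warning("only %d paired values for (%s, %s)", len(paired), fa, fb)
            diffs = (paired[fa] - paired[fb]).to_numpy()
            nz = diffs[diffs != 0]
            if nz.size == 0:
                stat_val, p, effect = 0.0, 1.0, 0.0
            else:
                res = stats.wilcoxon(nz, method="auto")
                stat_val, p = float(res.statistic), float(res.pvalue)
                ranks = stats.rankdata(np.abs(nz))
                t_plus = ranks[nz > 0].sum()
                t_minus = ranks[nz < 0].sum()
                effect = float((t_plus - t_minus) / (t_plus + t_minus))
            rows.append({"pair": f"{fa}|{fb}", "statistic": stat_val,
                         "p_raw": p, "effect_size": effect})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p_raw"].to_numpy(), method="fdr_bh")[1]
    return out[["pair", "statistic", "p_raw", "p_adjusted", "effect_size"]]
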