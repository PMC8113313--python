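"""Two-level consensus clustering of radiomic features into tumor phenotypes.

Level 1 reduces a z-scored tumor-by-feature matrix to k derived signatures:
features are clustered with complete-linkage agglomeration under the
correlation distance d = 1 - r^2 (strongly covarying features are close,
regardless of sign), the number of clusters is chosen by consensus
clustering with the CDF delta-area rule, and each cluster is summarized by
its first principal component.  Level 2 applies the same consensus machinery
to the tumors-by-signatures matrix to define radiomic phenotypes, whose
2-vs-1 significance is assessed with a SigClust Monte-Carlo test.

Note 1 - r^2 is symmetric with zero diagonal but is not a metric (the
triangle inequality can fail); nothing here assumes metricity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

__all__ = [
    "ZScoredMatrix",
    "ConsensusResult",
    "SignatureMatrix",
    "PhenotypeAssignment",
    "zscore_features",
    "correlation_distance",
    "hierarchical_cut",
    "consensus_cluster",
    "select_k_by_cdf",
    "derive_signatures",
    "assign_phenotypes",
    "sigclust_test",
    "two_means",
]

CDF_GRID_POINTS = 100


@dataclass
class ZScoredMatrix:
    values: pd.DataFrame           # tumors x retained features, mean 0 / sd 1
    feature_means: pd.Series
    feature_sds: pd.Series
    dropped: list[str] = field(default_factory=list)


@dataclass
class ConsensusResult:
    ks: list[int]
    consensus: dict[int, np.ndarray]   # k -> items x items consensus matrix
    cdf_grid: np.ndarray
    cdfs: dict[int, np.ndarray]
    areas: dict[int, float]            # k -> A(k), area under the consensus CDF
    relative_change: dict[int, float]  # k -> (A(k+1) - A(k)) / A(k)
    selected_k: int | None = None


@dataclass
class SignatureMatrix:
    values: pd.DataFrame               # tumors x k first-PC scores
    explained_variance: pd.Series      # per signature, fraction of cluster variance
    feature_labels: pd.Series          # feature -> cluster id


@dataclass
class PhenotypeAssignment:
    labels: pd.Series                  # tumor -> phenotype in {1..m}, 1 = largest
    n_phenotypes: int
    consensus: ConsensusResult
    sigclust_p: float | None = None


def zscore_features(matrix: pd.DataFrame) -> ZScoredMatrix:
    """Standardize each feature to mean 0, sample sd 1 (ddof=1).

    Constant features carry no between-tumor information and break the
    correlation distance; they are dropped with a warning.
    """
    matrix = pd.DataFrame(matrix)
    if len(matrix) < 2:
        raise ValueError("z-scoring needs at least 2 tumors")
    means = matrix.mean(axis=0)
    sds = matrix.std(axis=0, ddof=1)
    dropped = list(matrix.columns[(sds == 0) | sds.isna()])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} constant feature(s): {dropped[:5]}...")
        logger.warning("zscore_features: dropped %d constant features", len(dropped))
    keep = [c for c in matrix.columns if c not in set(dropped)]
    z = (matrix[keep] - means[keep]) / sds[keep]
    return ZScoredMatrix(values=z, feature_means=means[keep], feature_sds=sds[keep], dropped=dropped)


def correlation_distance(z: ZScoredMatrix | pd.DataFrame) -> pd.DataFrame:
    """Feature-feature distance d = 1 - r^2 (Pearson r across tumors)."""
    values = z.values if isinstance(z, ZScoredMatrix) else pd.DataFrame(z)
    if len(values) < 2:
        raise ValueError("need at least 2 tumors")
    r = np.corrcoef(values.to_numpy(dtype=float), rowvar=False)
    r = np.atleast_2d(r)
    d = 1.0 - r**2
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(d, index=values.columns, columns=values.columns)


def _as_square(distance) -> np.ndarray:
    d = np.asarray(distance, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance must be a square matrix")
    return d


def hierarchical_cut(distance, n_clusters: int) -> np.ndarray:
    """Complete-linkage agglomerative clustering cut to ``n_clusters``.

    Returns 1-based labels; scipy's nearest-neighbor-chain linkage on the
    condensed distances is deterministic given input order.
    """
    d = _as_square(distance)
    n = d.shape[0]
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must be in [1, {n}], got {n_clusters}")
    if n == 1:
        return np.array([1])
    Z = linkage(squareform(d, checks=False), method="complete")
    return cut_tree(Z, n_clusters=n_clusters).ravel() + 1


def consensus_cluster(
    distance,
    k_range,
    n_resamples: int = 500,
    subsample_frac: float = 0.8,
    seed: int = 0,
) -> ConsensusResult:
    """Resampling-based consensus over complete-linkage clusterings.

    For each resample, a fraction of the items is drawn without replacement
    and clustered on the restricted distance; one linkage serves every k.
    M(i, j) = co-clustered count / co-sampled count (0 for never co-sampled
    pairs).  A(k) is the area under the empirical CDF of the upper-triangle
    consensus entries, evaluated on a fixed grid over [0, 1].
    """
    d = _as_square(distance)
    n = d.shape[0]
    if n < 3:
        raise ValueError("consensus clustering needs at least 3 items")
    ks = sorted(int(k) for k in k_range)
    if not ks:
        raise ValueError("empty k_range")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("k_range must be consecutive integers")
    if ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    if not 0.0 < subsample_frac <= 1.0:
        raise ValueError("subsample_frac must be in (0, 1]")

    rng = np.random.default_rng(seed)
    m = max(2, int(np.ceil(subsample_frac * n)))
    co_sampled = np.zeros((n, n))
    co_clustered = {k: np.zeros((n, n)) for k in ks}
    for _ in range(n_resamples):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        sub = d[np.ix_(idx, idx)]
        Z = linkage(squareform(sub, checks=False), method="complete")
        cuts = cut_tree(Z, n_clusters=ks)  # m x len(ks)
        co_sampled[np.ix_(idx, idx)] += 1.0
        for col, k in enumerate(ks):
            lab = cuts[:, col]
            same = lab[:, None] == lab[None, :]
            co_clustered[k][np.ix_(idx, idx)] += same

    grid = np.linspace(0.0, 1.0, CDF_GRID_POINTS)
    iu = np.triu_indices(n, k=1)
    consensus, cdfs, areas = {}, {}, {}
    with np.errstate(invalid="ignore"):
        for k in ks:
            M = np.where(co_sampled > 0, co_clustered[k] / np.where(co_sampled > 0, co_sampled, 1), 0.0)
            np.fill_diagonal(M, 1.0)
            consensus[k] = M
            vals = M[iu]
            cdf = np.searchsorted(np.sort(vals), grid, side="right") / vals.size
            cdfs[k] = cdf
            areas[k] = float(np.sum(np.diff(grid) * cdf[1:]))
    rel = {
        k: (areas[k + 1] - areas[k]) / areas[k] if areas[k] > 0 else np.inf
        for k in ks[:-1]
    }
    return ConsensusResult(ks=ks, consensus=consensus, cdf_grid=grid, cdfs=cdfs, areas=areas, relative_change=rel)


def select_k_by_cdf(result: ConsensusResult, cutoff: float = 0.10) -> int:
    """Smallest k whose relative delta-area (A(k+1) - A(k)) / A(k) < cutoff.

    Falls back to the largest k in range (with a warning) when the area keeps
    growing by at least the cutoff everywhere.
    """
    if not result.ks:
        raise ValueError("empty consensus result")
    for k in result.ks[:-1]:
        if result.relative_change[k] < cutoff:
            result.selected_k = k
            return k
    warnings.warn(
        f"consensus CDF area never stabilized below the {cutoff:.0%} cutoff; "
        f"falling back to k = {result.ks[-1]}"
    )
    result.selected_k = result.ks[-1]
    return result.ks[-1]


def derive_signatures(z: ZScoredMatrix | pd.DataFrame, feature_labels) -> SignatureMatrix:
    """First-PC score of each feature cluster, one signature column per cluster.

    PCA is on the tumors x cluster-features submatrix of z-scored values (so
    the sample covariance is the correlation structure).  Each PC is
    sign-aligned to correlate non-negatively with the cluster's mean feature.
    """
    values = z.values if isinstance(z, ZScoredMatrix) else pd.DataFrame(z)
    labels = pd.Series(feature_labels)
    if not set(values.columns) <= set(labels.index):
        labels = pd.Series(np.asarray(feature_labels), index=values.columns)
    missing = set(values.columns) - set(labels.index)
    if missing:
        raise ValueError(f"feature labels missing for {len(missing)} features")
    cluster_ids = sorted(pd.unique(labels[values.columns]))
    scores, evr = {}, {}
    for cid in cluster_ids:
        cols = [c for c in values.columns if labels[c] == cid]
        if not cols:
            raise ValueError(f"cluster {cid} has no features")
        X = values[cols].to_numpy(dtype=float)
        Xc = X - X.mean(axis=0)
        _, s, vt = np.linalg.svd(Xc, full_matrices=False)
        pc = Xc @ vt[0]
        mean_feature = Xc.mean(axis=1)
        if pc @ mean_feature < 0:
            pc = -pc
        scores[f"signature_{cid:02d}"] = pc
        total = float((s**2).sum())
        evr[f"signature_{cid:02d}"] = float(s[0] ** 2 / total) if total > 0 else 1.0
    sig = pd.DataFrame(scores, index=values.index)
    return SignatureMatrix(
        values=sig,
        explained_variance=pd.Series(evr),
        feature_labels=labels[values.columns],
    )


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """1 = largest cluster; ties broken by the lowest member index."""
    ids = pd.unique(labels)
    sizes = {i: int((labels == i).sum()) for i in ids}
    first = {i: int(np.flatnonzero(labels == i)[0]) for i in ids}
    order = sorted(ids, key=lambda i: (-sizes[i], first[i]))
    remap = {old: new + 1 for new, old in enumerate(order)}
    return np.array([remap[v] for v in labels])


def assign_phenotypes(
    signatures: SignatureMatrix | pd.DataFrame,
    k_range=(2, 3, 4, 5),
    n_resamples: int = 500,
    subsample_frac: float = 0.8,
    seed: int = 0,
    tumor_distance: str = "euclidean",
    cdf_cutoff: float = 0.10,
) -> PhenotypeAssignment:
    """Cluster tumors on their signature rows into radiomic phenotypes.

    Tumor distance defaults to Euclidean on the signature rows; ``corr``
    uses 1 - r^2 across signature vectors instead.  The phenotype count is
    chosen by the same consensus CDF rule as the feature level, and the final
    labels come from a complete-linkage cut of 1 - consensus at that k.
    """
    sig = signatures.values if isinstance(signatures, SignatureMatrix) else pd.DataFrame(signatures)
    n = len(sig)
    if n < 4:
        raise ValueError("phenotype clustering needs at least 4 tumors")
    X = sig.to_numpy(dtype=float)
    if tumor_distance == "euclidean":
        d = squareform(pdist(X, metric="euclidean"))
    elif tumor_distance == "corr":
        d = correlation_distance(pd.DataFrame(X.T)).to_numpy()
    else:
        raise ValueError(f"unknown tumor_distance {tumor_distance!r}")
    res = consensus_cluster(d, k_range, n_resamples=n_resamples, subsample_frac=subsample_frac, seed=seed)
    m = select_k_by_cdf(res, cutoff=cdf_cutoff)
    labels = hierarchical_cut(1.0 - res.consensus[m], m)
    labels = _relabel_by_size(labels)
    return PhenotypeAssignment(
        labels=pd.Series(labels, index=sig.index, name="phenotype"),
        n_phenotypes=m,
        consensus=res,
    )


def two_means(X: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Deterministic 2-means: PC1-split initialization + Lloyd iterations."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    proj = Xc @ vt[0]
    labels = (proj > np.median(proj)).astype(int)
    if labels.sum() in (0, len(labels)):
        labels[np.argmax(proj)] = 1 - labels[0]
    for _ in range(max_iter):
        c0 = X[labels == 0].mean(axis=0)
        c1 = X[labels == 1].mean(axis=0)
        d0 = ((X - c0) ** 2).sum(axis=1)
        d1 = ((X - c1) ** 2).sum(axis=1)
        new = (d1 < d0).astype(int)
        if new.sum() in (0, len(new)):
            break
        if np.array_equal(new, labels):
            break
        labels = new
    return labels


def _cluster_index(X: np.ndarray, labels: np.ndarray) -> float:
    """Within-cluster SS / total SS for a 2-way split (lower = tighter)."""
    total = float(((X - X.mean(axis=0)) ** 2).sum())
    if total == 0:
        return 1.0
    wss = 0.0
    for g in np.unique(labels):
        sub = X[labels == g]
        wss += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return wss / total


def sigclust_test(data, labels, n_sim: int = 1000, seed: int = 0) -> float:
    """SigClust: is a 2-way split significant versus one Gaussian cluster?

    The statistic is the cluster index CI = within-cluster SS / total SS of
    the observed split.  The null is a single zero-mean Gaussian whose
    diagonal covariance takes the sample-covariance eigenvalues floored at a
    background noise variance (the squared MAD-based sd of all matrix
    entries); each simulated dataset is split by 2-means and
    p = (1 + #{CI_null <= CI_obs}) / (1 + n_sim).
    """
    X = np.asarray(data, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError("SigClust requires exactly 2 clusters")
    if min((labels == u).sum() for u in uniq) < 2:
        raise ValueError("each cluster needs at least 2 members")
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    n, p = X.shape
    ci_obs = _cluster_index(X, labels)

    flat = X.ravel()
    mad = np.median(np.abs(flat - np.median(flat)))
    sigma_bg2 = (mad / 0.674489750196082) ** 2
    cov = np.cov(X, rowvar=False)
    cov = np.atleast_2d(cov)
    eigvals = np.clip(np.linalg.eigvalsh(cov), 0.0, None)
    eigvals = np.maximum(eigvals, sigma_bg2)

    rng = np.random.default_rng(seed)
    hits = 0
    sd = np.sqrt(eigvals)
    for _ in range(n_sim):
        sim = rng.standard_normal((n, p)) * sd
        sim_labels = two_means(sim)
        if _cluster_index(sim, sim_labels) <= ci_obs:
            hits += 1
    return (hits + 1) / (n_sim + 1)
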