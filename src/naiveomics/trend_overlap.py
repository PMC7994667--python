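"""Treatment-overlap statistics and temporal module discovery.

Two questions recur throughout the analysis: (1) do two treatments regulate
significantly overlapping feature sets, and (2) how many distinct temporal
modules do the regulated trajectories form?  The first is answered with an
upper-tail hypergeometric test plus the representation factor
rf = k·N/(K·n) (observed overlap over the independence expectation).  The
second uses the gap statistic to pick the cluster number and seeded k-means
to assign features, followed by per-cluster centroid correlations between
the two treatments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln, logsumexp
from sklearn.cluster import KMeans

from .differential import CorrelationResult, pearson_cor_test
from .preprocess import TrajectoryMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Hypergeometric overlap
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OverlapStat:
    """2x2 overlap summary: counts, representation factor, upper-tail p.

    k = overlap, K = size of set 1, n = size of set 2, N = universe.
    p = P(X >= k) for X ~ Hypergeometric(N, K, n), computed in log space so
    extreme enrichments (p < 1e-300) keep a finite log10_p.
    """

    k: int
    K: int
    n: int
    N: int
    rf: float
    p: float
    log10_p: float


def _log_hypergeom_pmf(k: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    """log P(X = k) via log-beta functions (numerically stable)."""
    k = np.asarray(k, dtype=float)
    # log C(a, b) = -log(a+1) - betaln(a-b+1, b+1)
    def logcomb(a: float, b: np.ndarray) -> np.ndarray:
        b = np.asarray(b, dtype=float)
        return -np.log(a + 1.0) - betaln(a - b + 1.0, b + 1.0)

    return logcomb(K, k) + logcomb(N - K, n - k) - logcomb(N, np.asarray([n], dtype=float))


def hypergeom_pmf(k: int, K: int, n: int, N: int) -> float:
    """Point probability P(X = k) for X ~ Hypergeometric(N, K, n)."""
    _validate_overlap(k, K, n, N)
    return float(np.exp(_log_hypergeom_pmf(np.array([k]), N, K, n)[0]))


def _validate_overlap(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"overlap k={k} must lie in [0, min(K, n)={min(K, n)}]")
    if K > N or n > N:
        raise ValueError("set sizes K and n cannot exceed the universe N")
    if min(K, n, N) < 0:
        raise ValueError("counts must be non-negative")
    if k < K + n - N:
        raise ValueError(f"k={k} below the forced minimum overlap K+n-N={K + n - N}")


def hypergeom_overlap(k: int, K: int, n: int, N: int) -> OverlapStat:
    """Upper-tail hypergeometric overlap test with representation factor.

    The one-sided (enrichment) p-value P(X >= k) is accumulated in log space
    over the support [k, min(K, n)].
    """
    _validate_overlap(k, K, n, N)
    if k <= max(0, K + n - N):
        logp = 0.0                      # whole support: P(X >= k) = 1 exactly
    else:
        support = np.arange(k, min(K, n) + 1)
        logp = min(float(logsumexp(_log_hypergeom_pmf(support, N, K, n))), 0.0)
    rf = k * N / (K * n) if K and n else float("nan")
    return OverlapStat(k=k, K=K, n=n, N=N, rf=rf,
                       p=float(np.exp(logp)), log10_p=logp / np.log(10.0))


def overlap_from_sets(set1: set, set2: set, universe: set) -> OverlapStat:
    """Overlap statistic from explicit feature-id sets within a universe."""
    s1, s2 = set(set1) & set(universe), set(set2) & set(universe)
    return hypergeom_overlap(len(s1 & s2), len(s1), len(s2), len(universe))


# ---------------------------------------------------------------------------
# Trend correlation
# ---------------------------------------------------------------------------


def trend_correlation(tm: TrajectoryMatrix, r_min: float = 0.6,
                      treatments: tuple[str, str] = ("2i", "Cdk8i")
                      ) -> tuple[pd.DataFrame, list[str]]:
    """Per-feature Pearson correlation between the two treatment trajectories.

    Returns (table with r/n/p per feature, list of feature ids with
    r > r_min).  Features with a constant trajectory in either treatment are
    skipped with reason 'constant'.
    """
    a = tm.treatment_block(treatments[0])
    b = tm.treatment_block(treatments[1])
    if a.shape[1] != b.shape[1]:
        raise ValueError("treatments must share an equal timepoint grid")
    rows = []
    for fid in a.index:
        x, y = a.loc[fid].to_numpy(), b.loc[fid].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((fid, np.nan, len(x), np.nan, "constant"))
            continue
        res = pearson_cor_test(x, y)
        rows.append((fid, res.r, res.n, res.p, ""))
    table = pd.DataFrame(rows, columns=["feature", "r", "n", "p", "skipped"]).set_index("feature")
    kept = table.index[table["r"] > r_min].tolist()
    return table, kept


# ---------------------------------------------------------------------------
# Gap statistic + k-means
# ---------------------------------------------------------------------------


@dataclass
class GapProfile:
    """Gap-statistic scan: per k the dispersion W_k, Gap(k) and its sd term.

    chosen_K is the smallest k with Gap(k) >= Gap(k+1) - s_{k+1}; if no k
    satisfies the rule the scan maximum is returned.
    """

    table: pd.DataFrame  # columns: k, W, log_W, gap, s
    B: int
    chosen_K: int


def _within_dispersion(x: np.ndarray, k: int, seed: int, n_init: int) -> float:
    """W_k = sum over clusters of (1/(2 n_r)) * sum of pairwise squared
    distances, which equals the k-means inertia at the fitted centroids."""
    if k == 1:
        centroid = x.mean(axis=0)
        return float(((x - centroid) ** 2).sum())
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(x)
    return float(km.inertia_)


def gap_statistic(x: np.ndarray | pd.DataFrame, k_max: int = 20, B: int = 50,
                  seed: int = 0, n_init: int = 5) -> GapProfile:
    """Pick the cluster number by comparing log W_k against uniform references.

    References are drawn uniformly over each dimension's observed range.
    Gap(k) = mean_b log W*_kb - log W_k and s_k = sd_b(log W*_kb)·sqrt(1+1/B).
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2:
        raise ValueError("trajectory rows must form a 2-d array")
    n_rows = arr.shape[0]
    if k_max >= n_rows:
        raise ValueError(f"k_max={k_max} must be below the number of rows {n_rows}")
    if n_rows < 5 * k_max:
        logger.warning("fewer than 5 rows per candidate cluster; gap scan may be noisy")
    rng = np.random.default_rng(seed)
    lo, hi = arr.min(axis=0), arr.max(axis=0)
    ks = np.arange(1, k_max + 1)
    log_w = np.array([np.log(_within_dispersion(arr, k, seed, n_init)) for k in ks])
    log_w_ref = np.empty((B, k_max))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=arr.shape)
        ref_seed = int(rng.integers(2**31 - 1))
        for i, k in enumerate(ks):
            log_w_ref[b, i] = np.log(_within_dispersion(ref, k, ref_seed, n_init))
    gap = log_w_ref.mean(axis=0) - log_w
    s = log_w_ref.std(axis=0, ddof=1) * np.sqrt(1.0 + 1.0 / B)
    chosen = int(ks[-1])
    for i in range(k_max - 1):
        if gap[i] >= gap[i + 1] - s[i + 1]:
            chosen = int(ks[i])
            break
    table = pd.DataFrame({"k": ks, "W": np.exp(log_w), "log_W": log_w,
                          "gap": gap, "s": s})
    return GapProfile(table=table, B=B, chosen_K=chosen)


@dataclass
class TrendClusterModel:
    """K-means clustering of z-scored trajectories.

    assignments maps feature id -> cluster id (0-based); centroids holds one
    mean trajectory per cluster with (treatment, timepoint) columns;
    centroid_correlations gives the per-cluster Pearson r between the two
    treatment centroids (NaN where a centroid is constant).
    """

    assignments: pd.Series
    centroids: pd.DataFrame
    inertia: float
    gap: GapProfile | None = None
    centroid_correlations: pd.DataFrame | None = None
    treatments: tuple[str, str] = ("2i", "Cdk8i")


def kmeans_trajectories(tm: TrajectoryMatrix, K: int, seed: int = 0,
                        restarts: int = 25, gap: GapProfile | None = None
                        ) -> TrendClusterModel:
    """Cluster concatenated treatment trajectories with seeded k-means.

    Lloyd iterations, best of ``restarts`` initialisations by within-cluster
    dispersion; deterministic given the seed.
    """
    x = tm.data
    if K > len(x):
        raise ValueError("K cannot exceed the number of trajectory rows")
    km = KMeans(n_clusters=K, n_init=restarts, random_state=seed).fit(x.to_numpy())
    assignments = pd.Series(km.labels_, index=x.index, name="cluster")
    centroids = x.groupby(assignments).mean()
    centroids.index.name = "cluster"
    model = TrendClusterModel(assignments=assignments, centroids=centroids,
                              inertia=float(km.inertia_), gap=gap,
                              treatments=tuple(tm.treatments[:2]))
    model.centroid_correlations = centroid_correlation(model)
    return model


def centroid_correlation(model: TrendClusterModel) -> pd.DataFrame:
    """Pearson correlation between the two treatment centroids per cluster.

    Degenerate (constant) centroids are reported with NaN r and flagged.
    """
    t1, t2 = model.treatments
    rows = []
    for cluster, row in model.centroids.iterrows():
        a = row[t1].to_numpy(dtype=float)
        b = row[t2].to_numpy(dtype=float)
        if len(a) < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
            rows.append((cluster, np.nan, len(a), np.nan, True))
            continue
        res: CorrelationResult = pearson_cor_test(a, b)
        rows.append((cluster, res.r, res.n, res.p, False))
    return pd.DataFrame(rows, columns=["cluster", "r", "n", "p", "degenerate"]
                        ).set_index("cluster")
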