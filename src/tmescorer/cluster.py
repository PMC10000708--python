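"""Monti-style consensus clustering with CDF/delta-area model selection.

Items (samples or genes) are repeatedly subsampled, clustered with a base
clusterer, and the consensus matrix entry (i, j) records the fraction of
co-samplings in which i and j landed in the same cluster. Final labels come
from average-linkage hierarchical clustering of ``1 - consensus``. The
number of clusters is chosen from consensus stability: by default the PAC
criterion (proportion of ambiguous consensus values), with the classic
CDF/delta-area convention available as an alternative and always reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

BASE_CLUSTERERS = ("hclust_complete_manhattan", "hclust_wardD2_euclidean", "kmeans_euclidean")


def hclust(
    data: np.ndarray,
    k: int,
    metric: str = "euclidean",
    method: str = "complete",
) -> np.ndarray:
    """Agglomerative clustering labels (1..k) via Lance–Williams updates."""
    if k > data.shape[0]:
        raise ValueError(f"k={k} exceeds number of items {data.shape[0]}")
    if method == "wardD2":
        method = "ward"
    d = pdist(np.asarray(data, dtype=float), metric=metric)
    z = linkage(d, method=method)
    return fcluster(z, t=k, criterion="maxclust")


def kmeans(data: np.ndarray, k: int, n_init: int = 10, seed: int = 0) -> np.ndarray:
    """k-means labels (1..k), k-means++ seeding, best of ``n_init`` inits."""
    if k > data.shape[0]:
        raise ValueError(f"k={k} exceeds number of items {data.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=int(seed) % (2**32 - 1))
    return km.fit_predict(np.asarray(data, dtype=float)) + 1


def _base_fn(base: str) -> Callable[[np.ndarray, int, int], np.ndarray]:
    if base == "hclust_complete_manhattan":
        return lambda x, k, s: hclust(x, k, metric="cityblock", method="complete")
    if base == "hclust_wardD2_euclidean":
        return lambda x, k, s: hclust(x, k, metric="euclidean", method="ward")
    if base == "kmeans_euclidean":
        return lambda x, k, s: kmeans(x, k, n_init=5, seed=s)
    raise ValueError(f"unknown base clusterer {base!r}; expected one of {BASE_CLUSTERERS}")


def _cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of off-diagonal consensus values."""
    iu = np.triu_indices_from(consensus, k=1)
    vals = np.sort(consensus[iu])
    if vals.size == 0:
        return 0.0
    cdf = np.arange(1, vals.size + 1) / vals.size
    return float(np.sum(np.diff(vals) * cdf[:-1]))


@dataclass
class ConsensusResult:
    """Consensus matrix, derived labels and CDF-area summary for one k."""

    k: int
    consensus: np.ndarray
    labels: np.ndarray
    cdf_area: float
    co_sample_counts: np.ndarray
    item_ids: list | None = None

    def labels_series(self) -> pd.Series:
        index = self.item_ids if self.item_ids is not None else range(len(self.labels))
        return pd.Series(self.labels, index=index, name=f"consensus_k{self.k}")


def consensus_cluster(
    data: np.ndarray | pd.DataFrame,
    k: int,
    reps: int = 1000,
    p_item: float = 0.8,
    p_feature: float = 1.0,
    base: str = "hclust_complete_manhattan",
    seed: int = 0,
) -> ConsensusResult:
    """Resampled consensus clustering of ``data`` (items x features) at ``k``.

    Each rep draws ``ceil(p_item * n)`` items (and ``ceil(p_feature * d)``
    features) without replacement, clusters them with the base clusterer and
    accumulates co-cluster / co-sampling counts. Deterministic given ``seed``.
    """
    item_ids = list(data.index) if isinstance(data, pd.DataFrame) else None
    x = np.asarray(data, dtype=float)
    n, d = x.shape
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not 0 < p_item <= 1:
        raise ValueError("p_item must be in (0, 1]")
    fn = _base_fn(base)
    n_sub = math.ceil(p_item * n)
    d_sub = math.ceil(p_feature * d)
    rng = np.random.default_rng(seed)

    co_cluster = np.zeros((n, n))
    co_sample = np.zeros((n, n))
    for _ in range(reps):
        items = rng.choice(n, size=n_sub, replace=False) if n_sub < n else np.arange(n)
        feats = rng.choice(d, size=d_sub, replace=False) if d_sub < d else np.arange(d)
        sub = x[np.ix_(items, feats)]
        labels = fn(sub, min(k, n_sub), int(rng.integers(2**31)))
        co_sample[np.ix_(items, items)] += 1
        for c in np.unique(labels):
            idx = items[labels == c]
            co_cluster[np.ix_(idx, idx)] += 1

    never = (co_sample == 0) & ~np.eye(n, dtype=bool)
    if never.any():
        logger.warning(
            "%d item pair(s) were never co-sampled; their consensus is set to 0",
            int(never.sum()) // 2,
        )
    with np.errstate(invalid="ignore"):
        consensus = np.where(co_sample > 0, co_cluster / np.maximum(co_sample, 1), 0.0)
    consensus = (consensus + consensus.T) / 2.0

    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(z, t=k, criterion="maxclust")
    return ConsensusResult(
        k=k,
        consensus=consensus,
        labels=labels,
        cdf_area=_cdf_area(consensus),
        co_sample_counts=co_sample,
        item_ids=item_ids,
    )


def consensus_sweep(
    data: np.ndarray | pd.DataFrame,
    k_range: Sequence[int],
    seed: int = 0,
    **kwargs,
) -> list[ConsensusResult]:
    """Run :func:`consensus_cluster` for each k with independent child seeds."""
    seeds = np.random.SeedSequence(seed).spawn(len(list(k_range)))
    return [
        consensus_cluster(data, k, seed=int(s.generate_state(1)[0] % (2**31)), **kwargs)
        for k, s in zip(k_range, seeds)
    ]


def delta_areas(results: Sequence[ConsensusResult]) -> pd.Series:
    """Relative delta area per k: A(2) for k=2, else (A(k)-A(k-1))/A(k-1)."""
    results = sorted(results, key=lambda r: r.k)
    ks = [r.k for r in results]
    if len(ks) < 2:
        raise ValueError("need consensus results for at least two values of k")
    if ks[0] != 2 or ks != list(range(2, 2 + len(ks))):
        raise ValueError(f"k_range must be contiguous starting at 2, got {ks}")
    areas = np.array([r.cdf_area for r in results])
    deltas = [areas[0]]
    for i in range(1, len(areas)):
        prev = areas[i - 1]
        deltas.append((areas[i] - prev) / prev if prev > 0 else 0.0)
    return pd.Series(deltas, index=pd.Index(ks, name="k"), name="delta_area")


def pac_score(result: ConsensusResult, lower: float = 0.1, upper: float = 0.9) -> float:
    """Proportion of ambiguous clustering: off-diagonal consensus in (lower, upper).

    0 means every pair is either always or never co-clustered (a perfectly
    stable partition); values near 1 mean no reproducible structure.
    """
    iu = np.triu_indices_from(result.consensus, k=1)
    vals = result.consensus[iu]
    return float(((vals > lower) & (vals < upper)).mean()) if vals.size else 0.0


def select_k(
    results: Sequence[ConsensusResult],
    threshold: float = 0.1,
    method: str = "pac",
) -> int:
    """Choose the number of clusters from a consensus sweep (k contiguous from 2).

    ``method="pac"`` (default): the largest k whose proportion of ambiguous
    consensus values (:func:`pac_score`) is at most ``threshold``; if no k is
    that stable (e.g. structureless data, PAC near 1 everywhere) return 2.
    The CDF delta-area criterion tends to keep growing past the true k on
    noisy data, which is why PAC is the default; ``method="delta_area"``
    (largest k with relative delta area above ``threshold``, elbow fallback)
    is retained for comparison with the classic convention.
    """
    results = sorted(results, key=lambda r: r.k)
    if method == "pac":
        delta_areas(results)  # validates the contiguous-from-2 precondition
        stable = [r.k for r in results if pac_score(r) <= threshold]
        return max(stable) if stable else 2
    if method == "delta_area":
        deltas = delta_areas(results)
        above = [int(k) for k, v in deltas.items() if v > threshold]
        if above:
            return max(above)
        tail = deltas[deltas.index > 2]
        if len(tail) == 0 or (tail <= 0).all():
            return 2
        return int(tail.idxmax())
    raise ValueError(f"unknown select_k method {method!r}")
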