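"""Recurrent connectivity-state estimation.

Windowed FC vectors pooled over all participants are clustered by L1
(city-block) k-means — the distance recommended for high-dimensional FC
data — with per-coordinate *median* centroid updates, the true L1
minimizer.  The number of states is chosen where the elbow criterion and
Dunn's index converge; states are then re-coded in order of descending
total occupancy across the cohort, and each participant's per-state FC is
summarized by the coordinate-wise median over the windows spent in that
state.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .connectivity import WindowedFCSeries

log = logging.getLogger(__name__)


@dataclass
class StateModel:
    """Fitted k-means state model over pooled windows."""

    k: int
    centroids: np.ndarray                 # k x n_pairs
    labels: dict = field(repr=False)      # participant_id -> window labels (1..k)
    cost: float = np.nan                  # total within-cluster L1 cost
    occupancy: np.ndarray | None = None   # per-state window counts, post-relabel
    relabel_map: dict | None = None       # original cluster id -> final state id
    n_iter: int = 0

    def pooled_labels(self) -> np.ndarray:
        return np.concatenate([self.labels[p] for p in self.labels])


def _l1_cost(X: np.ndarray, centroids: np.ndarray, labels: np.ndarray) -> float:
    return float(
        np.abs(X - centroids[labels]).sum()
    )


def _plusplus_init(X: np.ndarray, k: int, rng) -> np.ndarray:
    """k-means++-style seeding with city-block distances."""
    n = X.shape[0]
    centroids = np.empty((k, X.shape[1]))
    centroids[0] = X[rng.integers(n)]
    d = cdist(X, centroids[:1], metric="cityblock")[:, 0]
    for c in range(1, k):
        probs = d / d.sum() if d.sum() > 0 else np.full(n, 1.0 / n)
        centroids[c] = X[rng.choice(n, p=probs)]
        d = np.minimum(d, cdist(X, centroids[c:c + 1], metric="cityblock")[:, 0])
    return centroids


def kmeans_cityblock(
    X: np.ndarray,
    k: int,
    n_init: int = 20,
    max_iter: int = 300,
    seed: int = 0,
    init: str = "++",
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """L1 (city-block) k-means with median centroid updates.

    Lloyd-style alternation: assign each row to the nearest centroid in L1
    distance, then move each centroid to the coordinate-wise median of its
    rows.  Best of ``n_init`` restarts (k-means++-style distance-weighted
    seeding by default, ``init="random"`` for plain row sampling) by total
    within-cluster L1 cost; deterministic under ``seed``.  An emptied
    cluster is re-seeded at the point farthest from its current centroid.

    Returns ``(labels, centroids, cost, n_iter)`` with labels in 0..k-1.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError(f"need at least k={k} rows, got {n}")
    rng = np.random.default_rng(seed)
    best: tuple | None = None
    for _ in range(n_init):
        if init == "++":
            centroids = _plusplus_init(X, k, rng)
        else:
            centroids = X[rng.choice(n, size=k, replace=False)].copy()
        labels = np.full(n, -1)
        it = 0
        for it in range(1, max_iter + 1):
            D = cdist(X, centroids, metric="cityblock")
            new_labels = D.argmin(axis=1)
            for c in range(k):
                if not np.any(new_labels == c):
                    own = D[np.arange(n), new_labels]
                    far = int(own.argmax())
                    centroids[c] = X[far]
                    new_labels[far] = c
                    log.debug("re-seeded empty cluster %d at row %d", c, far)
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for c in range(k):
                centroids[c] = np.median(X[labels == c], axis=0)
        cost = _l1_cost(X, centroids, labels)
        if best is None or cost < best[2]:
            best = (labels, centroids, cost, it)
    return best


def dunns_index(
    X: np.ndarray,
    labels: np.ndarray,
    max_points: int | None = None,
    seed: int = 0,
) -> float:
    """Dunn's cluster-validity index under city-block distance.

    Minimum inter-cluster distance (closest pair of points in different
    clusters) divided by the maximum intra-cluster diameter (farthest pair
    within one cluster).  When every diameter is zero (all clusters are
    coincident points) the index is +inf.  ``max_points`` optionally
    subsamples rows (seeded) to bound the O(n^2) distance computation.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("Dunn's index needs >= 2 clusters")
    if max_points is not None and X.shape[0] > max_points:
        rng = np.random.default_rng(seed)
        # stratified subsample so no cluster disappears
        keep: list[np.ndarray] = []
        for c in uniq:
            idx = np.flatnonzero(labels == c)
            m = max(2, int(round(max_points * idx.size / X.shape[0])))
            keep.append(rng.choice(idx, size=min(m, idx.size), replace=False))
        sel = np.concatenate(keep)
        X, labels = X[sel], labels[sel]
    D = cdist(X, X, metric="cityblock")
    same = labels[:, None] == labels[None, :]
    diam = 0.0
    for c in np.unique(labels):
        mask = labels == c
        if mask.sum() > 1:
            diam = max(diam, D[np.ix_(mask, mask)].max())
    inter = D[~same]
    min_inter = float(inter.min()) if inter.size else np.inf
    if diam == 0.0:
        return np.inf
    return min_inter / diam


def select_k(
    X: np.ndarray,
    k_range=range(2, 11),
    seed: int = 0,
    n_init: int = 5,
    max_iter: int = 100,
    dunn_max_points: int | None = 2000,
) -> tuple[int, pd.DataFrame]:
    """Choose the number of states by elbow + Dunn's-index convergence.

    The elbow candidate maximizes the cost drop ratio
    ``(f(k-1) - f(k)) / (f(k) - f(k+1))`` of the within-cluster L1 cost
    normalized by the k = 1 cost: at the generative k the numerator is the
    last structural drop while the denominator is pure noise splitting, so
    the ratio peaks there even when cluster sizes are unequal (where the
    raw second difference is biased toward small k).  The Dunn candidate
    maximizes Dunn's index.  When the two agree that k is returned;
    otherwise the elbow k is returned and the diagnostics table carries
    ``converged = False``.

    Returns ``(k, diagnostics)``; diagnostics has one row per k with
    columns ``k, cost, norm_cost, drop, drop_ratio, dunn`` plus attrs
    ``elbow_k, dunn_k, converged``.
    """
    ks = list(k_range)
    if len(ks) < 3:
        raise ValueError("k_range must contain at least 3 values for the elbow")
    # anchor the cost curve one k below the scan so the smallest candidate
    # has a defined second difference (k=1 is always feasible)
    ks_cost = ([ks[0] - 1] if ks[0] >= 2 else []) + ks
    costs, dunns = [], []
    for i, k in enumerate(ks_cost):
        labels, centroids, cost, _ = kmeans_cityblock(
            X, k, n_init=n_init, max_iter=max_iter, seed=seed + i)
        costs.append(cost)
        if k in ks:
            dunns.append(dunns_index(X, labels, max_points=dunn_max_points,
                                     seed=seed + i))
    costs = np.asarray(costs)
    f = costs / costs[0]
    # drop into each k and ratio of consecutive drops
    drop_all = np.full(len(ks_cost), np.nan)
    ratio_all = np.full(len(ks_cost), np.nan)
    for i in range(1, len(ks_cost)):
        drop_all[i] = f[i - 1] - f[i]
    for i in range(1, len(ks_cost) - 1):
        ratio_all[i] = max(drop_all[i], 0.0) / max(drop_all[i + 1], 1e-4)
    off = len(ks_cost) - len(ks)
    costs = costs[off:]
    f = f[off:]
    drop = drop_all[off:]
    ratio = ratio_all[off:]
    elbow_k = ks[int(np.nanargmax(ratio))]
    dunn_k = ks[int(np.argmax(dunns))]
    converged = elbow_k == dunn_k
    if not converged:
        log.warning("elbow (k=%d) and Dunn's index (k=%d) diverge; "
                    "returning the elbow k", elbow_k, dunn_k)
    diag = pd.DataFrame({
        "k": ks, "cost": costs, "norm_cost": f,
        "drop": drop, "drop_ratio": ratio, "dunn": dunns,
    })
    diag.attrs.update(elbow_k=elbow_k, dunn_k=dunn_k, converged=converged)
    return elbow_k, diag


def cluster_windows(
    wfc: dict,
    k: int,
    n_init: int = 20,
    max_iter: int = 300,
    seed: int = 0,
) -> StateModel:
    """Pool all participants' windows, cluster, and relabel by occupancy.

    ``wfc`` maps participant id to :class:`WindowedFCSeries`; windows from
    all participants (patients and controls) are clustered jointly.
    """
    pids = list(wfc)
    counts = [wfc[p].n_windows for p in pids]
    X = np.concatenate([wfc[p].values for p in pids], axis=0)
    raw_labels, centroids, cost, n_iter = kmeans_cityblock(
        X, k, n_init=n_init, max_iter=max_iter, seed=seed)
    labels: dict = {}
    off = 0
    for p, c in zip(pids, counts):
        labels[p] = raw_labels[off:off + c] + 1
        off += c
    model = StateModel(k=k, centroids=centroids, labels=labels,
                       cost=cost, n_iter=n_iter)
    return relabel_by_occupancy(model)


def relabel_by_occupancy(model: StateModel) -> StateModel:
    """Re-code states so state 1 has the greatest total window count.

    Ties are broken by ascending original cluster id.
    """
    pooled = model.pooled_labels()
    counts = np.array([(pooled == c + 1).sum() for c in range(model.k)])
    order = sorted(range(model.k), key=lambda c: (-counts[c], c))
    relabel = {orig + 1: rank + 1 for rank, orig in enumerate(order)}
    if any(relabel[c] != c for c in relabel):
        log.info("occupancy re-coding map: %s", relabel)
    lut = np.empty(model.k + 1, dtype=int)
    for orig, new in relabel.items():
        lut[orig] = new
    new_labels = {p: lut[v] for p, v in model.labels.items()}
    new_centroids = np.empty_like(model.centroids)
    for orig, new in relabel.items():
        new_centroids[new - 1] = model.centroids[orig - 1]
    occupancy = counts[order]
    return StateModel(
        k=model.k, centroids=new_centroids, labels=new_labels,
        cost=model.cost, occupancy=occupancy, relabel_map=relabel,
        n_iter=model.n_iter,
    )


@dataclass
class StateSummary:
    """Per-participant, per-state median FC vectors.

    ``medians[p]`` is a k x n_pairs array with NaN rows for unvisited
    states; ``visited[p]`` the corresponding boolean mask.
    """

    k: int
    medians: dict = field(repr=False)
    visited: dict = field(repr=False)


def participant_state_medians(
    wfc: dict, labels: dict, k: int
) -> StateSummary:
    """Coordinate-wise median FC over each participant's windows per state.

    Unvisited states are missing (NaN rows), never zero.
    """
    medians: dict = {}
    visited: dict = {}
    for p, series in wfc.items():
        V = series.values if isinstance(series, WindowedFCSeries) else np.asarray(series)
        lab = np.asarray(labels[p])
        if lab.shape[0] != V.shape[0]:
            raise ValueError(f"labels misaligned with windows for {p}")
        med = np.full((k, V.shape[1]), np.nan)
        vis = np.zeros(k, dtype=bool)
        for s in range(k):
            mask = lab == s + 1
            if mask.any():
                med[s] = np.median(V[mask], axis=0)
                vis[s] = True
        medians[p] = med
        visited[p] = vis
    return StateSummary(k=k, medians=medians, visited=visited)
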