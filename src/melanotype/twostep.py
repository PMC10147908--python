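"""Two-step cluster analysis for continuous features.

The procedure mirrors the classic scalable two-step clusterer: a sequential
pre-clustering pass compresses records into sufficient-statistic summaries
(count, per-feature sum and sum of squares), which are then merged
agglomeratively under a log-likelihood distance,

    xi_v   = -N_v * sum_k 0.5 * ln(g_k + s2_vk)
    d(i,j) = xi_i + xi_j - xi_{i u j},

where ``g_k`` is the global variance of feature k (a smoothing term that
keeps the log defined for singletons) and ``s2_vk`` the cluster's ML
variance. The number of clusters is chosen automatically from the BIC
trace, BIC(J) = -2 * sum_v xi_v + 2*K*J*ln N, by a two-stage rule: an
initial estimate from the ratio of successive BIC improvements (threshold
0.04), refined by the ratio of minimum inter-cluster merge distances
(threshold 1.15). Records are finally hard-assigned to the nearest cluster
under the singleton-to-cluster distance. Model quality is summarized by a
centroid-based silhouette of cohesion and separation.

Features are standardized to zero mean and unit variance by default; the
pre-clustering pass is order-dependent, so the input order is shuffled once
with the run seed, which is recorded in the fitted model.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd

__all__ = [
    "ClusterFeatureSpace",
    "ClusterSummary",
    "ClusterModel",
    "build_feature_space",
    "loglik_distance",
    "precluster",
    "merge_and_select_k",
    "silhouette_cohesion_separation",
    "fit_twostep",
    "search_feature_subset",
]

JMAX_DEFAULT = 6
BIC_RATIO_THRESHOLD = 0.04
DISTANCE_RATIO_THRESHOLD = 1.15
PRECLUSTER_BYPASS_N = 5_000
MAX_LEAF_ENTRIES = 512


@dataclass(frozen=True)
class ClusterFeatureSpace:
    """Feature names, the affine transform applied, and the smoothing variances."""

    features: tuple[str, ...]
    offset: np.ndarray   # subtracted from raw features
    scale: np.ndarray    # divisor
    g: np.ndarray        # per-feature global variance in working units

    def __post_init__(self):
        if np.any(self.g <= 0):
            raise ValueError("global feature variances must be positive")

    def transform(self, x_raw: np.ndarray) -> np.ndarray:
        return (x_raw - self.offset) / self.scale

    def inverse(self, x: np.ndarray) -> np.ndarray:
        return x * self.scale + self.offset


def build_feature_space(
    x_raw: np.ndarray, features, standardize: bool = True
) -> ClusterFeatureSpace:
    x_raw = np.asarray(x_raw, dtype=float)
    mean = x_raw.mean(axis=0)
    var = x_raw.var(axis=0)
    if np.any(var <= 0):
        bad = [f for f, v in zip(features, var) if v <= 0]
        raise ValueError(f"features with zero variance: {bad}")
    if standardize:
        scale = np.sqrt(var)
        g = np.ones_like(var)
        offset = mean
    else:
        scale = np.ones_like(var)
        g = var.copy()
        offset = np.zeros_like(var)
    return ClusterFeatureSpace(tuple(features), offset, scale, g)


# ---------------------------------------------------------------------------
# sufficient statistics and the log-likelihood distance
# ---------------------------------------------------------------------------

@dataclass
class ClusterSummary:
    """Mergeable sufficient statistics of one (sub)cluster."""

    n: float
    s: np.ndarray   # per-feature sum
    q: np.ndarray   # per-feature sum of squares

    @classmethod
    def from_points(cls, x: np.ndarray) -> "ClusterSummary":
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return cls(n=float(len(x)), s=x.sum(axis=0), q=(x**2).sum(axis=0))

    def merge(self, other: "ClusterSummary") -> "ClusterSummary":
        return ClusterSummary(self.n + other.n, self.s + other.s, self.q + other.q)

    @property
    def mean(self) -> np.ndarray:
        return self.s / self.n

    @property
    def ml_var(self) -> np.ndarray:
        return np.clip(self.q / self.n - (self.s / self.n) ** 2, 0.0, None)


def _xi(n, s, q, g):
    """xi contribution of clusters given stacked stats (broadcasts)."""
    n = np.asarray(n, dtype=float)
    var = np.clip(q / n[..., None] - (s / n[..., None]) ** 2, 0.0, None)
    return -n * 0.5 * np.log(g + var).sum(axis=-1)


def loglik_distance(i: ClusterSummary, j: ClusterSummary, space: ClusterFeatureSpace) -> float:
    """d(i, j) = xi_i + xi_j - xi_{i u j}; symmetric and >= 0."""
    if i.n <= 0 or j.n <= 0:
        raise ValueError("cluster summaries must be non-empty")
    g = space.g
    xi_i = float(_xi(i.n, i.s, i.q, g))
    xi_j = float(_xi(j.n, j.s, j.q, g))
    m = i.merge(j)
    return xi_i + xi_j - float(_xi(m.n, m.s, m.q, g))


def _dist_one_to_many(n_i, s_i, q_i, xi_i, n, s, q, xi, g):
    """Vectorized d(cluster i, each cluster in the stacked arrays)."""
    nm = n_i + n
    sm = s_i[None, :] + s
    qm = q_i[None, :] + q
    xim = _xi(nm, sm, qm, g)
    return xi_i + xi - xim


# ---------------------------------------------------------------------------
# sequential pre-clustering (CF-style leaf entries, flat, threshold-grown)
# ---------------------------------------------------------------------------

@numba.njit(cache=False)
def _seq_insert(x, start, n, s, q, xi, m, threshold, max_entries, g, membership):
    """Sequential CF insertion loop; returns (m, next_record_index).

    Stops (for a Python-level rebuild) as soon as entries exceed
    ``max_entries``; otherwise runs to the end of ``x``.
    """
    n_rec, n_feat = x.shape
    # xi of any singleton: variance 0 in every feature
    xi_single = 0.0
    for k in range(n_feat):
        xi_single -= 0.5 * np.log(g[k])
    for r in range(start, n_rec):
        best = -1
        best_d = np.inf
        for j in range(m):
            nm = n[j] + 1.0
            xim = 0.0
            for k in range(n_feat):
                sm = s[j, k] + x[r, k]
                qm = q[j, k] + x[r, k] * x[r, k]
                var = qm / nm - (sm / nm) ** 2
                if var < 0.0:
                    var = 0.0
                xim += np.log(g[k] + var)
            d = xi[j] + xi_single + 0.5 * nm * xim
            if d < best_d:
                best_d = d
                best = j
        if best >= 0 and best_d <= threshold:
            n[best] += 1.0
            acc = 0.0
            for k in range(n_feat):
                s[best, k] += x[r, k]
                q[best, k] += x[r, k] * x[r, k]
                var = q[best, k] / n[best] - (s[best, k] / n[best]) ** 2
                if var < 0.0:
                    var = 0.0
                acc += np.log(g[k] + var)
            xi[best] = -n[best] * 0.5 * acc
            membership[r] = best
        else:
            n[m] = 1.0
            for k in range(n_feat):
                s[m, k] = x[r, k]
                q[m, k] = x[r, k] * x[r, k]
            xi[m] = xi_single
            membership[r] = m
            m += 1
            if m > max_entries:
                return m, r + 1
    return m, n_rec


def precluster(
    x: np.ndarray,
    space: ClusterFeatureSpace,
    max_leaf_entries: int = MAX_LEAF_ENTRIES,
    bypass_n: int | None = PRECLUSTER_BYPASS_N,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Compress rows of ``x`` into subcluster stats ``(n, s, q, membership)``.

    Each record joins its nearest entry when the log-likelihood distance
    increase stays below the current threshold, else starts a new entry.
    When entries exceed ``max_leaf_entries`` the threshold is raised to the
    median nearest-neighbour merge distance and all entries are re-inserted.
    With ``bypass_n`` set and N <= bypass_n, every record is its own summary.

    ``membership[r]`` is the subcluster index of record r.
    """
    x = np.ascontiguousarray(x, dtype=float)
    n_rec, n_feat = x.shape
    if n_rec == 0:
        raise ValueError("need at least one record")
    if bypass_n is not None and n_rec <= bypass_n:
        return (
            np.ones(n_rec),
            x.copy(),
            x**2,
            np.arange(n_rec),
        )

    g = np.ascontiguousarray(space.g, dtype=float)
    cap = max_leaf_entries + 1
    n = np.zeros(cap)
    s = np.zeros((cap, n_feat))
    q = np.zeros((cap, n_feat))
    xi = np.zeros(cap)
    m = 0
    threshold = 0.0
    membership = np.empty(n_rec, dtype=np.int64)
    r = 0
    while r < n_rec:
        m, r = _seq_insert(x, r, n, s, q, xi, m, threshold, max_leaf_entries, g, membership)
        if m > max_leaf_entries:
            # record -> entry assignments survive rebuilds via a relabel map
            n, s, q, xi, m, threshold, relabel = _rebuild(
                n, s, q, xi, m, threshold, g, max_leaf_entries, cap
            )
            membership[:r] = relabel[membership[:r]]
    return n[:m].copy(), s[:m].copy(), q[:m].copy(), membership


def _rebuild(n, s, q, xi, m, threshold, g, max_leaf_entries, cap):
    """Raise the threshold and re-insert entries until they fit the leaf cap."""
    relabel_total = np.arange(m)
    while m > max_leaf_entries:
        # nearest-neighbour merge distance of each entry
        nn = np.empty(m)
        for i in range(m):
            d = _dist_one_to_many(n[i], s[i], q[i], xi[i], n[:m], s[:m], q[:m], xi[:m], g)
            d[i] = np.inf
            nn[i] = d.min()
        threshold = max(float(np.median(nn)), threshold * 2.0, 1e-12)
        nn_new = np.zeros(cap)
        s_new = np.zeros_like(s)
        q_new = np.zeros_like(q)
        xi_new = np.zeros(cap)
        m_new = 0
        relabel = np.empty(m, dtype=np.int64)
        for i in range(m):
            if m_new > 0:
                d = _dist_one_to_many(
                    n[i], s[i], q[i], xi[i],
                    nn_new[:m_new], s_new[:m_new], q_new[:m_new], xi_new[:m_new], g,
                )
                j = int(np.argmin(d))
            else:
                j = -1
            if j >= 0 and d[j] <= threshold:
                nn_new[j] += n[i]
                s_new[j] += s[i]
                q_new[j] += q[i]
                xi_new[j] = float(_xi(nn_new[j], s_new[j], q_new[j], g))
                relabel[i] = j
            else:
                nn_new[m_new] = n[i]
                s_new[m_new] = s[i]
                q_new[m_new] = q[i]
                xi_new[m_new] = xi[i]
                relabel[i] = m_new
                m_new += 1
        n, s, q, xi, m = nn_new, s_new, q_new, xi_new, m_new
        relabel_total = relabel[relabel_total]
    return n, s, q, xi, m, threshold, relabel_total


# ---------------------------------------------------------------------------
# agglomeration, BIC trace, automatic choice of k
# ---------------------------------------------------------------------------

@dataclass
class ClusterModel:
    """Fitted two-step clustering result."""

    k: int
    features: tuple[str, ...]
    assignments: np.ndarray            # record -> cluster id (0..k-1)
    sizes: np.ndarray                  # N_v from the final hard assignment
    centroids: np.ndarray              # standardized/working units, (k, K)
    centroids_raw: np.ndarray          # raw feature units
    variances: np.ndarray              # ML variances, working units
    bic: np.ndarray                    # BIC(J), J = 1..Jmax (NaN where undefined)
    merge_distances: dict[int, float]  # J -> distance of the merge J -> J-1
    silhouette: float
    seed: int | None
    space: ClusterFeatureSpace

    @property
    def proportions(self) -> np.ndarray:
        return self.sizes / self.sizes.sum()


def merge_and_select_k(n, s, q, space: ClusterFeatureSpace, jmax: int = JMAX_DEFAULT):
    """Greedy agglomeration with BIC-based automatic selection of k.

    Parameters are stacked subcluster stats. Returns ``(k, bic, merge_dists,
    snapshots)`` where ``snapshots[J]`` holds the cluster stats and the
    subcluster->cluster mapping of the J-cluster solution.
    """
    g = space.g
    n = np.asarray(n, dtype=float).copy()
    s = np.asarray(s, dtype=float).copy()
    q = np.asarray(q, dtype=float).copy()
    m0 = len(n)
    n_total = n.sum()
    xi = _xi(n, s, q, g)
    active = np.ones(m0, dtype=bool)
    parent = np.arange(m0)  # subcluster -> current cluster root
    nn_dist = np.full(m0, np.inf)
    nn_idx = np.full(m0, -1)

    def rescan(i):
        idx = np.flatnonzero(active)
        d = _dist_one_to_many(n[i], s[i], q[i], xi[i], n[idx], s[idx], q[idx], xi[idx], g)
        d[idx == i] = np.inf
        j = int(np.argmin(d))
        nn_dist[i] = d[j]
        nn_idx[i] = idx[j]
        return idx, d

    snapshots: dict[int, dict] = {}

    def snapshot(count):
        idx = np.flatnonzero(active)
        snapshots[count] = {
            "idx": idx.copy(),
            "n": n[idx].copy(),
            "s": s[idx].copy(),
            "q": q[idx].copy(),
            "sum_xi": float(xi[idx].sum()),
            "parent": parent.copy(),
        }

    if m0 > 1:
        for i in range(m0):
            rescan(i)
    count = m0
    if count <= jmax:
        snapshot(count)
    merge_dists: dict[int, float] = {}
    while count > 1:
        idx = np.flatnonzero(active)
        best = idx[int(np.argmin(nn_dist[idx]))]
        i, j = best, int(nn_idx[best])
        d_star = float(nn_dist[best])
        # merge j into i
        n[i] += n[j]
        s[i] += s[j]
        q[i] += q[j]
        xi[i] = float(_xi(n[i], s[i], q[i], g))
        active[j] = False
        parent[parent == j] = i
        merge_dists[count] = d_star
        count -= 1
        if count > 1:
            _, d_to_i = rescan(i)
            idx = np.flatnonzero(active)
            # i's stats changed: it may have become (or stopped being) a NN
            closer = d_to_i < nn_dist[idx]
            nn_dist[idx[closer]] = d_to_i[closer]
            nn_idx[idx[closer]] = i
            stale = idx[(nn_idx[idx] == j) | ((nn_idx[idx] == i) & ~closer)]
            for r in stale:
                if r != i:
                    rescan(r)
        if count <= jmax:
            snapshot(count)

    k_feat = s.shape[1]
    bic = np.full(jmax, np.nan)
    for j_count, snap in snapshots.items():
        if j_count <= jmax:
            bic[j_count - 1] = -2.0 * snap["sum_xi"] + 2.0 * k_feat * j_count * np.log(n_total)
    k = _choose_k(bic, merge_dists, jmax, available=max(snapshots) if snapshots else 1)
    return k, bic, merge_dists, snapshots


def _choose_k(bic, merge_dists, jmax, available):
    """Two-stage automatic cluster-count rule (0.04 BIC ratio, 1.15 distance ratio)."""
    jmax_eff = min(jmax, available)
    if jmax_eff <= 1 or np.isnan(bic[1]):
        return 1
    dbic = {j: bic[j - 1] - bic[j - 2] for j in range(2, jmax_eff + 1) if not np.isnan(bic[j - 1])}
    if 2 not in dbic or dbic[2] >= 0:
        return 1
    j1 = 2
    for j in range(3, jmax_eff + 1):
        if j not in dbic or dbic[j] / dbic[2] < BIC_RATIO_THRESHOLD:
            break
        j1 = j
    if j1 == 1:
        return 1
    # refinement: jumps in the minimum inter-cluster merge distance
    ratios = {}
    for j in range(2, j1 + 1):
        if j in merge_dists and (j + 1) in merge_dists and merge_dists[j + 1] > 0:
            ratios[j] = merge_dists[j] / merge_dists[j + 1]
    if not ratios:
        return j1
    order = sorted(ratios, key=lambda j: ratios[j], reverse=True)
    if len(order) == 1:
        return order[0]
    top, second = order[0], order[1]
    if ratios[top] / ratios[second] >= DISTANCE_RATIO_THRESHOLD:
        return top
    return max(top, second)


def _assign_records(x, snap, space):
    """Hard assignment: nearest cluster by singleton-to-cluster distance."""
    g = space.g
    n_v, s_v, q_v = snap["n"], snap["s"], snap["q"]
    xi_v = _xi(n_v, s_v, q_v, g)
    x2 = x**2
    xi_x = _xi(np.ones(len(x)), x, x2, g)
    d = np.empty((len(x), len(n_v)))
    for v in range(len(n_v)):
        nm = n_v[v] + 1.0
        sm = s_v[v][None, :] + x
        qm = q_v[v][None, :] + x2
        var = np.clip(qm / nm - (sm / nm) ** 2, 0.0, None)
        xim = -nm * 0.5 * np.log(g + var).sum(axis=1)
        d[:, v] = xi_v[v] + xi_x - xim
    return np.argmin(d, axis=1)


def silhouette_cohesion_separation(x, assignments, space=None):
    """Centroid-based mean silhouette on the working feature space.

    a(i) = Euclidean distance to the own-cluster centroid, b(i) = distance
    to the nearest other centroid, s(i) = (b - a)/max(a, b). Undefined for
    k = 1 (returns NaN with a warning).
    """
    x = np.asarray(x, dtype=float)
    assignments = np.asarray(assignments)
    labels = np.unique(assignments)
    if len(labels) < 2:
        warnings.warn("silhouette undefined for a single cluster; returning NaN")
        return float("nan")
    centroids = np.stack([x[assignments == lab].mean(axis=0) for lab in labels])
    d = np.sqrt(((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2))
    own_col = np.searchsorted(labels, assignments)
    a = d[np.arange(len(x)), own_col]
    d_other = d.copy()
    d_other[np.arange(len(x)), own_col] = np.inf
    b = d_other.min(axis=1)
    denom = np.maximum(a, b)
    s = np.where(denom > 0, (b - a) / np.where(denom > 0, denom, 1.0), 0.0)
    return float(s.mean())


def fit_twostep(
    data,
    features,
    jmax: int = JMAX_DEFAULT,
    seed: int | None = 0,
    standardize: bool = True,
    bypass_n: int | None = PRECLUSTER_BYPASS_N,
    max_leaf_entries: int = MAX_LEAF_ENTRIES,
) -> ClusterModel:
    """Fit the full two-step clustering to a feature table.

    ``data`` is a DataFrame with the feature columns (or a 2-D array in the
    order of ``features``). The input order is shuffled once with ``seed``
    before the order-dependent pre-clustering pass; assignments are returned
    in the original record order.
    """
    features = tuple(features)
    if isinstance(data, pd.DataFrame):
        x_raw = data.loc[:, list(features)].to_numpy(dtype=float)
    else:
        x_raw = np.asarray(data, dtype=float)
        if x_raw.shape[1] != len(features):
            raise ValueError("data width does not match the feature list")
    if len(x_raw) < 1:
        raise ValueError("need at least one record")
    space = build_feature_space(x_raw, features, standardize=standardize)
    x = space.transform(x_raw)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(x)) if seed is not None else np.arange(len(x))
    x_shuf = x[order]

    n, s, q, _membership = precluster(
        x_shuf, space, max_leaf_entries=max_leaf_entries, bypass_n=bypass_n
    )
    k, bic, merge_dists, snapshots = merge_and_select_k(n, s, q, space, jmax=jmax)
    snap = snapshots.get(k) or snapshots[min(snapshots)]
    assign_shuf = _assign_records(x_shuf, snap, space)
    assignments = np.empty(len(x), dtype=np.int64)
    assignments[order] = assign_shuf

    sizes = np.bincount(assignments, minlength=len(snap["n"])).astype(float)
    centroids = np.empty((len(snap["n"]), x.shape[1]))
    variances = np.empty_like(centroids)
    for v in range(len(snap["n"])):
        mask = assignments == v
        if mask.any():
            centroids[v] = x[mask].mean(axis=0)
            variances[v] = x[mask].var(axis=0)
        else:  # cluster emptied by reassignment; fall back to merged stats
            centroids[v] = snap["s"][v] / snap["n"][v]
            variances[v] = np.clip(
                snap["q"][v] / snap["n"][v] - centroids[v] ** 2, 0.0, None
            )
    sil = (
        silhouette_cohesion_separation(x, assignments, space)
        if len(np.unique(assignments)) > 1
        else float("nan")
    )
    return ClusterModel(
        k=int(k),
        features=features,
        assignments=assignments,
        sizes=sizes,
        centroids=centroids,
        centroids_raw=space.inverse(centroids),
        variances=variances,
        bic=bic,
        merge_distances=merge_dists,
        silhouette=sil,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        space=space,
    )


def search_feature_subset(
    data: pd.DataFrame,
    candidates,
    jmax: int = JMAX_DEFAULT,
    seed: int | None = 0,
    standardize: bool = True,
    bypass_n: int | None = 2_000,
    max_leaf_entries: int = 256,
):
    """Exhaustively fit every non-empty feature subset; maximize silhouette.

    Returns ``(best_subset, models, silhouettes)`` with one fitted model per
    subset. Subsets whose model degenerates to one cluster score -inf. Ties
    break toward fewer features, then lexicographic order. Pre-clustering is
    applied above ``bypass_n`` records to keep the 2^|candidates|-1 fits
    tractable.
    """
    candidates = tuple(candidates)
    if not candidates:
        raise ValueError("candidate feature list is empty")
    models: dict[tuple[str, ...], ClusterModel] = {}
    silhouettes: dict[tuple[str, ...], float] = {}
    best = None
    best_key = None
    for size in range(1, len(candidates) + 1):
        for subset in itertools.combinations(candidates, size):
            model = fit_twostep(
                data, subset, jmax=jmax, seed=seed, standardize=standardize,
                bypass_n=bypass_n, max_leaf_entries=max_leaf_entries,
            )
            sil = model.silhouette
            score = -np.inf if not np.isfinite(sil) else sil
            models[subset] = model
            silhouettes[subset] = sil
            key = (score, -size, tuple(-ord(c) for c in ",".join(subset)))
            if best_key is None or key > best_key:
                best_key = key
                best = subset
    return best, models, silhouettes
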