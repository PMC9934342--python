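"""Cohort stratification on the inhibition metric M(r) = (L_r, G_r).

Per-patient coordinates are z-scored across the cohort, the optimal
number of groups is chosen by a majority vote of cluster-validity
indices, k-means splits the cohort, and the cluster whose metric is
more dispersed is labelled the "Invasion" group (clustered, invasive
phenotype) while the tighter cluster is the "Gibbs" group (inhibited
phenotype, where L_r and G_r agree).  An incremental-centroid
trajectory — re-clustering growing patient prefixes — makes the
convergence of the Gibbs group visible.

Index battery (each implemented from its published formula and voting
for the k at which it is optimal): silhouette, Calinski-Harabasz,
Davies-Bouldin, Dunn, gap statistic, C-index, McClain-Rao,
Ratkowsky-Lance, point-biserial, Ball-Hall.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from sklearn.cluster import KMeans
from sklearn.metrics import (calinski_harabasz_score, davies_bouldin_score,
                             silhouette_score)

__all__ = ["ClusteringResult", "zscore_metrics", "optimal_k",
           "kmeans_cluster", "incremental_centroids", "index_battery",
           "name_groups_by_interaction", "GROUP_GIBBS", "GROUP_INVASION"]

GROUP_GIBBS = "Gibbs"
GROUP_INVASION = "Invasion"


def zscore_metrics(records: pd.DataFrame,
                   columns=("L_r", "G_r")) -> pd.DataFrame:
    """Append per-coordinate z-scores (sample SD, n-1) as z_<col>.

    Raises on fewer than 2 records or a zero-variance coordinate
    (a degenerate cohort cannot be standardised).
    """
    if len(records) < 2:
        raise ValueError("z-scoring needs at least 2 records")
    out = records.copy()
    for c in columns:
        x = records[c].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        # a coordinate constant to within round-off cannot be
        # standardised (the centred values are pure cancellation noise)
        if sd <= 1e-12 * max(1.0, float(np.abs(x).max())):
            raise ValueError(f"coordinate {c!r} has zero variance")
        out[f"z_{c}"] = (x - x.mean()) / sd
    return out


# --------------------------------------------------------------------------
# k-means
# --------------------------------------------------------------------------

@dataclass
class ClusteringResult:
    k: int
    labels: np.ndarray                 # integer labels in [0, k)
    centroids: np.ndarray              # (k, d)
    inertia: float
    within_cluster_ss: np.ndarray      # per-cluster sum of squares
    group_of_cluster: dict = field(default_factory=dict)
    seed: int | None = None
    n_restarts: int = 50
    optimal_k: int | None = None
    votes: dict = field(default_factory=dict)

    @property
    def group_labels(self) -> np.ndarray:
        """Phenotype name per observation (k = 2 only)."""
        if not self.group_of_cluster:
            raise ValueError("group naming is defined only for k = 2")
        return np.array([self.group_of_cluster[l] for l in self.labels])


def kmeans_cluster(points, k: int, seed=None,
                   n_restarts: int = 50) -> ClusteringResult:
    """Best-of-restarts k-means++ with variance-based group naming.

    For k = 2 the cluster whose metric is more dispersed (larger
    within-cluster variance, i.e. mean squared deviation from its
    centroid) is named "Invasion" and the tighter one "Gibbs"; an exact
    tie is broken by centroid norm (larger norm -> Invasion).
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2:
        raise ValueError("points must be 2-D (n, d)")
    n = len(X)
    if k < 1 or k > n:
        raise ValueError(f"k = {k} out of range for n = {n}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts,
                tol=1e-10, random_state=None if seed is None else int(seed))
    labels = km.fit_predict(X)
    centroids = km.cluster_centers_
    wss = np.array([
        ((X[labels == j] - centroids[j]) ** 2).sum() for j in range(k)
    ])
    groups = {}
    if k == 2:
        sizes = np.array([(labels == j).sum() for j in range(k)])
        wvar = wss / np.maximum(sizes, 1)
        if wvar[0] != wvar[1]:
            invasion = int(np.argmax(wvar))
        else:
            invasion = int(np.argmax(np.linalg.norm(centroids, axis=1)))
        groups = {invasion: GROUP_INVASION, 1 - invasion: GROUP_GIBBS}
    return ClusteringResult(k=k, labels=labels, centroids=centroids,
                            inertia=float(km.inertia_),
                            within_cluster_ss=wss, group_of_cluster=groups,
                            seed=seed, n_restarts=n_restarts)


def name_groups_by_interaction(labels, gamma) -> dict:
    """Name two clusters from their mean fitted interaction strength.

    The cluster whose patterns carry the smaller mean log gamma — the
    direct evidence of inhibition from the Geyer fits — is the "Gibbs"
    group, the other "Invasion".  This is more robust than the
    within-cluster-variance heuristic when the two clusters are
    comparably dispersed; it requires the fitted gamma per observation,
    so it applies downstream of the model-fitting stage only.
    """
    labels = np.asarray(labels)
    lg = np.log(np.maximum(np.asarray(gamma, dtype=float), 1e-12))
    ks = np.unique(labels)
    if len(ks) != 2:
        raise ValueError("interaction naming is defined for k = 2")
    means = {k: np.nanmean(lg[labels == k]) for k in ks}
    gibbs = min(means, key=means.get)
    other = [k for k in ks if k != gibbs][0]
    return {int(gibbs): GROUP_GIBBS, int(other): GROUP_INVASION}


# --------------------------------------------------------------------------
# validity indices
# --------------------------------------------------------------------------

def _pair_split(X, labels):
    """Within/between pairwise distances and the pooled sorted distances."""
    d = pdist(X)
    n = len(X)
    iu, ju = np.triu_indices(n, k=1)
    same = labels[iu] == labels[ju]
    return d[same], d[~same], d


def _wss_total(X, labels, centroids):
    return float(sum(((X[labels == j] - centroids[j]) ** 2).sum()
                     for j in range(len(centroids))))


def index_battery(X: np.ndarray, results: dict[int, ClusteringResult],
                  gap_B: int = 20, seed=None) -> dict[str, dict]:
    """Evaluate the 10 validity indices at every k in ``results``.

    Returns {index_name: {"values": {k: value}, "best_k": k}}.  Rules:
    maximise silhouette, Calinski-Harabasz, Dunn, point-biserial and
    Ratkowsky-Lance; minimise Davies-Bouldin, C-index and McClain-Rao;
    the gap statistic uses the Tibshirani one-SE rule; Ball-Hall votes
    for the largest drop between successive levels.
    """
    ks = sorted(results)
    rng = np.random.default_rng(seed)
    n, p = X.shape
    tss_per_var = ((X - X.mean(axis=0)) ** 2).sum(axis=0)

    vals: dict[str, dict[int, float]] = {name: {} for name in (
        "silhouette", "calinski_harabasz", "davies_bouldin", "dunn",
        "gap", "c_index", "mcclain_rao", "ratkowsky_lance",
        "point_biserial", "ball_hall")}
    gap_sk: dict[int, float] = {}

    # reference sets for the gap statistic: uniform over the bounding box
    # of the data in its principal-component frame (the recommended form
    # of the reference; an axis-aligned box badly overstates the null
    # dispersion of elongated, correlated clouds)
    Xc = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    Xp = Xc @ Vt.T
    mins, maxs = Xp.min(axis=0), Xp.max(axis=0)
    ref_logW = {k: [] for k in ks}
    for _ in range(gap_B):
        R = rng.uniform(mins, maxs, size=(n, p)) @ Vt
        for k in ks:
            km = KMeans(n_clusters=k, n_init=5,
                        random_state=int(rng.integers(2 ** 31)))
            km.fit(R)
            ref_logW[k].append(np.log(max(km.inertia_, 1e-300)))

    for k in ks:
        res = results[k]
        labels, C = res.labels, res.centroids
        W = max(_wss_total(X, labels, C), 1e-300)

        if k >= 2 and len(set(labels)) >= 2:
            vals["silhouette"][k] = silhouette_score(X, labels)
            vals["calinski_harabasz"][k] = calinski_harabasz_score(X, labels)
            vals["davies_bouldin"][k] = davies_bouldin_score(X, labels)

            dw, db, dall = _pair_split(X, labels)
            # Dunn: min between-cluster distance / max cluster diameter
            diam = max(dw.max() if len(dw) else 0.0, 1e-300)
            vals["dunn"][k] = (db.min() if len(db) else np.inf) / diam
            # C-index
            s = dw.sum()
            nw = len(dw)
            dsort = np.sort(dall)
            smin, smax = dsort[:nw].sum(), dsort[-nw:].sum()
            vals["c_index"][k] = (s - smin) / max(smax - smin, 1e-300)
            # McClain-Rao: mean within / mean between
            vals["mcclain_rao"][k] = (dw.mean() / db.mean()
                                      if len(db) else np.inf)
            # point-biserial: (mean between - mean within) scaled
            nb = len(db)
            nt = nw + nb
            sd_all = dall.std()
            vals["point_biserial"][k] = (
                (db.mean() - dw.mean())
                * np.sqrt(nw * nb / nt ** 2) / max(sd_all, 1e-300))
        # Ratkowsky-Lance: mean_j sqrt(BGSS_j / TSS_j) / sqrt(k)
        bgss_per_var = np.zeros(p)
        for j in range(len(C)):
            nj = (labels == j).sum()
            bgss_per_var += nj * (C[j] - X.mean(axis=0)) ** 2
        ratio = np.sqrt(np.clip(bgss_per_var / np.maximum(tss_per_var, 1e-300),
                                0, 1))
        vals["ratkowsky_lance"][k] = ratio.mean() / np.sqrt(k)
        # Ball-Hall: W_k / k
        vals["ball_hall"][k] = W / k
        # gap
        logWref = np.array(ref_logW[k])
        gap = logWref.mean() - np.log(W)
        vals["gap"][k] = gap
        gap_sk[k] = logWref.std() * np.sqrt(1.0 + 1.0 / gap_B)

    out = {}
    maximise = {"silhouette", "calinski_harabasz", "dunn",
                "point_biserial", "ratkowsky_lance"}
    minimise = {"davies_bouldin", "c_index", "mcclain_rao"}
    for name, v in vals.items():
        if not v:
            continue
        kk = sorted(v)
        if name in maximise:
            best = kk[int(np.argmax([v[k] for k in kk]))]
        elif name in minimise:
            best = kk[int(np.argmin([v[k] for k in kk]))]
        elif name == "ball_hall":
            if len(kk) < 2:
                best = kk[0]
            else:
                drops = [v[kk[i]] - v[kk[i + 1]] for i in range(len(kk) - 1)]
                best = kk[int(np.argmax(drops)) + 1]
        elif name == "gap":
            best = kk[-1]
            for i, k in enumerate(kk[:-1]):
                if v[k] >= v[kk[i + 1]] - gap_sk[kk[i + 1]]:
                    best = k
                    break
        out[name] = {"values": v, "best_k": int(best)}
    return out


def optimal_k(points, k_range=range(2, 9), seed=None,
              n_restarts: int = 20, gap_B: int = 20):
    """Modal best-k over the index battery; ties go to the smaller k.

    Returns (k_star, votes) where ``votes`` maps index name to its vote.
    """
    X = np.asarray(points, dtype=float)
    k_range = sorted(k_range)
    if len(X) < 2 * max(k_range):
        raise ValueError(
            f"need at least {2 * max(k_range)} points for k up to "
            f"{max(k_range)}")
    rng = np.random.default_rng(seed)
    results = {k: kmeans_cluster(X, k, seed=int(rng.integers(2 ** 31)),
                                 n_restarts=n_restarts) for k in k_range}
    battery = index_battery(X, results, gap_B=gap_B,
                            seed=int(rng.integers(2 ** 31)))
    votes = {name: rec["best_k"] for name, rec in battery.items()}
    counts = pd.Series(list(votes.values())).value_counts()
    top = counts[counts == counts.max()].index.min()
    return int(top), votes


# --------------------------------------------------------------------------
# incremental centroids
# --------------------------------------------------------------------------

def incremental_centroids(points, inclusion_order=None, start: int = 20,
                          k: int = 2, seed=None, n_restarts: int = 10):
    """Centroid trajectories over growing prefixes of the cohort.

    Re-runs k-means on points[order[:m]] for m = start .. n and records
    the k centroids, matching cluster identities between successive
    prefix sizes by nearest-centroid continuity.  Returns an array of
    shape (n - start + 1, k, d).
    """
    X = np.asarray(points, dtype=float)
    n = len(X)
    if start < 2 * k:
        raise ValueError("start must be at least 2k")
    if inclusion_order is None:
        inclusion_order = np.arange(n)
    order = np.asarray(inclusion_order)
    rng = np.random.default_rng(seed)

    traj = []
    prev = None
    for m in range(start, n + 1):
        res = kmeans_cluster(X[order[:m]], k,
                             seed=int(rng.integers(2 ** 31)),
                             n_restarts=n_restarts)
        C = res.centroids
        if prev is not None:
            # greedy nearest-centroid matching to the previous step
            D = cdist(prev, C)
            perm = np.full(k, -1)
            used = set()
            for _ in range(k):
                i, j = np.unravel_index(np.argmin(D), D.shape)
                perm[i] = j
                used.add(j)
                D[i, :] = np.inf
                D[:, j] = np.inf
            C = C[perm]
        traj.append(C)
        prev = C
    return np.asarray(traj)
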