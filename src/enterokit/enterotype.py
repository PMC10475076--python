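"""Enterotyping: PAM clustering on the root-JSD distance with
Calinski–Harabasz model selection and silhouette validation.

The protocol: keep the most abundant genera (top 35 by mean relative
abundance), compute pairwise root-JSD with a 1e-6 pseudocount, cluster by
partitioning around medoids for each candidate k, pick the k maximising
the Calinski–Harabasz index, validate with the mean silhouette width, and
name each cluster by its driver — the genus with the highest mean relative
abundance inside the cluster.

PAM is the full Kaufman–Rousseeuw BUILD + SWAP algorithm (greedy seeding,
then steepest-descent swaps to a local optimum of total distance to
medoid), not k-medoids-by-alternation: CH and silhouette values are
sensitive to local optima. The algorithm is deterministic — ties in BUILD
and SWAP break on the lowest sample index — so results are reproducible
without a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from sklearn.base import BaseEstimator, ClusterMixin

from .distance import DEFAULT_PSEUDOCOUNT, pairwise
from .ordination import _as_square, pcoa_coordinates
from .preprocess import _as_table


def select_top_taxa(table: pd.DataFrame, n: int = 35) -> pd.DataFrame:
    """Keep the *n* taxa with the highest mean relative abundance.

    Rows are NOT renormalised: the downstream distance applies its own
    pseudocount renormalisation, and reported abundances stay on the
    original scale. Ties in the mean break on column order.
    """
    table = _as_table(table)
    if table.shape[1] < n:
        raise ValueError(f"table has {table.shape[1]} taxa, fewer than n={n}")
    means = table.mean(axis=0).to_numpy()
    order = np.argsort(-means, kind="stable")[:n]
    return table.iloc[:, np.sort(order)]


# ---------------------------------------------------------------------------
# PAM


def _pam_build(D: np.ndarray, k: int) -> list[int]:
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        nearest = D[:, medoids].min(axis=1)
        # gain of adding candidate c: Σ_i max(nearest_i − d(i,c), 0)
        gains = np.maximum(nearest[:, None] - D, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    return medoids


def _pam_swap(D: np.ndarray, medoids: list[int]) -> tuple[np.ndarray, list[int], float]:
    n = D.shape[0]
    medoids = list(medoids)
    while True:
        dm = D[:, medoids]  # n × k
        order = np.argsort(dm, axis=1, kind="stable")
        d1 = dm[np.arange(n), order[:, 0]]
        n1 = order[:, 0]  # index into medoid list
        d2 = dm[np.arange(n), order[:, 1]] if len(medoids) > 1 else np.full(n, np.inf)
        cost = d1.sum()
        best = (0.0, None, None)
        in_medoids = np.zeros(n, dtype=bool)
        in_medoids[medoids] = True
        candidates = np.flatnonzero(~in_medoids)
        for mi, m in enumerate(medoids):
            loses_m = n1 == mi
            base = np.where(loses_m, d2, d1)  # distance if m removed (h ignored)
            for h in candidates:
                new = np.minimum(base, D[:, h])
                delta = new.sum() - cost
                if delta < best[0] - 1e-12:
                    best = (delta, mi, h)
        if best[1] is None:
            break
        medoids[best[1]] = int(best[2])
        new_cost = D[:, medoids].min(axis=1).sum()
        assert new_cost <= cost + 1e-9, "PAM swap increased total cost"
    dm = D[:, medoids]
    labels = np.argmin(dm, axis=1)
    return labels, medoids, float(dm.min(axis=1).sum())


def pam(d, k: int, seed: int | None = None) -> tuple[np.ndarray, list[str], float]:
    """Partition a distance matrix around *k* medoids.

    Returns (labels, medoid ids, total cost). *seed* is accepted for
    interface stability but unused: BUILD and SWAP are deterministic with
    lowest-index tie-breaking.
    """
    D, ids = _as_square(d)
    n = D.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for n={n}")
    if k == n:
        return np.arange(n), list(ids), 0.0
    medoids = _pam_build(D, k)
    labels, medoids, cost = _pam_swap(D, medoids)
    return labels, [ids[m] for m in medoids], cost


class KMedoids(BaseEstimator, ClusterMixin):
    """PAM clustering on a precomputed distance matrix, sklearn-style.

    Attributes after :meth:`fit`: ``labels_``, ``medoid_indices_``,
    ``medoid_ids_``, ``inertia_`` (total distance to medoid).
    """

    def __init__(self, n_clusters: int = 2, random_state: int | None = None):
        self.n_clusters = n_clusters
        self.random_state = random_state

    def fit(self, X, y=None):
        D, ids = _as_square(X)
        labels, medoid_ids, cost = pam(X, self.n_clusters, seed=self.random_state)
        self.labels_ = labels
        self.medoid_ids_ = medoid_ids
        self.medoid_indices_ = np.array([ids.index(m) for m in medoid_ids])
        self.inertia_ = cost
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


# ---------------------------------------------------------------------------
# cluster-number selection and validation


def ch_index(d, labels, method: str = "distance") -> float:
    """Calinski–Harabasz index CH = (B/(k−1)) / (W/(n−k)).

    ``method="distance"`` (default) uses the pairwise-distance form that
    operates directly on any dissimilarity matrix: W = Σ_g Σ_{i<j∈g}
    d²_ij / n_g, total T = Σ_{i<j} d²_ij / n, B = T − W. In Euclidean
    space this equals the textbook centroid-variance form; on root-JSD —
    which has no centroids — it is the natural generalisation, and equals
    the PERMANOVA pseudo-F of the clustering.

    ``method="pcoa"`` embeds the matrix by classical metric scaling and
    evaluates the centroid form on the coordinates.
    """
    D, _ = _as_square(d)
    labels = np.asarray(labels)
    n = D.shape[0]
    uniq = np.unique(labels)
    k = len(uniq)
    if k < 2:
        raise ValueError("CH index undefined for a single cluster")
    if k >= n:
        raise ValueError("CH index undefined for k >= n")
    if method == "pcoa":
        from sklearn.metrics import calinski_harabasz_score

        coords = pcoa_coordinates(D, min(n - 1, D.shape[0] - 1))
        return float(calinski_harabasz_score(coords, labels))
    if method != "distance":
        raise ValueError(f"unknown method {method!r}")
    D2 = D**2
    total = D2.sum() / (2.0 * n)
    within = 0.0
    for g in uniq:
        mask = labels == g
        n_g = int(mask.sum())
        within += D2[np.ix_(mask, mask)].sum() / (2.0 * n_g)
    between = total - within
    return float((between / (k - 1)) / (within / (n - k)))


@dataclass
class CHCurve:
    """CH index over a range of candidate cluster numbers."""

    k_values: list[int]
    ch: list[float]

    @property
    def argmax_k(self) -> int:
        return self.k_values[int(np.argmax(self.ch))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k_values, "ch": self.ch}).set_index("k")


def scan_k(
    d, k_min: int = 2, k_max: int = 9, seed: int | None = None
) -> tuple[CHCurve, dict[int, np.ndarray]]:
    """PAM + CH index at each k in [k_min, k_max]; returns the curve and
    the PAM solution (labels, medoid ids) per k, so the selected
    clustering needn't be refit."""
    D, _ = _as_square(d)
    n = D.shape[0]
    if not 2 <= k_min <= k_max < n:
        raise ValueError(f"need 2 <= k_min <= k_max < n; got [{k_min}, {k_max}], n={n}")
    ks, chs, solutions = [], [], {}
    for k in range(k_min, k_max + 1):
        labels, medoid_ids, _ = pam(d, k, seed=seed)
        ks.append(k)
        chs.append(ch_index(d, labels))
        solutions[k] = (labels, medoid_ids)
    return CHCurve(ks, chs), solutions


def silhouette(d, labels) -> float:
    """Mean silhouette width over samples, in [−1, 1].

    Per sample, a = mean distance to its own cluster (excluding itself),
    b = smallest mean distance to another cluster, s = (b − a)/max(a, b);
    members of singleton clusters contribute 0.
    """
    D, _ = _as_square(d)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    n = D.shape[0]
    scores = np.zeros(n)
    masks = {g: labels == g for g in uniq}
    sizes = {g: int(m.sum()) for g, m in masks.items()}
    for i in range(n):
        own = labels[i]
        if sizes[own] == 1:
            continue
        a = D[i, masks[own]].sum() / (sizes[own] - 1)
        b = min(D[i, masks[g]].mean() for g in uniq if g != own)
        scores[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(scores.mean())


def assign_driver_taxa(table: pd.DataFrame, labels) -> dict[int, tuple[str, float]]:
    """Name each cluster by its most abundant genus.

    Returns {cluster: (taxon, mean relative abundance in cluster)} — e.g.
    a *Bacteroides* cluster at 0.38 means *Bacteroides* averages 38% of
    the community among that cluster's samples.
    """
    table = _as_table(table)
    labels = np.asarray(labels)
    if len(labels) != table.shape[0]:
        raise ValueError("one label per sample required")
    out: dict[int, tuple[str, float]] = {}
    for g in np.unique(labels):
        mask = labels == g
        if not mask.any():
            raise ValueError(f"empty cluster {g}")
        means = table.loc[mask].mean(axis=0)
        out[int(g)] = (str(means.idxmax()), float(means.max()))
    return out


# ---------------------------------------------------------------------------
# the full protocol


@dataclass
class EnterotypeResult:
    """Everything the enterotyping protocol produces."""

    labels: pd.Series  # cluster index per sample
    medoid_ids: list[str]
    ch_curve: CHCurve
    best_k: int
    silhouette: float
    driver_taxa: dict[int, tuple[str, float]]
    cluster_sizes: dict[int, int]
    distance: skbio.DistanceMatrix
    weak_structure: bool

    def summary(self) -> dict:
        return {
            "best_k": self.best_k,
            "silhouette": self.silhouette,
            "cluster_sizes": {str(k): v for k, v in self.cluster_sizes.items()},
            "driver_taxa": {
                str(k): {"taxon": t, "mean_abundance": a}
                for k, (t, a) in self.driver_taxa.items()
            },
            "medoid_ids": self.medoid_ids,
            "ch_curve": {str(k): c for k, c in zip(self.ch_curve.k_values, self.ch_curve.ch)},
            "weak_structure": self.weak_structure,
        }


class Enterotyper(BaseEstimator, ClusterMixin):
    """The full enterotyping protocol as a clusterer over abundance tables.

    ``fit`` expects a samples × taxa relative-abundance DataFrame and runs:
    top-``top_n`` genus selection → pairwise root-JSD (pseudocount
    ``pseudocount``) → PAM at each k in [``k_min``, ``k_max``] → CH-index
    argmax (unless ``n_clusters`` forces k) → silhouette validation →
    driver naming on the full input table.

    A fit with mean silhouette below ``weak_silhouette`` sets
    ``weak_structure_`` — the data may not support discrete enterotypes
    (see the methods note for the threshold's rationale).
    """

    def __init__(
        self,
        top_n: int = 35,
        k_min: int = 2,
        k_max: int = 9,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        n_clusters: int | None = None,
        weak_silhouette: float = 0.15,
        random_state: int | None = None,
    ):
        self.top_n = top_n
        self.k_min = k_min
        self.k_max = k_max
        self.pseudocount = pseudocount
        self.n_clusters = n_clusters
        self.weak_silhouette = weak_silhouette
        self.random_state = random_state

    def fit(self, X, y=None):
        table = _as_table(X)
        top = select_top_taxa(table, n=min(self.top_n, table.shape[1]))
        dist = pairwise(top, "jsd", pseudocount=self.pseudocount)
        curve, solutions = scan_k(
            dist, k_min=self.k_min, k_max=self.k_max, seed=self.random_state
        )
        best_k = self.n_clusters if self.n_clusters is not None else curve.argmax_k
        if best_k in solutions:
            labels, medoid_ids = solutions[best_k]
        else:
            labels, medoid_ids, _ = pam(dist, best_k, seed=self.random_state)
        sil = silhouette(dist, labels)
        self.labels_ = labels
        self.medoid_ids_ = medoid_ids
        self.ch_curve_ = curve
        self.best_k_ = int(best_k)
        self.silhouette_ = sil
        self.driver_taxa_ = assign_driver_taxa(table, labels)
        self.cluster_sizes_ = {int(g): int((labels == g).sum()) for g in np.unique(labels)}
        self.distance_ = dist
        self.sample_ids_ = list(table.index)
        self.weak_structure_ = sil < self.weak_silhouette
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def enterotype_pipeline(
    table: pd.DataFrame,
    k_min: int = 2,
    k_max: int = 9,
    top_n: int = 35,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    seed: int | None = None,
) -> EnterotypeResult:
    """Functional form of :class:`Enterotyper` returning an
    :class:`EnterotypeResult`."""
    est = Enterotyper(
        top_n=top_n,
        k_min=k_min,
        k_max=k_max,
        pseudocount=pseudocount,
        random_state=seed,
    ).fit(table)
    return EnterotypeResult(
        labels=pd.Series(est.labels_, index=est.sample_ids_, name="enterotype"),
        medoid_ids=est.medoid_ids_,
        ch_curve=est.ch_curve_,
        best_k=est.best_k_,
        silhouette=est.silhouette_,
        driver_taxa=est.driver_taxa_,
        cluster_sizes=est.cluster_sizes_,
        distance=est.distance_,
        weak_structure=est.weak_structure_,
    )


__all__ = [
    "select_top_taxa",
    "pam",
    "KMedoids",
    "ch_index",
    "CHCurve",
    "scan_k",
    "silhouette",
    "assign_driver_taxa",
    "EnterotypeResult",
    "Enterotyper",
    "enterotype_pipeline",
]
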