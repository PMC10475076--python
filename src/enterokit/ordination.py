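"""Ordination and distance-based permutation tests.

NMDS embeds a dissimilarity matrix in few dimensions preserving rank
order, via SMACOF stress majorization with isotonic regression (Kruskal's
primary approach to ties); quality is Kruskal stress-1. PERMANOVA
partitions squared dissimilarities into between/within-group sums via the
Gower-centred identity; ANOSIM compares mean between- vs within-group
distance ranks. Both tests use the (1 + #{perm ≥ obs})/(1 + n_perm)
p-value convention, so the minimum attainable p is 1/(n_perm + 1) and
p = 0 is impossible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from scipy.stats import rankdata
from sklearn.base import BaseEstimator
from sklearn.manifold import smacof


def _as_square(d) -> tuple[np.ndarray, list[str]]:
    if isinstance(d, skbio.DistanceMatrix):
        return d.data.copy(), [str(i) for i in d.ids]
    arr = np.asarray(d, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("expected a square distance matrix")
    return arr, [str(i) for i in range(arr.shape[0])]


def pcoa_coordinates(D: np.ndarray, n_components: int) -> np.ndarray:
    """Classical metric scaling (principal coordinates) of a distance matrix."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:n_components]
    coords = vecs[:, order] * np.sqrt(np.clip(vals[order], 0.0, None))
    if coords.shape[1] < n_components:  # pad degenerate cases
        coords = np.pad(coords, ((0, 0), (0, n_components - coords.shape[1])))
    return coords


class NMDS(BaseEstimator):
    """Non-metric multidimensional scaling on a precomputed dissimilarity.

    Runs ``n_starts`` SMACOF optimisations — the first initialised from
    classical metric scaling (PCoA) so one start is deterministic and
    usually near-optimal, the rest from random configurations — and keeps
    the lowest-stress solution. Stress is Kruskal stress-1 in [0, 1].

    Attributes (after :meth:`fit`)
    ------------------------------
    embedding_ : ndarray of shape (n_samples, n_components), centred at 0
    stress_ : float
    sample_ids_ : list of str
    """

    def __init__(
        self,
        n_components: int = 2,
        n_starts: int = 20,
        max_iter: int = 300,
        eps: float = 1e-9,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.eps = eps
        self.random_state = random_state

    def fit(self, X, y=None):
        D, ids = _as_square(X)
        n = D.shape[0]
        if n < self.n_components + 1:
            raise ValueError("NMDS needs at least n_components + 1 samples")
        rng = np.random.default_rng(self.random_state)
        best: tuple[float, np.ndarray] | None = None
        for start in range(self.n_starts):
            if start == 0:
                init = pcoa_coordinates(D, self.n_components)
            else:
                init = rng.normal(size=(n, self.n_components))
            coords, stress = smacof(
                D,
                metric=False,
                n_components=self.n_components,
                init=init,
                n_init=1,
                max_iter=self.max_iter,
                eps=self.eps,
                normalized_stress=True,
            )
            if best is None or stress < best[0]:
                best = (float(stress), coords)
        stress, coords = best[0], best[1]
        self.embedding_ = coords - coords.mean(axis=0)
        self.stress_ = stress
        self.sample_ids_ = ids
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).embedding_


@dataclass
class Ordination:
    """An NMDS solution: centred coordinates plus the achieved stress."""

    coordinates: pd.DataFrame
    stress: float
    n_starts: int
    seed: int | None


def nmds(
    d,
    n_dims: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    seed: int | None = None,
) -> Ordination:
    """Functional form of :class:`NMDS`."""
    est = NMDS(
        n_components=n_dims, n_starts=n_starts, max_iter=max_iter, random_state=seed
    ).fit(d)
    frame = pd.DataFrame(
        est.embedding_,
        index=est.sample_ids_,
        columns=[f"NMDS{i + 1}" for i in range(n_dims)],
    )
    return Ordination(coordinates=frame, stress=est.stress_, n_starts=n_starts, seed=seed)


@dataclass
class PermutationTestResult:
    """Observed statistic with its label-permutation p-value."""

    statistic_name: str
    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None


def _group_setup(d, groups):
    D, ids = _as_square(d)
    groups = np.asarray(groups)
    if len(groups) != D.shape[0]:
        raise ValueError("one group label per sample required")
    levels, codes = np.unique(groups, return_inverse=True)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    if np.bincount(codes).max() == len(codes):
        raise ValueError("one group absorbs all samples")
    return D, codes, len(levels)


def _permanova_f(D2: np.ndarray, codes_batch: np.ndarray, k: int) -> np.ndarray:
    """Pseudo-F for each row of label codes (batch × n)."""
    n = D2.shape[0]
    ss_total = D2.sum() / (2.0 * n)
    ss_within = np.zeros(codes_batch.shape[0])
    for g in range(k):
        Z = (codes_batch == g).astype(float)
        n_g = Z.sum(axis=1)
        pair_sum = ((Z @ D2) * Z).sum(axis=1)  # = 2 · Σ_{i<j∈g} d²
        ss_within += np.where(n_g > 0, pair_sum / (2.0 * np.maximum(n_g, 1)), 0.0)
    ss_between = ss_total - ss_within
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def permanova(
    d, groups, n_permutations: int = 999, seed: int | None = None
) -> PermutationTestResult:
    """PERMANOVA (adonis): pseudo-F on a distance matrix, p by permutation.

    pseudo-F = (SS_between/(k−1)) / (SS_within/(n−k)) with the sums of
    squares obtained from pairwise squared distances via the Gower-centred
    partition (SS_total = Σ_{i<j} d²_ij / n, SS_within summed per group
    with its own size as divisor).
    """
    D, codes, k = _group_setup(d, groups)
    D2 = D**2
    observed = float(_permanova_f(D2, codes[None, :], k)[0])
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(codes) for _ in range(n_permutations)])
    null = _permanova_f(D2, perms, k) if n_permutations else np.empty(0)
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_permutations)
    return PermutationTestResult("pseudo-F", observed, float(p), n_permutations, seed)


def _anosim_r(rank_sq: np.ndarray, codes_batch: np.ndarray, k: int) -> np.ndarray:
    n = rank_sq.shape[0]
    m = n * (n - 1) / 2.0
    total_sum = rank_sq.sum() / 2.0
    within_sum = np.zeros(codes_batch.shape[0])
    within_cnt = np.zeros(codes_batch.shape[0])
    for g in range(k):
        Z = (codes_batch == g).astype(float)
        n_g = Z.sum(axis=1)
        within_sum += ((Z @ rank_sq) * Z).sum(axis=1) / 2.0
        within_cnt += n_g * (n_g - 1) / 2.0
    between_cnt = m - within_cnt
    r_w = within_sum / within_cnt
    r_b = (total_sum - within_sum) / between_cnt
    return (r_b - r_w) / (m / 2.0)


def anosim(
    d, groups, n_permutations: int = 999, seed: int | None = None
) -> PermutationTestResult:
    """ANOSIM: R = (mean between-group rank − mean within-group rank)/(M/2).

    Distance ranks use midranks for ties over the M = n(n−1)/2 pairs;
    R ∈ [−1, 1], near 0 under exchangeable labels, 1 when every
    between-group distance exceeds every within-group distance.
    """
    D, codes, k = _group_setup(d, groups)
    n = D.shape[0]
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(D[iu])
    rank_sq = np.zeros((n, n))
    rank_sq[iu] = ranks
    rank_sq = rank_sq + rank_sq.T
    observed = float(_anosim_r(rank_sq, codes[None, :], k)[0])
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(codes) for _ in range(n_permutations)])
    null = _anosim_r(rank_sq, perms, k) if n_permutations else np.empty(0)
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_permutations)
    return PermutationTestResult("R", observed, float(p), n_permutations, seed)


__all__ = [
    "NMDS",
    "Ordination",
    "nmds",
    "pcoa_coordinates",
    "PermutationTestResult",
    "permanova",
    "anosim",
]
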