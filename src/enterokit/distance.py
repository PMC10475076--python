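"""Pairwise sample dissimilarities: the root-JSD enterotyping metric,
Bray–Curtis, binary Jaccard, and both UniFrac variants.

The enterotyping distance between samples *a* and *b* is

    D(a, b) = sqrt( ½·KLD(p_a, m) + ½·KLD(p_b, m) ),   m = (p_a + p_b)/2,

the square root of the Jensen–Shannon divergence of the two abundance
distributions, with natural-log KLD(x, y) = Σ_i x_i log(x_i / y_i). A
pseudocount (default 1e-6) is added to every entry and the profiles are
renormalised, so the divergence is always finite; root-JSD is a true
metric on the simplex, bounded by sqrt(log 2).

UniFrac is computed by a single post-order pass that accumulates, for each
branch, the fraction of each sample's reads descending through it;
unweighted UniFrac is unique-over-covered branch length on presence,
weighted UniFrac the classic unnormalised Σ_b l_b·|A_b − B_b|.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import skbio
from scipy.special import rel_entr

from .preprocess import _as_table

#: pseudocount applied before JSD to avoid zeros in the log
DEFAULT_PSEUDOCOUNT = 1e-6


def _as_profile(x) -> np.ndarray:
    p = np.asarray(x, dtype=float)
    if (p < 0).any():
        raise ValueError("negative abundances")
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero profile")
    return p / total


def kld(x, y) -> float:
    """Kullback–Leibler divergence Σ x_i log(x_i / y_i), natural log.

    Terms with x_i = 0 contribute 0; a y_i = 0 where x_i > 0 is an error
    (apply a pseudocount first if zeros are possible).
    """
    x = _as_profile(x)
    y = _as_profile(y)
    if np.any((y == 0) & (x > 0)):
        raise ValueError("KLD undefined: y has a zero where x is positive")
    return float(rel_entr(x, y).sum())


def _pseudocounted(p: np.ndarray, pseudocount: float) -> np.ndarray:
    p = p + pseudocount
    return p / p.sum(axis=-1, keepdims=True)


def jsd_metric(a, b, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """Root Jensen–Shannon divergence between two abundance profiles."""
    pa = _pseudocounted(_as_profile(a), pseudocount)
    pb = _pseudocounted(_as_profile(b), pseudocount)
    m = 0.5 * (pa + pb)
    jsd = 0.5 * rel_entr(pa, m).sum() + 0.5 * rel_entr(pb, m).sum()
    return float(np.sqrt(max(jsd, 0.0)))


def bray_curtis(a, b) -> float:
    """Bray–Curtis dissimilarity Σ|a_i − b_i| / Σ(a_i + b_i)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    denom = (a + b).sum()
    if denom <= 0:
        raise ValueError("Bray–Curtis undefined for two all-zero samples")
    return float(np.abs(a - b).sum() / denom)


def binary_jaccard(a, b) -> float:
    """1 − |A∩B|/|A∪B| on the presence (count > 0) sets."""
    a = np.asarray(a, dtype=float) > 0
    b = np.asarray(b, dtype=float) > 0
    union = (a | b).sum()
    if union == 0:
        raise ValueError("Jaccard undefined for two all-zero samples")
    return float(1.0 - (a & b).sum() / union)


# ---------------------------------------------------------------------------
# UniFrac


def _tree_arrays(tree: skbio.TreeNode, taxon_ids) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths and branch × taxon incidence for a leaf-labelled tree.

    Row r of the incidence matrix flags the taxa descending through branch
    r (the edge above node r); the root's edge is excluded. Raises if a
    requested taxon is not a leaf of the tree.
    """
    taxon_ids = list(taxon_ids)
    pos = {t: i for i, t in enumerate(taxon_ids)}
    missing = set(taxon_ids) - {leaf.name for leaf in tree.tips()}
    if missing:
        raise ValueError(f"taxa missing from tree: {sorted(missing)[:5]}")
    lengths: list[float] = []
    rows: list[np.ndarray] = []
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            mask = np.zeros(len(taxon_ids), dtype=bool)
            if node.name in pos:
                mask[pos[node.name]] = True
        else:
            mask = np.zeros(len(taxon_ids), dtype=bool)
            for child in node.children:
                mask |= below[id(child)]
        below[id(node)] = mask
        if node.parent is not None:  # root edge excluded
            lengths.append(float(node.length or 0.0))
            rows.append(mask)
    return np.asarray(lengths), np.asarray(rows)


def unweighted_unifrac(a, b, tree: skbio.TreeNode, taxon_ids=None) -> float:
    """Fraction of covered branch length unique to one of the two samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if taxon_ids is None:
        taxon_ids = [leaf.name for leaf in tree.tips()]
    lengths, incidence = _tree_arrays(tree, taxon_ids)
    in_a = incidence @ (a > 0) > 0
    in_b = incidence @ (b > 0) > 0
    covered = float(lengths[in_a | in_b].sum())
    if covered == 0:
        raise ValueError("UniFrac undefined: no covered branches")
    unique = float(lengths[in_a ^ in_b].sum())
    return unique / covered


def weighted_unifrac(a, b, tree: skbio.TreeNode, taxon_ids=None) -> float:
    """Classic unnormalised weighted UniFrac Σ_b l_b·|A_b − B_b|."""
    pa = _as_profile(a)
    pb = _as_profile(b)
    if taxon_ids is None:
        taxon_ids = [leaf.name for leaf in tree.tips()]
    lengths, incidence = _tree_arrays(tree, taxon_ids)
    return float(np.abs(incidence @ pa - incidence @ pb) @ lengths)


# ---------------------------------------------------------------------------
# pairwise matrices

METRICS = ("jsd", "braycurtis", "jaccard", "unifrac-u", "unifrac-w")


def _jsd_matrix(P: np.ndarray, pseudocount: float) -> np.ndarray:
    P = _pseudocounted(P / P.sum(axis=1, keepdims=True), pseudocount)
    n = P.shape[0]
    out = np.zeros((n, n))
    for i in range(n - 1):
        rest = P[i + 1 :]
        m = 0.5 * (P[i] + rest)
        jsd = 0.5 * rel_entr(P[i], m).sum(axis=1) + 0.5 * rel_entr(rest, m).sum(axis=1)
        out[i, i + 1 :] = np.sqrt(np.maximum(jsd, 0.0))
    return out + out.T


def pairwise(
    table: pd.DataFrame,
    metric: str,
    tree: skbio.TreeNode | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> skbio.DistanceMatrix:
    """All-pairs dissimilarity matrix for a samples × taxa table.

    ``metric`` is one of ``jsd``, ``braycurtis``, ``jaccard``,
    ``unifrac-u``, ``unifrac-w`` (the UniFrac variants require *tree*).
    Returns a :class:`skbio.DistanceMatrix`, which enforces symmetry and a
    zero diagonal.
    """
    table = _as_table(table)
    if table.shape[0] < 2:
        raise ValueError("pairwise distances need at least 2 samples")
    X = table.to_numpy(dtype=float)
    ids = list(table.index)
    n = len(ids)

    if metric == "jsd":
        if np.any(X.sum(axis=1) <= 0):
            raise ValueError("all-zero sample in table")
        data = _jsd_matrix(X, pseudocount)
    elif metric == "braycurtis":
        data = np.zeros((n, n))
        for i in range(n - 1):
            rest = X[i + 1 :]
            denom = (X[i] + rest).sum(axis=1)
            if np.any(denom <= 0):
                bad = ids[i + 1 + int(np.argmax(denom <= 0))]
                raise ValueError(f"Bray–Curtis undefined for all-zero pair ({ids[i]}, {bad})")
            data[i, i + 1 :] = np.abs(X[i] - rest).sum(axis=1) / denom
        data = data + data.T
    elif metric == "jaccard":
        B = X > 0
        inter = B.astype(float) @ B.T
        sizes = B.sum(axis=1)
        union = sizes[:, None] + sizes[None, :] - inter
        if np.any(union == 0):
            raise ValueError("Jaccard undefined: a pair of all-zero samples")
        data = 1.0 - inter / union
        np.fill_diagonal(data, 0.0)
    elif metric in ("unifrac-u", "unifrac-w"):
        if tree is None:
            raise ValueError(f"metric {metric!r} requires a phylogeny")
        lengths, incidence = _tree_arrays(tree, table.columns)
        if metric == "unifrac-u":
            present = (incidence.astype(float) @ (X > 0).T) > 0  # branches × samples
            data = np.zeros((n, n))
            for i in range(n - 1):
                other = present[:, i + 1 :].T
                union = np.where(other | present[:, i], lengths, 0.0).sum(axis=1)
                sym = np.where(other ^ present[:, i], lengths, 0.0).sum(axis=1)
                if np.any(union == 0):
                    raise ValueError("UniFrac undefined: pair with no covered branches")
                data[i, i + 1 :] = sym / union
            data = data + data.T
        else:
            totals = X.sum(axis=1, keepdims=True)
            if np.any(totals <= 0):
                raise ValueError("all-zero sample in table")
            U = (X / totals) @ incidence.T  # samples × branches
            data = np.zeros((n, n))
            for i in range(n - 1):
                data[i, i + 1 :] = np.abs(U[i + 1 :] - U[i]) @ lengths
            data = data + data.T
    else:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")

    return skbio.DistanceMatrix(data, ids=ids)


__all__ = [
    "DEFAULT_PSEUDOCOUNT",
    "METRICS",
    "kld",
    "jsd_metric",
    "bray_curtis",
    "binary_jaccard",
    "unweighted_unifrac",
    "weighted_unifrac",
    "pairwise",
]
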