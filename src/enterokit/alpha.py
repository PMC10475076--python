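"""Alpha diversity: Chao1 richness, Shannon diversity, Kruskal–Wallis
group comparison.

Chao1 uses the bias-corrected form S_obs + F1(F1−1)/(2(F2+1)) (F1 =
singletons, F2 = doubletons), which is defined even when no doubletons are
observed; Shannon is reported in bits (log base 2) by default, matching the
convention of the QIIME 2 diversity ecosystem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import _as_table, to_relative


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness estimate for one sample.

    Requires integer counts (estimate from rarefied data); always at least
    the observed richness, and strictly larger whenever two or more
    singletons are present.
    """
    counts = np.asarray(counts, dtype=float)
    if not np.all(counts == np.floor(counts)):
        raise ValueError("Chao1 requires integer counts")
    s_obs = int(np.count_nonzero(counts))
    f1 = int(np.sum(counts == 1))
    f2 = int(np.sum(counts == 2))
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon(profile, base: float = 2.0) -> float:
    """Shannon entropy −Σ p_i log p_i of a relative-abundance profile.

    Zero entries contribute nothing (lim p→0 of p log p). Accepts
    unnormalised non-negative vectors, which are normalised first.
    """
    p = np.asarray(profile, dtype=float)
    if (p < 0).any():
        raise ValueError("negative abundances")
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero profile")
    p = p / total
    nz = p[p > 0]
    return float(-(nz * (np.log(nz) / np.log(base))).sum())


@dataclass
class GroupTest:
    """A rank-based omnibus comparison across groups."""

    statistic_name: str
    statistic: float
    p_value: float
    df: int
    group_sizes: dict[str, int]


def kruskal_wallis(values, groups) -> GroupTest:
    """Kruskal–Wallis H test of *values* across the levels of *groups*.

    Tie-corrected H with the χ² asymptotic p-value on k−1 degrees of
    freedom, as standard implementations report it.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("Kruskal–Wallis needs at least two groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group needs at least one observation")
    try:
        h, p = stats.kruskal(*samples)
    except ValueError:
        # all values identical: H = 0, no evidence against the null
        h, p = 0.0, 1.0
    return GroupTest(
        statistic_name="H",
        statistic=float(h),
        p_value=float(p),
        df=len(levels) - 1,
        group_sizes={str(g): int(len(s)) for g, s in zip(levels, samples)},
    )


def alpha_diversity(table: pd.DataFrame, base: float = 2.0) -> pd.DataFrame:
    """Per-sample Chao1 and Shannon for a (rarefied) count table."""
    table = _as_table(table)
    rel = to_relative(table)
    return pd.DataFrame(
        {
            "chao1": [chao1(row) for row in table.to_numpy()],
            "shannon": [shannon(row, base=base) for row in rel.to_numpy()],
        },
        index=table.index,
    )


def compare_alpha(
    alpha: pd.DataFrame, metadata: pd.DataFrame, phenotype: str
) -> pd.DataFrame:
    """Kruskal–Wallis comparison of each alpha metric across phenotype levels."""
    if phenotype not in metadata.columns:
        raise KeyError(f"phenotype {phenotype!r} not in metadata")
    groups = metadata.loc[alpha.index, phenotype]
    mask = groups.notna().to_numpy()
    rows = []
    for metric in alpha.columns:
        res = kruskal_wallis(alpha[metric].to_numpy()[mask], groups.to_numpy()[mask])
        rows.append(
            {"metric": metric, "H": res.statistic, "p_value": res.p_value, "df": res.df}
        )
    return pd.DataFrame(rows).set_index("metric")


__all__ = ["chao1", "shannon", "kruskal_wallis", "alpha_diversity", "compare_alpha", "GroupTest"]
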