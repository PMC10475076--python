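"""Taxon–phenotype association testing with FDR control, plus the
enterotype–phenotype contingency check.

For a categorical phenotype, each surviving taxon is tested per level pair
(Welch two-sample t on relative abundances) or across all levels at once
(Kruskal–Wallis); p-values are Benjamini–Hochberg adjusted to q-values,
with the adjustment family being all taxon × contrast tests of one
phenotype. The inclusion filter mirrors the convention of multivariable
microbiome association tools: a taxon enters testing only if present in
MORE than 10% of samples and its mean relative abundance exceeds 0.01%.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from itertools import combinations
from scipy import stats

from .alpha import kruskal_wallis
from .preprocess import _as_table

logger = logging.getLogger(__name__)


class PrevalenceAbundanceFilter:
    """Keep taxa with prevalence > ``min_prevalence`` (default 10%) AND
    mean relative abundance > ``min_rel_abund`` (default 0.01%).

    Both thresholds are strict: a taxon present in exactly 10% of samples
    is excluded. An empty survivor set is a warning, not an error.
    """

    def __init__(self, min_prevalence: float = 0.10, min_rel_abund: float = 0.0001):
        self.min_prevalence = min_prevalence
        self.min_rel_abund = min_rel_abund

    def get_params(self, deep: bool = True) -> dict:
        return {"min_prevalence": self.min_prevalence, "min_rel_abund": self.min_rel_abund}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        table = _as_table(X)
        values = table.to_numpy(dtype=float)
        prevalence = (values > 0).mean(axis=0)
        mean_abund = values.mean(axis=0)
        keep = (prevalence > self.min_prevalence) & (mean_abund > self.min_rel_abund)
        self.kept_taxa_ = list(table.columns[keep])
        if not self.kept_taxa_:
            logger.warning("prevalence/abundance filter removed every taxon")
        return self

    def transform(self, X) -> pd.DataFrame:
        return _as_table(X).loc[:, self.kept_taxa_]

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)


def prevalence_abundance_filter(
    table: pd.DataFrame, min_prevalence: float = 0.10, min_rel_abund: float = 0.0001
) -> pd.DataFrame:
    """Functional form of :class:`PrevalenceAbundanceFilter`."""
    return PrevalenceAbundanceFilter(min_prevalence, min_rel_abund).fit_transform(table)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order.

    q_(i) = min_{j ≥ i} m·p_(j)/j over the sorted p-values, capped at 1.
    Monotone in p (sorting by p sorts by q) and q ≥ p always.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class AssociationResult:
    """One taxon × contrast test within a phenotype's family."""

    taxon: str
    phenotype: str
    contrast: str
    statistic: float
    p_value: float
    q_value: float
    direction: int  # sign of mean(level A) − mean(level B); 0 for omnibus


def group_tests(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    phenotype: str,
    method: str = "ttest",
    equal_var: bool = False,
    log_transform: bool = False,
    log_pseudocount: float = 1e-6,
) -> pd.DataFrame:
    """Test every taxon against a categorical phenotype.

    ``method="ttest"`` runs a Welch two-sample t-test (pooled-variance via
    ``equal_var=True``) for every pair of phenotype levels;
    ``method="kw"`` runs one Kruskal–Wallis omnibus test per taxon across
    all levels. Optionally the abundances are log10(x + pseudocount)
    transformed first. BH adjustment is applied across all taxon ×
    contrast p-values of this phenotype. Levels with fewer than 2 samples
    are skipped with a log entry.

    Returns a long-format DataFrame of :class:`AssociationResult` fields.
    """
    table = _as_table(table)
    if phenotype not in metadata.columns:
        raise KeyError(f"phenotype {phenotype!r} not in metadata")
    if method not in ("ttest", "kw"):
        raise ValueError(f"unknown method {method!r}")
    groups = metadata.loc[table.index, phenotype]
    mask = groups.notna().to_numpy()
    groups = groups.to_numpy()[mask]
    X = table.to_numpy(dtype=float)[mask]
    if log_transform:
        X = np.log10(X + log_pseudocount)
    levels = [g for g in pd.unique(groups)]
    usable = []
    for g in levels:
        size = int((groups == g).sum())
        if size < 2:
            logger.info("phenotype %s: level %r has %d samples; skipped", phenotype, g, size)
        else:
            usable.append(g)
    if len(usable) < 2:
        raise ValueError(f"phenotype {phenotype!r} has fewer than two usable levels")

    rows = []
    for j, taxon in enumerate(table.columns):
        x = X[:, j]
        if method == "kw":
            keep = np.isin(groups, usable)
            res = kruskal_wallis(x[keep], groups[keep])
            rows.append((str(taxon), "omnibus", res.statistic, res.p_value, 0))
        else:
            for ga, gb in combinations(usable, 2):
                xa, xb = x[groups == ga], x[groups == gb]
                if np.ptp(np.concatenate([xa, xb])) == 0:
                    t, p = 0.0, 1.0
                else:
                    with warnings.catch_warnings():
                        # near-identical groups trip scipy's precision-loss
                        # warning; the t≈0, p≈1 result is what we want
                        warnings.simplefilter("ignore", RuntimeWarning)
                        t, p = stats.ttest_ind(xa, xb, equal_var=equal_var)
                rows.append(
                    (
                        str(taxon),
                        f"{ga} vs {gb}",
                        float(t),
                        float(p),
                        int(np.sign(xa.mean() - xb.mean())),
                    )
                )
    frame = pd.DataFrame(rows, columns=["taxon", "contrast", "statistic", "p_value", "direction"])
    frame.insert(1, "phenotype", phenotype)
    frame["q_value"] = bh_adjust(frame["p_value"].to_numpy())
    return frame


def enterotype_phenotype_independence(
    labels,
    metadata: pd.DataFrame,
    phenotype: str,
    n_monte_carlo: int = 9999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Pearson χ² test of independence between enterotype and a phenotype.

    Builds the r × c contingency table of enterotype label against
    phenotype level and computes the Pearson χ² statistic on
    (r−1)(c−1) degrees of freedom (no continuity correction). When any
    expected cell count is below 5 the asymptotic p is unreliable, so a
    seeded Monte-Carlo p — the fraction of margin-preserving simulated
    tables with χ² at least the observed, with the +1 convention — is
    reported instead. Returns (χ², p).
    """
    if phenotype not in metadata.columns:
        raise KeyError(f"phenotype {phenotype!r} not in metadata")
    if isinstance(labels, pd.Series):
        pheno = metadata.loc[labels.index, phenotype]
        labels = labels.to_numpy()
    else:
        labels = np.asarray(labels)
        if len(labels) != len(metadata):
            raise ValueError("one enterotype label per metadata row required")
        pheno = metadata[phenotype]
    pheno = np.asarray(pheno.astype(object))
    keep = ~pd.isna(pheno)
    labels, pheno = labels[keep], pheno[keep]
    if len(pd.unique(pheno)) < 2:
        raise ValueError(f"phenotype {phenotype!r} is constant")
    if len(pd.unique(labels)) < 2:
        raise ValueError("need at least two enterotypes")
    _, rcode = np.unique(labels.astype(str), return_inverse=True)
    _, ccode = np.unique(pheno.astype(str), return_inverse=True)
    r, c = rcode.max() + 1, ccode.max() + 1
    observed = np.bincount(rcode * c + ccode, minlength=r * c).reshape(r, c)
    chi2, p_asym, dof, expected = stats.chi2_contingency(observed, correction=False)
    if expected.min() >= 5:
        return float(chi2), float(p_asym)
    # Monte-Carlo under fixed margins: permute the phenotype vector
    rng = np.random.default_rng(seed)
    n_cells = expected.size
    flat_expected = expected.ravel()
    exceed = 0
    for _ in range(n_monte_carlo):
        perm = np.bincount(
            rcode * expected.shape[1] + rng.permutation(ccode), minlength=n_cells
        )
        stat = ((perm - flat_expected) ** 2 / flat_expected).sum()
        if stat >= chi2 - 1e-12:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_monte_carlo)
    return float(chi2), float(p)


__all__ = [
    "PrevalenceAbundanceFilter",
    "prevalence_abundance_filter",
    "bh_adjust",
    "AssociationResult",
    "group_tests",
    "enterotype_phenotype_independence",
]
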