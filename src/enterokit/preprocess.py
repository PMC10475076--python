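"""Count-table preprocessing: rarefaction, rare-feature removal, relative
abundance, and detection-rate flora classification.

The canonical order mirrors a standard amplicon workflow: rarefy to a
common depth, drop rare features, convert to relative abundance. Each step
is exposed both as a scikit-learn transformer (composable in a
:class:`sklearn.pipeline.Pipeline` over DataFrames) and as a plain
function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import validate_abundance


def _as_table(X) -> pd.DataFrame:
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X))
        X.index = X.index.astype(str)
        X.columns = X.columns.astype(str)
    if X.shape[0] == 0 or X.shape[1] == 0:
        raise ValueError("empty abundance table")
    return validate_abundance(X)


class Rarefier(BaseEstimator, TransformerMixin):
    """Subsample every sample to a fixed library size without replacement.

    Samples whose total count is below ``depth`` cannot be rarefied and are
    dropped; their ids are recorded in ``dropped_`` after ``transform``.
    Subsampling is multivariate hypergeometric (each retained read drawn
    without replacement), so a taxon absent before rarefaction stays
    absent and expected post-rarefaction counts are depth × the
    within-sample relative abundance.

    Parameters
    ----------
    depth : int, default 2000
        Target library size per sample.
    random_state : int or None
        Seed; a fixed seed gives bit-identical output.
    """

    def __init__(self, depth: int = 2000, random_state: int | None = None):
        self.depth = depth
        self.random_state = random_state

    def fit(self, X, y=None):
        if self.depth <= 0:
            raise ValueError("rarefaction depth must be positive")
        self.n_features_in_ = _as_table(X).shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        table = _as_table(X)
        if self.depth <= 0:
            raise ValueError("rarefaction depth must be positive")
        values = table.to_numpy()
        if not np.all(values == np.floor(values)):
            raise ValueError("rarefaction requires integer counts")
        counts = values.astype(np.int64)
        totals = counts.sum(axis=1)
        keep = totals >= self.depth
        self.dropped_ = list(table.index[~keep])
        rng = np.random.default_rng(self.random_state)
        out = np.empty((int(keep.sum()), counts.shape[1]), dtype=np.int64)
        for row, i in enumerate(np.flatnonzero(keep)):
            out[row] = rng.multivariate_hypergeometric(counts[i], self.depth)
        return pd.DataFrame(out, index=table.index[keep], columns=table.columns)


class RareFeatureFilter(BaseEstimator, TransformerMixin):
    """Remove rare taxa by total count, prevalence and overall abundance.

    A taxon is removed when ANY of these holds:

    * total count across samples < ``min_total`` (default 5);
    * present (count > 0) in fewer than ``min_samples`` samples (default 2,
      i.e. observed in at most one sample);
    * overall relative abundance below ``min_rel_abund`` (default 0.1%).

    The abundance rule is table-wide by default (taxon total / grand
    total, the common QIIME 2 reading); set ``per_sample_abundance=True``
    to instead require the taxon's maximum within-sample relative
    abundance to reach the threshold. Thresholds are exclusive below
    (exactly 0.1% overall abundance is NOT "below 0.1%" and is retained).
    """

    def __init__(
        self,
        min_total: float = 5,
        min_samples: int = 2,
        min_rel_abund: float = 0.001,
        per_sample_abundance: bool = False,
    ):
        self.min_total = min_total
        self.min_samples = min_samples
        self.min_rel_abund = min_rel_abund
        self.per_sample_abundance = per_sample_abundance

    def fit(self, X, y=None):
        table = _as_table(X)
        values = table.to_numpy(dtype=float)
        totals = values.sum(axis=0)
        prevalence = (values > 0).sum(axis=0)
        if self.per_sample_abundance:
            row_sums = values.sum(axis=1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                rel = np.where(row_sums > 0, values / row_sums, 0.0)
            abund = rel.max(axis=0)
        else:
            abund = totals / values.sum()
        remove = (totals < self.min_total) | (prevalence < self.min_samples) | (
            abund < self.min_rel_abund
        )
        self.kept_taxa_ = list(table.columns[~remove])
        self.removed_taxa_ = list(table.columns[remove])
        self.n_features_in_ = table.shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        table = _as_table(X)
        return table.loc[:, self.kept_taxa_]


class RelativeAbundance(BaseEstimator, TransformerMixin):
    """Row-normalise counts to per-sample relative abundance profiles."""

    def fit(self, X, y=None):
        self.n_features_in_ = _as_table(X).shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        table = _as_table(X)
        totals = table.sum(axis=1)
        zero = totals[totals == 0]
        if len(zero):
            raise ValueError(f"all-zero samples cannot be normalised: {list(zero.index[:5])}")
        return table.div(totals, axis=0)


@dataclass
class FrequencyClassification:
    """Per-taxon detection rate and low/medium/high frequency class.

    Detection rate is the fraction of samples in which the taxon has a
    nonzero count. Classes follow the <10% / 10–70% / >70% convention:
    rates of exactly 10% or 70% fall in the medium class (the only reading
    consistent with the three stated ranges).
    """

    table: pd.DataFrame  # columns: detection_rate, frequency_class

    @property
    def class_counts(self) -> dict[str, int]:
        counts = self.table["frequency_class"].value_counts()
        return {c: int(counts.get(c, 0)) for c in ("low", "medium", "high")}

    def taxa_in_class(self, cls: str) -> list[str]:
        return list(self.table.index[self.table["frequency_class"] == cls])


def classify_detection_rate(
    table: pd.DataFrame, low: float = 0.10, high: float = 0.70
) -> FrequencyClassification:
    """Classify taxa into low/medium/high-frequency flora by detection rate."""
    table = _as_table(table)
    rate = (table.to_numpy(dtype=float) > 0).mean(axis=0)
    cls = np.where(rate < low, "low", np.where(rate > high, "high", "medium"))
    frame = pd.DataFrame(
        {"detection_rate": rate, "frequency_class": cls}, index=table.columns
    )
    frame.index.name = "taxon"
    return FrequencyClassification(frame)


def rarefy(
    table: pd.DataFrame, depth: int = 2000, seed: int | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Functional form of :class:`Rarefier`; returns (table, dropped ids)."""
    est = Rarefier(depth=depth, random_state=seed)
    out = est.fit(table).transform(table)
    return out, est.dropped_


def filter_rare_features(
    table: pd.DataFrame,
    min_total: float = 5,
    min_samples: int = 2,
    min_rel_abund: float = 0.001,
    per_sample_abundance: bool = False,
) -> pd.DataFrame:
    """Functional form of :class:`RareFeatureFilter`."""
    return RareFeatureFilter(
        min_total=min_total,
        min_samples=min_samples,
        min_rel_abund=min_rel_abund,
        per_sample_abundance=per_sample_abundance,
    ).fit_transform(table)


def to_relative(table: pd.DataFrame) -> pd.DataFrame:
    """Functional form of :class:`RelativeAbundance`."""
    return RelativeAbundance().fit_transform(table)


__all__ = [
    "Rarefier",
    "RareFeatureFilter",
    "RelativeAbundance",
    "FrequencyClassification",
    "classify_detection_rate",
    "rarefy",
    "filter_rare_features",
    "to_relative",
]
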