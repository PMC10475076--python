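import numpy as np
import pandas as pd
import pytest

import enterokit as ek


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-sample, 60-genus two-enterotype cohort with planted effects."""
    spec = ek.default_cohort_spec(n_samples=120, n_taxa=60, seed=42)
    table, meta, labels = ek.generate_cohort(spec, ek.default_planted_effects())
    return spec, table, meta, labels


@pytest.fixture(scope="session")
def small_rel(small_cohort):
    """Rarefied, filtered, relative-abundance version of the small cohort."""
    _, table, meta, labels = small_cohort
    rarefied, dropped = ek.rarefy(table, depth=2000, seed=7)
    assert not dropped  # depths are drawn at >= 2000
    rel = ek.to_relative(ek.filter_rare_features(rarefied))
    return rel, meta.loc[rel.index], labels


def random_profiles(rng, n, t):
    """Random points on the t-simplex (Dirichlet with unit concentration)."""
    return rng.dirichlet(np.ones(t), size=n)


def random_table(rng, n=8, t=6, max_count=50):
    counts = rng.integers(0, max_count, size=(n, t))
    return pd.DataFrame(
        counts,
        index=[f"s{i}" for i in range(n)],
        columns=[f"t{j}" for j in range(t)],
    )
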