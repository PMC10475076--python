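"""Dissimilarity metrics against closed forms, brute-force oracles, metric
properties (Gibbs inequality, triangle inequality) and the scikit-bio
UniFrac reference implementation."""

import io as _io

import numpy as np
import pytest
import skbio
from hypothesis import given, settings, strategies as st

import enterokit as ek
from enterokit.distance import _pseudocounted
from enterokit.io import tree_to_newick
from tests.conftest import random_profiles, random_table


class TestKLD:
    def test_identity_is_zero(self):
        p = np.array([0.2, 0.3, 0.5])
        assert ek.kld(p, p) == pytest.approx(0.0, abs=1e-15)

    def test_hand_evaluation(self):
        expected = 0.5 * np.log(2) + 0.5 * np.log(2 / 3)
        assert ek.kld([0.5, 0.5], [0.25, 0.75]) == pytest.approx(expected, abs=1e-12)

    def test_nonnegative_gibbs(self):
        rng = np.random.default_rng(0)
        P = random_profiles(rng, 1000, 8)
        Q = random_profiles(rng, 1000, 8)
        for p, q in zip(P, Q):
            assert ek.kld(p, q) >= -1e-12

    def test_zero_in_y_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            ek.kld([0.5, 0.5], [1.0, 0.0])

    def test_zero_in_x_contributes_nothing(self):
        assert ek.kld([1.0, 0.0], [0.5, 0.5]) == pytest.approx(np.log(2))


def brute_force_jsd(a, b, pc=1e-6):
    """Definitional root-JSD, element by element."""
    a = np.asarray(a, float) / np.sum(a)
    b = np.asarray(b, float) / np.sum(b)
    a = (a + pc) / (a + pc).sum()
    b = (b + pc) / (b + pc).sum()
    m = (a + b) / 2
    jsd = 0.0
    for i in range(len(a)):
        jsd += 0.5 * a[i] * np.log(a[i] / m[i]) + 0.5 * b[i] * np.log(b[i] / m[i])
    return np.sqrt(jsd)


class TestRootJSD:
    def test_identity(self):
        p = np.array([0.1, 0.6, 0.3])
        assert ek.jsd_metric(p, p) == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_support_near_sqrt_log2(self):
        d = ek.jsd_metric([1.0, 0.0], [0.0, 1.0])
        assert d == pytest.approx(np.sqrt(np.log(2)), abs=1e-3)
        assert d <= np.sqrt(np.log(2)) + 1e-12  # root-JSD upper bound

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            a = rng.dirichlet(np.ones(10))
            b = rng.dirichlet(np.ones(10))
            assert ek.jsd_metric(a, b) == pytest.approx(
                brute_force_jsd(a, b), abs=1e-12
            )

    def test_triangle_inequality_on_random_triples(self):
        rng = np.random.default_rng(1)
        P = random_profiles(rng, 3000, 6)
        for a, b, c in P.reshape(1000, 3, 6):
            dab = ek.jsd_metric(a, b)
            dbc = ek.jsd_metric(b, c)
            dac = ek.jsd_metric(a, c)
            assert dac <= dab + dbc + 1e-12

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = random_profiles(rng, 2, 12)
        assert ek.jsd_metric(a, b) == pytest.approx(ek.jsd_metric(b, a), abs=1e-15)

    def test_pseudocount_keeps_profiles_on_simplex(self):
        p = _pseudocounted(np.array([0.5, 0.5, 0.0]), 1e-6)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert (p > 0).all()


class TestBrayCurtisJaccard:
    def test_bray_curtis_values(self):
        assert ek.bray_curtis([2, 2], [2, 2]) == 0.0
        assert ek.bray_curtis([6, 2], [2, 2]) == pytest.approx(1 / 3)

    def test_binary_jaccard_sets(self):
        # presence {A,B} vs {B,C}: intersection 1, union 3
        assert ek.binary_jaccard([1, 1, 0], [0, 1, 1]) == pytest.approx(2 / 3)

    @pytest.mark.parametrize("seed", range(5))
    def test_match_scipy(self, seed):
        from scipy.spatial.distance import braycurtis, jaccard

        rng = np.random.default_rng(seed)
        for _ in range(20):
            a = rng.integers(0, 5, size=10).astype(float)
            b = rng.integers(0, 5, size=10).astype(float)
            if (a + b).sum() == 0:
                continue
            assert ek.bray_curtis(a, b) == pytest.approx(braycurtis(a, b), abs=1e-12)
            assert ek.binary_jaccard(a, b) == pytest.approx(
                jaccard(a > 0, b > 0), abs=1e-12
            )

    def test_all_zero_pair_rejected(self):
        with pytest.raises(ValueError):
            ek.bray_curtis([0, 0], [0, 0])
        with pytest.raises(ValueError):
            ek.binary_jaccard([0, 0], [0, 0])


class TestUniFrac:
    def skbio_tree(self, tree):
        return skbio.TreeNode.read(_io.StringIO(tree_to_newick(tree)))

    def test_identical_samples_zero(self):
        taxa = [f"t{i}" for i in range(6)]
        tree = ek.generate_tree(taxa, seed=0)
        a = np.array([3, 1, 0, 2, 0, 5], dtype=float)
        assert ek.unweighted_unifrac(a, a, tree, taxa) == pytest.approx(0.0)
        assert ek.weighted_unifrac(a, a, tree, taxa) == pytest.approx(0.0)

    def test_disjoint_on_star_tree_is_one(self):
        tree = skbio.TreeNode.read(_io.StringIO("(A:1,B:1,C:1,D:1):0;"))
        a = np.array([1, 1, 0, 0], dtype=float)
        b = np.array([0, 0, 1, 1], dtype=float)
        assert ek.unweighted_unifrac(a, b, tree, list("ABCD")) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_skbio_reference(self, seed):
        from skbio.diversity import beta_diversity

        rng = np.random.default_rng(seed)
        taxa = [f"t{i}" for i in range(rng.integers(4, 15))]
        tree = ek.generate_tree(taxa, seed=seed + 100)
        table = random_table(rng, n=5, t=len(taxa))
        table.columns = taxa
        table.iloc[0, : len(taxa) // 2] = 0
        table += (table.sum(axis=1) == 0).to_numpy()[:, None]  # no empty samples
        sk = self.skbio_tree(tree)
        ref_u = beta_diversity(
            "unweighted_unifrac", table.to_numpy(), taxa=taxa, tree=sk
        ).data
        ref_w = beta_diversity(
            "weighted_unifrac", table.to_numpy(), taxa=taxa, tree=sk
        ).data
        mine_u = ek.pairwise(table, "unifrac-u", tree=tree).data
        mine_w = ek.pairwise(table, "unifrac-w", tree=tree).data
        np.testing.assert_allclose(mine_u, ref_u, atol=1e-9)
        np.testing.assert_allclose(mine_w, ref_w, atol=1e-9)

    def test_missing_taxon_rejected(self):
        tree = ek.generate_tree(["A", "B"], seed=0)
        with pytest.raises(ValueError, match="missing from tree"):
            ek.unweighted_unifrac([1, 1], [1, 0], tree, ["A", "Z"])


class TestPairwise:
    def test_identical_samples_zero_matrix(self):
        table = random_table(np.random.default_rng(0), n=1, t=8)
        table = table.loc[table.index.repeat(3)]
        table.index = ["a", "b", "c"]
        for metric in ("jsd", "braycurtis", "jaccard"):
            assert np.all(ek.pairwise(table + 1, metric).data == 0)

    @pytest.mark.parametrize("metric", ["jsd", "braycurtis", "jaccard"])
    def test_matches_scalar_loop(self, metric):
        rng = np.random.default_rng(3)
        table = random_table(rng, n=10, t=7) + 1
        dm = ek.pairwise(table, metric)
        scalar = {
            "jsd": ek.jsd_metric,
            "braycurtis": ek.bray_curtis,
            "jaccard": ek.binary_jaccard,
        }[metric]
        X = table.to_numpy(dtype=float)
        for i in range(10):
            for j in range(10):
                if i != j:
                    assert dm.data[i, j] == pytest.approx(scalar(X[i], X[j]), abs=1e-12)

    def test_matrix_invariants_on_larger_table(self, small_rel):
        rel, _, _ = small_rel
        dm = ek.pairwise(rel.iloc[:100], "jsd")
        D = dm.data
        assert np.abs(D - D.T).max() < 1e-12
        assert np.all(np.diag(D) == 0)
        assert np.isfinite(D).all() and (D >= 0).all()

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            ek.pairwise(random_table(np.random.default_rng(0), n=1), "jsd")

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError, match="unknown metric"):
            ek.pairwise(random_table(np.random.default_rng(0)), "euclid")


@settings(deadline=None, max_examples=60)
@given(st.data())
def test_metric_axioms_property(data):
    """d(a,a)=0, symmetry, non-negativity for every abundance metric."""
    t = data.draw(st.integers(3, 8))
    vecs = data.draw(
        st.lists(
            st.lists(st.integers(0, 20), min_size=t, max_size=t), min_size=2, max_size=2
        )
    )
    a, b = (np.array(v, dtype=float) + 0.5 for v in vecs)  # avoid all-zero
    for fn in (ek.jsd_metric, ek.bray_curtis, ek.binary_jaccard):
        assert fn(a, a) == pytest.approx(0.0, abs=1e-9)
        assert fn(a, b) == pytest.approx(fn(b, a), abs=1e-12)
        assert fn(a, b) >= -1e-12
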