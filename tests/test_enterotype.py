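"""Enterotyping protocol: top-taxon selection, PAM optimality and
determinism, CH index behaviour, k-selection, silhouette and driver
recovery on planted structure."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import enterokit as ek
from enterokit.enterotype import (
    CHCurve,
    ch_index,
    enterotype_pipeline,
    pam,
    scan_k,
    select_top_taxa,
    silhouette,
)


def blob_distance(sizes, spread=0.05, gap=5.0, seed=0, dim=2):
    """Euclidean distances for well-separated Gaussian blobs."""
    rng = np.random.default_rng(seed)
    pts, labels = [], []
    for g, size in enumerate(sizes):
        centre = np.zeros(dim)
        centre[0] = g * gap
        pts.append(centre + spread * rng.normal(size=(size, dim)))
        labels += [g] * size
    return squareform(pdist(np.vstack(pts))), np.array(labels)


class TestSelectTopTaxa:
    def test_keeps_requested_count(self, small_rel):
        rel, _, _ = small_rel
        out = select_top_taxa(rel, n=35)
        assert out.shape[1] == 35

    def test_identity_when_n_equals_taxa(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.dirichlet(np.ones(6), size=4))
        table.columns = [f"t{j}" for j in range(6)]
        table.index = [f"s{i}" for i in range(4)]
        assert select_top_taxa(table, n=6).equals(table)

    def test_matches_brute_force_column_mean_sort(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(
            rng.dirichlet(np.ones(20), size=15),
            index=[f"s{i}" for i in range(15)],
            columns=[f"t{j}" for j in range(20)],
        )
        out = select_top_taxa(table, n=7)
        expected = set(table.mean(axis=0).sort_values(ascending=False).index[:7])
        assert set(out.columns) == expected

    def test_rows_not_renormalised(self, small_rel):
        rel, _, _ = small_rel
        out = select_top_taxa(rel, n=10)
        assert (out.sum(axis=1) < 1.0).all()

    def test_too_few_taxa_rejected(self):
        table = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("xyz"))
        with pytest.raises(ValueError, match="fewer"):
            select_top_taxa(table, n=5)


class TestPAM:
    def test_two_blobs_recovered_with_zero_spread(self):
        D, truth = blob_distance([4, 4], spread=0.0)
        labels, medoids, cost = pam(D, 2)
        assert cost == pytest.approx(0.0, abs=1e-12)
        assert len(set(zip(labels, truth))) == 2  # one-to-one label match

    def test_k_equals_n_zero_cost(self):
        D, _ = blob_distance([3, 3])
        labels, medoids, cost = pam(D, 6)
        assert cost == 0.0
        assert sorted(labels) == list(range(6))

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_exhaustive_on_clusterable_toys(self, seed):
        D, _ = blob_distance([4, 4], spread=0.4, gap=3.0, seed=seed)
        _, _, cost = pam(D, 2)
        best = min(
            D[:, list(m)].min(axis=1).sum() for m in itertools.combinations(range(8), 2)
        )
        assert cost == pytest.approx(best, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_local_optimum_no_improving_swap(self, seed):
        """On arbitrary instances PAM guarantees a swap-local optimum."""
        rng = np.random.default_rng(seed)
        D = squareform(pdist(rng.normal(size=(9, 3))))
        labels, medoid_ids, cost = pam(D, 3)
        medoids = [int(m) for m in medoid_ids]
        for mi in range(3):
            for h in range(9):
                if h in medoids:
                    continue
                trial = list(medoids)
                trial[mi] = h
                assert D[:, trial].min(axis=1).sum() >= cost - 1e-12

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        D = squareform(pdist(rng.normal(size=(20, 4))))
        assert np.array_equal(pam(D, 3)[0], pam(D, 3)[0])
        assert pam(D, 3)[1] == pam(D, 3)[1]

    def test_k_out_of_range_rejected(self):
        D, _ = blob_distance([3, 3])
        with pytest.raises(ValueError, match="out of range"):
            pam(D, 0)
        with pytest.raises(ValueError, match="out of range"):
            pam(D, 7)

    def test_kmedoids_estimator_api(self):
        D, truth = blob_distance([5, 5], spread=0.1)
        est = ek.KMedoids(n_clusters=2).fit(D)
        assert est.labels_.shape == (10,)
        assert len(est.medoid_indices_) == 2
        assert est.inertia_ >= 0
        # medoids belong to their own clusters
        for m in est.medoid_indices_:
            assert est.labels_[m] in est.labels_
        params = est.get_params()
        assert params["n_clusters"] == 2


class TestCHIndex:
    def test_planted_blobs_beat_random_relabelings(self):
        D, truth = blob_distance([6, 6], spread=0.2)
        good = ch_index(D, truth)
        rng = np.random.default_rng(0)
        for _ in range(20):
            assert good > ch_index(D, rng.permutation(truth))

    def test_random_labels_on_iid_points_near_one(self):
        rng = np.random.default_rng(1)
        values = []
        for _ in range(200):
            D = squareform(pdist(rng.normal(size=(16, 3))))
            labels = rng.integers(0, 2, size=16)
            if len(set(labels)) < 2:
                continue
            values.append(ch_index(D, labels))
        assert abs(np.mean(values) - 1.0) < 0.15

    def test_single_cluster_rejected(self):
        D, _ = blob_distance([4])
        with pytest.raises(ValueError, match="single cluster"):
            ch_index(D, [0, 0, 0, 0])

    def test_label_permutation_invariance(self):
        D, truth = blob_distance([5, 4], spread=0.3)
        assert ch_index(D, truth) == pytest.approx(ch_index(D, 1 - truth), abs=1e-9)

    def test_pcoa_variant_agrees_in_euclidean_space(self):
        """On Euclidean data the distance form equals the centroid form up
        to the n/k normalisation conventions — both must prefer the truth."""
        D, truth = blob_distance([6, 6], spread=0.2, seed=3)
        rng = np.random.default_rng(0)
        rand = rng.permutation(truth)
        assert ch_index(D, truth, method="pcoa") > ch_index(D, rand, method="pcoa")


class TestScanK:
    def test_two_planted_blobs_argmax_two(self):
        D, _ = blob_distance([8, 8], spread=0.3)
        curve, _ = scan_k(D, k_min=2, k_max=6)
        assert curve.argmax_k == 2
        assert np.isfinite(curve.ch).all()

    def test_three_planted_blobs_argmax_three(self):
        D, _ = blob_distance([7, 7, 7], spread=0.2)
        curve, _ = scan_k(D, k_min=2, k_max=6)
        assert curve.argmax_k == 3

    def test_bad_range_rejected(self):
        D, _ = blob_distance([3, 3])
        with pytest.raises(ValueError, match="k_min"):
            scan_k(D, k_min=2, k_max=6)


class TestSilhouette:
    def test_tight_distant_blobs_near_one(self):
        D, truth = blob_distance([6, 6], spread=0.01, gap=10.0)
        assert silhouette(D, truth) > 0.95

    def test_random_labels_near_zero(self):
        rng = np.random.default_rng(2)
        vals = []
        for _ in range(100):
            D = squareform(pdist(rng.normal(size=(14, 3))))
            vals.append(silhouette(D, rng.integers(0, 2, size=14)))
        assert abs(np.mean(vals)) < 0.05

    def test_bounded(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            D = squareform(pdist(rng.normal(size=(10, 2))))
            s = silhouette(D, rng.integers(0, 3, size=10))
            assert -1.0 <= s <= 1.0

    def test_matches_sklearn(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(4)
        for _ in range(20):
            D = squareform(pdist(rng.normal(size=(12, 3))))
            labels = rng.integers(0, 3, size=12)
            if len(set(labels)) < 2:
                continue
            assert silhouette(D, labels) == pytest.approx(
                silhouette_score(D, labels, metric="precomputed"), abs=1e-9
            )

    def test_label_permutation_invariance(self):
        D, truth = blob_distance([5, 5], spread=0.2)
        assert silhouette(D, truth) == pytest.approx(silhouette(D, 1 - truth), abs=1e-12)

    def test_single_cluster_rejected(self):
        D, _ = blob_distance([4])
        with pytest.raises(ValueError, match="single cluster"):
            silhouette(D, [0] * 4)


class TestDrivers:
    def test_planted_drivers_recovered(self, small_rel):
        rel, _, labels = small_rel
        drivers = ek.assign_driver_taxa(rel, labels)
        assert {t for t, _ in drivers.values()} == {"Bacteroides", "Prevotella"}

    def test_single_cluster_overall_top_genus(self, small_rel):
        rel, _, _ = small_rel
        drivers = ek.assign_driver_taxa(rel, np.zeros(rel.shape[0], dtype=int))
        assert drivers[0][0] == rel.mean(axis=0).idxmax()

    def test_singleton_cluster_top_genus(self):
        table = pd.DataFrame(
            [[0.7, 0.3], [0.2, 0.8]], index=["a", "b"], columns=["x", "y"]
        )
        drivers = ek.assign_driver_taxa(table, [0, 1])
        assert drivers[0] == ("x", 0.7)
        assert drivers[1] == ("y", 0.8)


class TestFullProtocol:
    def test_two_enterotype_cohort(self, small_rel):
        from sklearn.metrics import adjusted_rand_score

        rel, _, truth = small_rel
        res = enterotype_pipeline(rel, seed=0)
        assert res.best_k == 2
        assert adjusted_rand_score(truth, res.labels.to_numpy()) > 0.9
        names = {t for t, _ in res.driver_taxa.values()}
        assert names == {"Bacteroides", "Prevotella"}
        assert sum(res.cluster_sizes.values()) == rel.shape[0]
        assert -1 <= res.silhouette <= 1
        assert not res.weak_structure
        # medoids belong to their own clusters
        for g, mid in enumerate(res.medoid_ids):
            assert res.labels.loc[mid] == g

    def test_single_component_negative_control(self):
        """One enterotype only: silhouette near zero at k=2, flagged weak."""
        from tests.test_synth import one_cluster_spec

        spec = one_cluster_spec(150, 60, ek.default_cohort_spec(n_taxa=60)
                                .dirichlet_concentrations[0], seed=9,
                                depth=(2000, 5000))
        table, _, _ = ek.generate_cohort(spec)
        rel = ek.to_relative(table)
        res = enterotype_pipeline(rel, seed=0)
        assert res.silhouette < 0.15
        assert res.weak_structure

    def test_determinism(self, small_rel):
        rel, _, _ = small_rel
        a = enterotype_pipeline(rel, seed=3)
        b = enterotype_pipeline(rel, seed=3)
        assert a.labels.equals(b.labels)
        assert a.medoid_ids == b.medoid_ids
        assert a.ch_curve.ch == b.ch_curve.ch
        assert a.silhouette == b.silhouette

    def test_estimator_interface(self, small_rel):
        rel, _, _ = small_rel
        est = ek.Enterotyper(n_clusters=2).fit(rel)
        assert est.best_k_ == 2
        assert len(est.labels_) == rel.shape[0]
        cloned_params = est.get_params()
        assert cloned_params["top_n"] == 35


def test_ch_curve_container():
    curve = CHCurve([2, 3, 4], [10.0, 5.0, 3.0])
    assert curve.argmax_k == 2
    assert list(curve.to_frame()["ch"]) == [10.0, 5.0, 3.0]
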