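"""Supertype classification: features, distances, Ward, k choice, PCA."""
import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster

from famsel.supertypes import (PBR_SITES, SupertypeClassifier, Z_SCALES,
                               assign_supertypes, build_feature_matrix,
                               choose_k, euclidean_distances,
                               site_influence_pca, standardized_z_table,
                               ward_cluster)
from famsel.types import Locus

from conftest import planted_group_sequences, synthetic_sequence


def test_pbr_site_lists():
    assert len(PBR_SITES[Locus.DRB1]) == 19
    assert len(PBR_SITES[Locus.DQB1]) == 15
    assert len(PBR_SITES[Locus.DQA1]) == 10
    for sites in PBR_SITES.values():
        assert list(sites) == sorted(sites)


def test_standardized_z_table_mean_zero_sd_one():
    table = standardized_z_table()
    vals = np.array([table[aa] for aa in sorted(Z_SCALES)])
    assert np.allclose(vals.mean(axis=0), 0, atol=1e-9)
    assert np.allclose(vals.std(axis=0), 1, atol=1e-9)


class TestBuildFeatureMatrix:
    def test_single_polymorphic_site_gives_five_columns(self):
        seqs = [synthetic_sequence(Locus.DRB1, "a1", {9: "L"}),
                synthetic_sequence(Locus.DRB1, "a2", {9: "F"})]
        X, poly = build_feature_matrix(seqs, PBR_SITES[Locus.DRB1])
        assert X.shape == (2, 5)
        assert poly == [9]

    def test_all_monomorphic_is_an_error(self):
        seqs = [synthetic_sequence(Locus.DQA1, f"q{i}", {}) for i in range(3)]
        with pytest.raises(ValueError, match="no polymorphic sites"):
            build_feature_matrix(seqs, PBR_SITES[Locus.DQA1])

    def test_non_canonical_residue_named(self):
        seqs = [synthetic_sequence(Locus.DRB1, "a1", {9: "X"}),
                synthetic_sequence(Locus.DRB1, "a2", {9: "F"})]
        with pytest.raises(ValueError, match="a1"):
            build_feature_matrix(seqs, PBR_SITES[Locus.DRB1])

    def test_column_count_scales_with_polymorphic_sites(self):
        seqs = [synthetic_sequence(Locus.DQB1, "b1", {9: "L", 13: "A"}),
                synthetic_sequence(Locus.DQB1, "b2", {9: "F", 13: "R"})]
        X, poly = build_feature_matrix(seqs, PBR_SITES[Locus.DQB1])
        assert X.shape == (2, 10) and poly == [9, 13]


class TestEuclideanDistances:
    def test_metric_properties_and_345(self):
        m = np.array([[0.0, 0.0], [3.0, 4.0]])
        d = euclidean_distances(m)
        assert d[0, 0] == d[1, 1] == 0
        assert d[0, 1] == d[1, 0] == pytest.approx(5.0)

    def test_matches_double_loop_recomputation(self, rng):
        m = rng.normal(size=(10, 6))
        d = euclidean_distances(m)
        for i in range(10):
            for j in range(10):
                ref = np.sqrt(np.sum((m[i] - m[j]) ** 2))
                assert abs(d[i, j] - ref) < 1e-10


def exhaustive_ward(points):
    """Oracle: greedy Ward agglomeration computed from raw coordinates.

    At each step merge the pair of clusters with the smallest increase in
    total within-cluster sum of squares; returns the merge-cost sequence
    (ward.D2 scale: sqrt(2 * delta SSE)).
    """
    clusters = [[i] for i in range(len(points))]
    heights = []
    pts = np.asarray(points, float)

    def sse(idx):
        sub = pts[idx]
        return float(((sub - sub.mean(axis=0)) ** 2).sum())

    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            delta = (sse(clusters[a] + clusters[b]) - sse(clusters[a])
                     - sse(clusters[b]))
            if best is None or delta < best[0] - 1e-12:
                best = (delta, a, b)
        delta, a, b = best
        heights.append(np.sqrt(2 * delta))
        merged = clusters[a] + clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)
    return np.array(heights)


class TestWardCluster:
    def test_coincident_pair_merges_first_at_zero(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0]])
        Z = ward_cluster(euclidean_distances(pts))
        assert Z[0, 2] == pytest.approx(0.0)
        assert set(Z[0, :2].astype(int)) == {0, 1}

    def test_two_tight_pairs_far_apart(self):
        pts = np.array([[0, 0], [0, 0.1], [10, 10], [10, 10.1]], float)
        Z = ward_cluster(euclidean_distances(pts))
        assert Z[-1, 2] > 50 * max(Z[0, 2], Z[1, 2])

    def test_matches_exhaustive_ward_on_small_point_sets(self, rng):
        for _ in range(5):
            pts = rng.normal(size=(8, 3))
            Z = ward_cluster(euclidean_distances(pts))
            ref = exhaustive_ward(pts)
            assert np.allclose(np.sort(Z[:, 2]), np.sort(ref), atol=1e-8)

    def test_planted_blobs_recovered_at_k2(self, rng):
        pts = np.vstack([rng.normal(0, 0.1, size=(4, 2)),
                         rng.normal(8, 0.1, size=(4, 2))])
        Z = ward_cluster(euclidean_distances(pts))
        labels = fcluster(Z, t=2, criterion="maxclust")
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[4]

    def test_legacy_variant_monotone_and_distinct(self, rng):
        pts = rng.normal(size=(6, 2))
        d = euclidean_distances(pts)
        Zd = ward_cluster(d, variant="D")
        Zd2 = ward_cluster(d, variant="D2")
        assert np.all(np.diff(Zd[:, 2]) >= -1e-9)
        assert not np.allclose(Zd[:, 2], Zd2[:, 2])


class TestChooseK:
    def test_jump_at_final_merge_gives_two(self):
        h = list(np.linspace(0.1, 1.0, 17)) + [1.1, 9.0]
        assert choose_k(h) == 2

    def test_geometric_heights_warn_and_override_honoured(self):
        h = [1.05 ** i for i in range(19)]
        with pytest.warns(UserWarning, match="weakly determined"):
            choose_k(h)
        assert choose_k(h, override=4) == 4

    def test_equal_heights_give_one_with_warning(self):
        with pytest.warns(UserWarning, match="k=1"):
            assert choose_k([1.0, 1.0, 1.0]) == 1

    def test_planted_three_blobs(self, rng):
        pts = np.vstack([rng.normal(c, 0.05, size=(5, 2))
                         for c in (0, 5, 11)])
        Z = ward_cluster(euclidean_distances(pts))
        assert choose_k(Z[:, 2]) == 3


class TestAssignSupertypes:
    def setup_method(self):
        self.rng = np.random.default_rng(3)
        pts = np.vstack([self.rng.normal(c, 0.05, size=(4, 2))
                         for c in (0, 6)])
        self.names = [f"a{i}" for i in range(8)]
        self.Z = ward_cluster(euclidean_distances(pts))

    def test_k_extremes(self):
        assert set(assign_supertypes(self.names, self.Z, 1).values()) == {1}
        singletons = assign_supertypes(self.names, self.Z, 8)
        assert sorted(singletons.values()) == list(range(1, 9))

    def test_classes_labelled_by_size_rank(self):
        pts = np.vstack([np.zeros((5, 2)), np.full((2, 2), 9.0)])
        Z = ward_cluster(euclidean_distances(pts))
        classes = assign_supertypes([f"a{i}" for i in range(7)], Z, 2)
        assert [classes[f"a{i}"] for i in range(7)] == [1] * 5 + [2] * 2


class TestSiteInfluencePca:
    def test_single_site_holds_all_influence(self):
        seqs = [synthetic_sequence(Locus.DRB1, "a1", {9: "L"}),
                synthetic_sequence(Locus.DRB1, "a2", {9: "F"})]
        X, poly = build_feature_matrix(seqs, PBR_SITES[Locus.DRB1])
        df, evr = site_influence_pca(X, poly)
        assert df.influence.iloc[0] == pytest.approx(df.influence.sum())
        assert df.codon_position.iloc[0] == 9

    def test_high_variance_site_ranks_first(self, rng):
        # site 9 varies over many residues, site 13 over two similar ones
        residues9 = ["A", "R", "W", "D", "K", "F", "G", "H"]
        seqs = [synthetic_sequence(
            Locus.DRB1, f"a{i}", {9: residues9[i], 13: "IL"[i % 2]})
            for i in range(8)]
        X, poly = build_feature_matrix(seqs, PBR_SITES[Locus.DRB1])
        df, _ = site_influence_pca(X, poly)
        assert df.codon_position.iloc[0] == 9

    def test_few_components_warns(self):
        seqs = [synthetic_sequence(Locus.DRB1, "a1", {9: "L"}),
                synthetic_sequence(Locus.DRB1, "a2", {9: "F"})]
        X, poly = build_feature_matrix(seqs, PBR_SITES[Locus.DRB1])
        with pytest.warns(UserWarning, match="informative principal"):
            site_influence_pca(X, poly, n_components=3)


class TestSupertypeClassifierPipeline:
    def test_recovers_planted_partition_and_is_order_invariant(self, rng):
        seqs, labels = planted_group_sequences(
            Locus.DRB1, PBR_SITES[Locus.DRB1], n_groups=3, per_group=6,
            rng=rng)
        clf = SupertypeClassifier().fit(seqs)
        assert clf.k_ == 3
        # partition equality up to relabelling
        mapping = {}
        for lab, true in zip(clf.labels_, labels):
            mapping.setdefault(true, lab)
            assert mapping[true] == lab
        # permutation invariance
        perm = rng.permutation(len(seqs))
        clf2 = SupertypeClassifier().fit([seqs[i] for i in perm])
        got = {seqs[i].allele.name: clf2.classes_map_[seqs[i].allele.name]
               for i in range(len(seqs))}
        remap = {}
        for name, cls in got.items():
            orig = clf.classes_map_[name]
            remap.setdefault(orig, cls)
            assert remap[orig] == cls

    def test_identical_pbr_alleles_always_cocluster(self, rng):
        seqs, _ = planted_group_sequences(
            Locus.DQB1, PBR_SITES[Locus.DQB1], n_groups=2, per_group=4,
            rng=rng)
        twin = synthetic_sequence(
            Locus.DQB1, "twin",
            {p: seqs[0].residue(p) for p in PBR_SITES[Locus.DQB1]})
        clf = SupertypeClassifier(k=4).fit(seqs + [twin])
        assert clf.classes_map_["twin"] == clf.classes_map_[
            seqs[0].allele.name]

    def test_predict_by_pbr_match_and_unseen_error(self, rng):
        seqs, _ = planted_group_sequences(
            Locus.DRB1, PBR_SITES[Locus.DRB1], n_groups=2, per_group=3,
            rng=rng)
        clf = SupertypeClassifier().fit(seqs)
        novel = synthetic_sequence(
            Locus.DRB1, "novel",
            {p: seqs[-1].residue(p) for p in PBR_SITES[Locus.DRB1]})
        assert clf.predict([novel])[0] == clf.classes_map_[
            seqs[-1].allele.name]
        alien = synthetic_sequence(Locus.DRB1, "alien",
                                   {p: "C" for p in PBR_SITES[Locus.DRB1]})
        with pytest.raises(ValueError, match="unseen PBR"):
            clf.predict([alien])

    def test_sklearn_param_interface(self):
        clf = SupertypeClassifier(k=5)
        assert clf.get_params()["k"] == 5
        clf.set_params(variant="D")
        assert clf.variant == "D"
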