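import numpy as np
import pandas as pd
import pytest

from seriesbin import community_profile as cp
from seriesbin.features import CoverageTable

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng, n=220):
    return "".join(rng.choice(list(AA20), size=n))


class TestClusterSpecies:
    def test_identical_sequences_form_one_cluster(self, rng):
        seq = random_protein(rng)
        clusters, excluded = cp.cluster_species({f"q{i}": seq for i in range(5)})
        assert len(clusters) == 1
        assert sorted(clusters[0].member_ids) == [f"q{i}" for i in range(5)]
        assert excluded == []

    def test_five_mismatches_in_200_split_at_99(self, rng):
        a = random_protein(rng, 200)
        b = list(a)
        for pos in (10, 50, 90, 130, 170):
            b[pos] = "W" if a[pos] != "W" else "Y"
        clusters, _ = cp.cluster_species({"a": a, "b": "".join(b)})
        # identity 195/200 = 97.5% < 99%
        assert len(clusters) == 2

    def test_two_mismatches_in_220_merge_at_99(self, rng):
        a = random_protein(rng)
        b = list(a)
        b[7] = "W" if a[7] != "W" else "Y"
        clusters, _ = cp.cluster_species({"a": a, "b": "".join(b)})
        # identity 219/220 = 99.5% >= 99%
        assert len(clusters) == 1

    def test_half_length_fragment_excluded(self, rng):
        a = random_protein(rng)
        fragment = a[55:165]  # 110 of 220 columns -> span 0.5 < 0.6
        clusters, excluded = cp.cluster_species({"full": a, "frag": fragment})
        assert [c.centroid_id for c in clusters] == ["full"]
        assert excluded == ["frag"]

    def test_seventy_percent_fragment_joins(self, rng):
        a = random_protein(rng)
        fragment = a[: int(0.7 * len(a))]
        clusters, excluded = cp.cluster_species({"full": a, "frag": fragment})
        assert len(clusters) == 1
        assert excluded == []
        assert sorted(clusters[0].member_ids) == ["frag", "full"]

    def test_identity_one_keeps_distinct_sequences_apart(self, rng):
        seqs = {f"q{i}": random_protein(rng) for i in range(4)}
        clusters, _ = cp.cluster_species(seqs, identity=1.0)
        assert len(clusters) == 4

    def test_tiny_identity_threshold_merges_everything(self, rng):
        seqs = {f"q{i}": random_protein(rng) for i in range(4)}
        clusters, _ = cp.cluster_species(seqs, identity=1e-6)
        assert len(clusters) == 1

    def test_empty_input(self):
        assert cp.cluster_species({}) == ([], [])

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            cp.cluster_species({"a": "MKV"}, identity=0.0)
        with pytest.raises(ValueError):
            cp.cluster_species({"a": "MKV"}, span=1.5)

    def test_synthetic_rps3_recovers_genomes(self, small_community):
        rps3 = small_community["rps3"]
        clusters, excluded = cp.cluster_species(rps3)
        # default divergence keeps every genome its own species
        assert len(clusters) == len(rps3)
        assert excluded == []


def toy_clusters():
    return [
        cp.SpeciesCluster("cluster_0001", "r1", ["r1"]),
        cp.SpeciesCluster("cluster_0002", "r2", ["r2", "r3"]),
    ]


def toy_coverage():
    return CoverageTable(
        pd.DataFrame(
            {"s1": [40.0, 3.0, 7.0], "s2": [8.0, 1.0, 1.0]},
            index=["scafA", "scafB", "scafC"],
        ),
        normalized=True,
    )


SEQ2SCAF = {"r1": "scafA", "r2": "scafB", "r3": "scafC"}


class TestAbundanceTable:
    def test_columns_sum_to_100(self):
        table = cp.abundance_table(toy_clusters(), toy_coverage(), SEQ2SCAF)
        np.testing.assert_allclose(table.values.sum(axis=0), [100.0, 100.0])

    def test_worked_two_scaffold_cluster(self):
        # cluster_0002 holds coverages 3 and 7 of a 50 total -> 20%
        table = cp.abundance_table(toy_clusters(), toy_coverage(), SEQ2SCAF)
        assert table.values.loc["cluster_0002", "s1"] == pytest.approx(20.0)
        assert table.values.loc["cluster_0001", "s1"] == pytest.approx(80.0)

    def test_single_cluster_is_total_community(self):
        clusters = [cp.SpeciesCluster("cluster_0001", "r1", ["r1"])]
        table = cp.abundance_table(clusters, toy_coverage(), SEQ2SCAF)
        np.testing.assert_allclose(table.values.to_numpy(), [[100.0, 100.0]])

    def test_unmapped_cluster_rejected(self):
        clusters = [cp.SpeciesCluster("cluster_0001", "nope", ["nope"])]
        with pytest.raises(ValueError, match="no coverage-mapped scaffold"):
            cp.abundance_table(clusters, toy_coverage(), SEQ2SCAF)

    def test_taxon_labels_follow_centroid(self):
        table = cp.abundance_table(
            toy_clusters(), toy_coverage(), SEQ2SCAF,
            taxa={"r1": "Acidobacteria", "r2": "Chloroflexi"},
        )
        assert table.taxon == {
            "cluster_0001": "Acidobacteria",
            "cluster_0002": "Chloroflexi",
        }


class TestPhylumRollup:
    def test_identity_partition(self):
        table = cp.AbundanceTable(
            values=pd.DataFrame(
                {"s1": [60.0, 40.0]}, index=["cluster_0001", "cluster_0002"]
            ),
            taxon={"cluster_0001": "A", "cluster_0002": "B"},
        )
        rolled = cp.phylum_rollup(table)
        np.testing.assert_allclose(np.sort(rolled["s1"].to_numpy()), [40.0, 60.0])

    def test_same_phylum_sums(self):
        table = cp.AbundanceTable(
            values=pd.DataFrame(
                {"s1": [10.0, 15.0, 75.0]},
                index=["c1", "c2", "c3"],
            ),
            taxon={"c1": "Gemmatimonadetes", "c2": "Gemmatimonadetes", "c3": "Rokubacteria"},
        )
        rolled = cp.phylum_rollup(table)
        assert rolled.loc["Gemmatimonadetes", "s1"] == pytest.approx(25.0)

    def test_column_sums_preserved_and_unlabeled_warns(self):
        table = cp.AbundanceTable(
            values=pd.DataFrame({"s1": [30.0, 70.0]}, index=["c1", "c2"]),
            taxon={"c1": "A"},
        )
        with pytest.warns(UserWarning, match="Unclassified"):
            rolled = cp.phylum_rollup(table)
        assert rolled["s1"].sum() == pytest.approx(100.0)
        assert "Unclassified" in rolled.index


class TestBrayCurtis:
    def test_identical_columns_distance_zero(self):
        df = pd.DataFrame({"s1": [1.0, 2.0], "s2": [1.0, 2.0]})
        assert cp.bray_curtis_matrix(df).loc["s1", "s2"] == 0.0

    def test_disjoint_supports_distance_one(self):
        df = pd.DataFrame({"s1": [5.0, 0.0], "s2": [0.0, 3.0]})
        assert cp.bray_curtis_matrix(df).loc["s1", "s2"] == 1.0

    def test_hand_worked_value(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [3.0, 2.0, 1.0]})
        assert cp.bray_curtis_matrix(df).loc["a", "b"] == pytest.approx(1 / 3)

    def test_matches_scipy_on_random_data(self, rng):
        from scipy.spatial.distance import braycurtis

        df = pd.DataFrame(
            rng.uniform(0, 10, size=(12, 5)), columns=[f"s{j}" for j in range(5)]
        )
        d = cp.bray_curtis_matrix(df)
        for i in range(5):
            for j in range(5):
                expected = 0.0 if i == j else braycurtis(df.iloc[:, i], df.iloc[:, j])
                assert d.iloc[i, j] == pytest.approx(expected)

    def test_symmetry_range_and_diagonal(self, rng):
        df = pd.DataFrame(rng.uniform(0, 1, size=(20, 6)))
        d = cp.bray_curtis_matrix(df).to_numpy()
        assert (d >= 0).all() and (d <= 1).all()
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0)

    def test_all_zero_pair_warns_and_is_zero(self):
        df = pd.DataFrame({"s1": [0.0, 0.0], "s2": [0.0, 0.0]})
        with pytest.warns(UserWarning, match="all-zero"):
            d = cp.bray_curtis_matrix(df)
        assert d.loc["s1", "s2"] == 0.0

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            cp.bray_curtis_matrix(pd.DataFrame({"s1": [-1.0], "s2": [1.0]}))


class TestPcoa:
    def test_all_zero_distances_collapse_to_origin(self):
        res = cp.pcoa(np.zeros((4, 4)), k=2)
        np.testing.assert_allclose(res.coordinates.to_numpy(), 0.0)

    def test_planar_points_reconstructed(self, rng):
        pts = rng.uniform(-3, 3, size=(4, 2))
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        res = cp.pcoa(d, k=2)
        xy = res.coordinates.to_numpy()
        recon = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=2)
        np.testing.assert_allclose(recon, d, atol=1e-8)

    def test_proportions_bounded(self, rng):
        x = rng.uniform(0, 5, size=(8, 10))
        d = cp.bray_curtis_matrix(pd.DataFrame(x.T)).to_numpy()
        res = cp.pcoa(d, k=4)
        assert res.proportion_explained.sum() <= 1.0 + 1e-12
        assert (res.eigenvalues > 0).all()

    def test_matches_scikit_bio_ordination(self, rng):
        """Cross-check coordinates against an independent PCoA implementation."""
        skbio_pcoa = pytest.importorskip("skbio.stats.ordination").pcoa

        x = rng.uniform(0, 5, size=(10, 7))
        d = cp.bray_curtis_matrix(pd.DataFrame(x.T))
        ours = cp.pcoa(d, k=2).coordinates.to_numpy()
        theirs = skbio_pcoa(d.to_numpy(), number_of_dimensions=2).samples.to_numpy()
        for axis in range(2):
            dot = np.dot(ours[:, axis], theirs[:, axis])
            sign = 1.0 if dot >= 0 else -1.0
            np.testing.assert_allclose(ours[:, axis], sign * theirs[:, axis], atol=1e-8)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            cp.pcoa(np.array([[0.0, 1.0], [0.5, 0.0]]))

    def test_excess_axes_truncated_with_warning(self):
        d = np.array(
            [[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]]
        )  # collinear points: 1 positive eigenvalue
        with pytest.warns(UserWarning, match="truncating"):
            res = cp.pcoa(d, k=2)
        assert res.coordinates.shape[1] == 1
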