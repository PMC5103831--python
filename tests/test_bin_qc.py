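import numpy as np
import pandas as pd
import pytest

from seriesbin import bin_qc
from seriesbin.esom import UNBINNED, BinAssignment
from seriesbin.features import CoverageTable


def markers_frame(entries):
    return pd.DataFrame(entries, columns=["scaffold_id", "marker_id"])


def spread_markers(marker_ids, scaffolds):
    return markers_frame(
        [(scaffolds[i % len(scaffolds)], m) for i, m in enumerate(marker_ids)]
    )


class TestMarkerSets:
    def test_default_cardinalities(self):
        assert len(bin_qc.BACTERIAL_MARKERS.marker_ids) == 51
        assert len(bin_qc.ARCHAEAL_MARKERS.marker_ids) == 38

    def test_wrong_cardinality_rejected(self):
        with pytest.raises(ValueError, match="51"):
            bin_qc.MarkerSet("bacteria", ("m1", "m2"))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            bin_qc.MarkerSet("bacteria", ("m1",) * 51)


class TestAssessBin:
    def test_forty_of_fiftyone_markers(self):
        ids = bin_qc.BACTERIAL_MARKERS.marker_ids[:40]
        m = spread_markers(ids, ["a", "b", "c"])
        q = bin_qc.assess_bin(["a", "b", "c"], m, domain="bacteria")
        assert q.completeness == pytest.approx(40 / 51)
        assert q.duplicated_marker_count == 0
        assert q.draft_quality

    def test_empty_bin(self):
        q = bin_qc.assess_bin(["a"], markers_frame([]), domain="bacteria")
        assert q.completeness == 0.0
        assert not q.draft_quality

    def test_duplication_above_cap_blocks_draft_quality(self):
        # 39/51 distinct (complete enough) but 6 markers duplicated (>10%)
        ids = list(bin_qc.BACTERIAL_MARKERS.marker_ids[:39])
        entries = [("a", m) for m in ids] + [("b", m) for m in ids[:6]]
        q = bin_qc.assess_bin(["a", "b"], markers_frame(entries), domain="bacteria")
        assert q.completeness > 0.70
        assert q.duplicated_marker_count == 6
        assert not q.draft_quality
        relaxed = bin_qc.assess_bin(
            ["a", "b"], markers_frame(entries), domain="bacteria", duplication_cap=0.2
        )
        assert relaxed.draft_quality

    def test_markers_outside_bin_ignored(self):
        entries = [("inside", "BSCG_01"), ("outside", "BSCG_02")]
        q = bin_qc.assess_bin(["inside"], markers_frame(entries), domain="bacteria")
        assert q.completeness == pytest.approx(1 / 51)

    def test_domain_auto_detection_prefers_higher_completeness(self):
        arch = spread_markers(bin_qc.ARCHAEAL_MARKERS.marker_ids[:30], ["a"])
        q = bin_qc.assess_bin(["a"], arch)
        assert q.domain == "archaea"
        assert q.completeness == pytest.approx(30 / 38)

    def test_domain_tie_goes_to_bacteria(self):
        q = bin_qc.assess_bin(["a"], markers_frame([]))
        assert q.domain == "bacteria"

    def test_unknown_domain_and_marker_rejected(self):
        with pytest.raises(ValueError, match="unknown domain"):
            bin_qc.assess_bin(["a"], markers_frame([]), domain="virus")
        with pytest.raises(ValueError, match="NOT_A_MARKER"):
            bin_qc.assess_bin(
                ["a"], markers_frame([("a", "NOT_A_MARKER")]), domain="bacteria"
            )

    def test_perfect_bin_and_split_bin_completeness(self, small_community):
        """A genome's complete bin scores 1.0; halving it partitions the
        markers so the halves' completeness sums to exactly 1.0."""
        scaffolds = small_community["scaffolds"]
        truth = small_community["truth"]
        gid = next(g for g, d in truth.genome_domain.items() if d == "bacteria")
        members = list(scaffolds.table.index[scaffolds.table["genome_id"] == gid])
        m = scaffolds.markers
        q = bin_qc.assess_bin(members, m, domain="bacteria")
        assert q.completeness == 1.0
        assert q.duplicated_marker_count == 0
        half = len(members) // 2
        qa = bin_qc.assess_bin(members[:half], m, domain="bacteria")
        qb = bin_qc.assess_bin(members[half:], m, domain="bacteria")
        assert qa.completeness + qb.completeness == pytest.approx(1.0)

    def test_merged_genomes_show_duplication(self, small_community):
        scaffolds = small_community["scaffolds"]
        truth = small_community["truth"]
        bact = [g for g, d in truth.genome_domain.items() if d == "bacteria"][:2]
        members = list(
            scaffolds.table.index[scaffolds.table["genome_id"].isin(bact)]
        )
        q = bin_qc.assess_bin(members, scaffolds.markers, domain="bacteria")
        assert q.completeness == 1.0
        assert q.duplicated_marker_count == 51


def make_cov(values, samples=3):
    idx = [f"s{i}" for i in range(len(values))]
    return CoverageTable(
        pd.DataFrame(
            np.tile(np.asarray(values, dtype=float)[:, None], (1, samples)),
            index=idx,
            columns=[f"c{j}" for j in range(samples)],
        ),
        normalized=True,
    )


class TestFlagContaminants:
    def test_homogeneous_bin_unflagged(self):
        members = [f"s{i}" for i in range(6)]
        gc = {m: 0.5 for m in members}
        cov = make_cov([10.0] * 6)
        taxon = {m: "Acidobacteria" for m in members}
        assert bin_qc.flag_contaminants(members, gc, cov, taxon) == []

    def test_gc_outlier_flagged_with_reason(self):
        members = [f"s{i}" for i in range(8)]
        gc_vals = np.array([0.50, 0.51, 0.49, 0.52, 0.48, 0.50, 0.51, 0.50])
        med = np.median(gc_vals)
        mad = np.median(np.abs(gc_vals - med))
        gc_vals = gc_vals.copy()
        gc_vals[3] = med + 10 * 3.5 * mad  # far beyond the 3.5-MAD fence
        gc = dict(zip(members, gc_vals))
        cov = make_cov([10.0 + 0.1 * i for i in range(8)])
        flags = bin_qc.flag_contaminants(members, gc, cov, None)
        assert [f.scaffold_id for f in flags] == ["s3"]
        assert flags[0].reasons == ("gc",)

    def test_coverage_outlier_flagged(self):
        members = [f"s{i}" for i in range(6)]
        gc = {m: 0.5 + 0.001 * i for i, m in enumerate(members)}
        cov = make_cov([10.0, 10.5, 9.5, 10.2, 9.8, 300.0])
        flags = bin_qc.flag_contaminants(members, gc, cov, None)
        assert [f.scaffold_id for f in flags] == ["s5"]
        assert "coverage" in flags[0].reasons

    def test_taxonomy_conflict_needs_strict_majority(self):
        members = [f"s{i}" for i in range(6)]
        gc = {m: 0.5 + 0.001 * i for i, m in enumerate(members)}
        cov = make_cov([10.0, 10.4, 9.7, 10.1, 9.9, 10.2])
        majority = dict.fromkeys(members, "Acidobacteria")
        majority["s5"] = "Chloroflexi"
        flags = bin_qc.flag_contaminants(members, gc, cov, majority)
        assert [f.scaffold_id for f in flags] == ["s5"]
        assert flags[0].reasons == ("taxonomy",)
        # 3/6 is not a strict majority: nothing to vote against
        split = dict(majority)
        split["s3"] = split["s4"] = "Chloroflexi"
        assert bin_qc.flag_contaminants(members, gc, cov, split) == []

    def test_small_bins_never_flagged(self):
        members = ["s0", "s1", "s2"]
        gc = {"s0": 0.2, "s1": 0.9, "s2": 0.5}
        cov = make_cov([1.0, 500.0, 2.0])
        assert bin_qc.flag_contaminants(members, gc, cov, None) == []

    def test_order_invariance(self):
        members = [f"s{i}" for i in range(8)]
        gc = {m: 0.5 + (0.2 if m == "s2" else 0.0005 * i) for i, m in enumerate(members)}
        cov = make_cov(np.linspace(9, 11, 8))
        fwd = bin_qc.flag_contaminants(members, gc, cov, None)
        rev = bin_qc.flag_contaminants(members[::-1], gc, cov, None)
        assert sorted(f.scaffold_id for f in fwd) == sorted(f.scaffold_id for f in rev)

    def test_missing_gc_rejected(self):
        members = [f"s{i}" for i in range(4)]
        cov = make_cov([1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="missing GC"):
            bin_qc.flag_contaminants(members, {"s0": 0.5}, cov, None)


class TestRefineBins:
    def assignment(self):
        labels = {f"s{i}": "bin_001" for i in range(6)}
        labels.update({f"t{i}": "bin_002" for i in range(4)})
        return BinAssignment(labels=labels)

    def test_no_flags_is_identity(self):
        a = self.assignment()
        assert bin_qc.refine_bins(a, []).labels == a.labels

    def test_flag_counting(self):
        a = self.assignment()
        flags = [bin_qc.ContaminantFlag(f"s{i}", ("gc",)) for i in range(3)]
        refined = bin_qc.refine_bins(a, flags)
        assert len(refined.bins["bin_001"]) == 3
        assert len(refined.bins["bin_002"]) == 4
        assert set(refined.unbinned) == {"s0", "s1", "s2"}
        # partition preserved
        assert set(refined.labels) == set(a.labels)

    def test_unknown_scaffold_rejected(self):
        with pytest.raises(ValueError, match="unassigned"):
            bin_qc.refine_bins(self.assignment(), [bin_qc.ContaminantFlag("zz", ("gc",))])

    def test_reassessment_excludes_removed_markers(self):
        m = markers_frame([("s0", "BSCG_01"), ("s1", "BSCG_02"), ("s2", "BSCG_03")])
        a = BinAssignment(labels={f"s{i}": "bin_001" for i in range(3)})
        refined = bin_qc.refine_bins(a, [bin_qc.ContaminantFlag("s1", ("taxonomy",))])
        q = bin_qc.assess_bin(refined.bins["bin_001"], m, domain="bacteria")
        assert q.completeness == pytest.approx(2 / 51)
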