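"""Topology maps, region classification and variant differential analysis."""

import pytest

import epihotspot as eh
from epihotspot import datasets as ds
from epihotspot.annotation import (
    EXOFACIAL,
    INTRACELLULAR,
    MAJORITY_OVERLAP,
    TRANSMEMBRANE,
    read_topology,
    write_topology_tsv,
)
from epihotspot.errors import ValidationError


def _simple_map():
    return eh.build_topology_map(
        "toy",
        [(1, 10, INTRACELLULAR), (11, 20, TRANSMEMBRANE), (21, 30, EXOFACIAL)],
    )


class TestTopologyMap:
    def test_valid_three_interval_map(self):
        tmap = _simple_map()
        assert tmap.length == 30
        assert tmap.label_at(1) == INTRACELLULAR
        assert tmap.label_at(15) == TRANSMEMBRANE
        assert tmap.label_at(30) == EXOFACIAL

    def test_gap_rejected(self):
        with pytest.raises(ValidationError, match="gap"):
            eh.build_topology_map(
                "bad", [(1, 14, INTRACELLULAR), (16, 30, TRANSMEMBRANE)]
            )

    def test_overlap_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            eh.build_topology_map(
                "bad", [(1, 16, INTRACELLULAR), (15, 30, TRANSMEMBRANE)]
            )

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError, match="unknown label"):
            eh.build_topology_map("bad", [(1, 30, "outer-space")])

    def test_tsv_round_trip(self, tmp_path):
        path = tmp_path / "topo.tsv"
        write_topology_tsv([_simple_map(), ds.rhd_topology()], path)
        maps = read_topology(path)
        assert maps["toy"].intervals == _simple_map().intervals
        assert maps["RHD"].intervals == ds.rhd_topology().intervals

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "topo.yaml"
        path.write_text(
            "toy:\n"
            "  - [1, 10, intracellular]\n"
            "  - [11, 20, transmembrane]\n"
            "  - [21, 30, exofacial]\n"
        )
        assert read_topology(path)["toy"].intervals == _simple_map().intervals


class TestClassifyRegion:
    @pytest.mark.parametrize(
        "start,expected",
        [
            (38, EXOFACIAL),       # inside exofacial loop 32-53
            (358, EXOFACIAL),      # only its first residue is exofacial (loop 347-358)
            (31, TRANSMEMBRANE),   # one residue before the 32-53 loop
            (390, INTRACELLULAR),  # first residue of the C-terminal tail
        ],
    )
    def test_start_residue_rule_on_packaged_rhd_map(self, start, expected):
        assert eh.classify_region(start, ds.rhd_topology()) == expected

    def test_majority_overlap_differs_at_loop_edge(self):
        """A core starting on the last exofacial residue is exofacial under
        start_residue but transmembrane under majority_overlap."""
        tmap = ds.rhd_topology()
        assert eh.classify_region(358, tmap) == EXOFACIAL
        assert eh.classify_region(358, tmap, rule=MAJORITY_OVERLAP) == TRANSMEMBRANE

    def test_majority_tie_breaks_toward_exofacial(self):
        tmap = eh.build_topology_map(
            "tie", [(1, 5, TRANSMEMBRANE), (6, 10, EXOFACIAL), (11, 20, TRANSMEMBRANE)]
        )
        # window 2..10: 4 TM + 5 exofacial -> exofacial; window 2..11 ties 5/5
        assert eh.classify_region(2, tmap, rule=MAJORITY_OVERLAP, k=10) == EXOFACIAL

    def test_total_over_all_window_starts(self):
        tmap = ds.rhd_topology()
        for start in range(1, tmap.length - 9 + 2):
            assert eh.classify_region(start, tmap) in (
                EXOFACIAL, TRANSMEMBRANE, INTRACELLULAR,
            )

    def test_out_of_range_start_rejected(self):
        with pytest.raises(ValidationError):
            eh.classify_region(0, _simple_map())
        with pytest.raises(ValidationError):
            eh.classify_region(31, _simple_map())


class TestDiffHotspots:
    def test_identical_lists_all_shared(self):
        calls = ds.rh_hotspot_calls(ds.RHD_NORMAL, ds.DRB)
        diff = eh.diff_hotspots(calls, calls)
        assert len(diff.shared) == len(calls)
        assert diff.changed_core == () and diff.lost == () and diff.gained == ()

    def test_weak_d1_drb_changed_core_at_270(self):
        diff = eh.diff_hotspots(
            ds.rh_hotspot_calls(ds.RHD_NORMAL, ds.DRB),
            ds.rh_hotspot_calls(ds.RHD_WEAK_D1, ds.DRB),
        )
        assert diff.lost == () and diff.gained == ()
        (change,) = diff.changed_core
        assert change.start == 269
        assert (change.ref_core, change.cmp_core) == ("YVHSAVLAG", "YGHSAVLAG")
        assert change.changed_positions == (270,)

    def test_weak_d1_dpa_dpb_losses(self):
        diff = eh.diff_hotspots(
            ds.rh_hotspot_calls(ds.RHD_NORMAL, ds.DPA_DPB),
            ds.rh_hotspot_calls(ds.RHD_WEAK_D1, ds.DPA_DPB),
        )
        assert diff.lost == (264, 267, 269)
        assert diff.gained == ()
        assert diff.changed_core == ()

    def test_partition_of_union(self, rng):
        def mk(starts_cores):
            return [eh.HotspotCall("ag", s, c, 1) for s, c in starts_cores]

        ref = mk([(1, "A" * 9), (5, "C" * 9), (9, "D" * 9)])
        cmp_ = mk([(5, "C" * 9), (9, "E" * 9), (13, "F" * 9)])
        diff = eh.diff_hotspots(ref, cmp_)
        union = {1, 5, 9, 13}
        assert diff.all_starts() == union
        buckets = [set(diff.shared), {c.start for c in diff.changed_core},
                   set(diff.lost), set(diff.gained)]
        assert sum(len(b) for b in buckets) == len(union)

    def test_duplicate_starts_rejected(self):
        calls = [eh.HotspotCall("ag", 5, "A" * 9, 1), eh.HotspotCall("ag", 5, "C" * 9, 1)]
        with pytest.raises(ValidationError, match="duplicate"):
            eh.diff_hotspots(calls, [])


class TestVariantCoreChanges:
    def test_interior_variant_covers_k_windows(self, rhd_scaffold):
        v = eh.parse_hgvs_p("p.Val270Gly")
        starts = eh.variant_core_changes(rhd_scaffold, v, k=9)
        assert starts == list(range(262, 271))  # p-k+1 .. p

    def test_clipped_at_n_terminus(self):
        seq = eh.ProteinSequence(id="s", residues="V" + "A" * 19)
        v = eh.ProteinVariant("V", 1, "G")
        assert eh.variant_core_changes(seq, v, k=9) == [1]

    def test_clipped_at_c_terminus(self):
        seq = eh.ProteinSequence(id="s", residues="A" * 19 + "V")
        v = eh.ProteinVariant("V", 20, "G")
        assert eh.variant_core_changes(seq, v, k=9) == [12]  # length-k+1

    def test_outside_sequence_rejected(self, rhd_scaffold):
        with pytest.raises(ValidationError):
            eh.variant_core_changes(rhd_scaffold, eh.ProteinVariant("V", 999, "G"))

    def test_diff_changed_positions_subset_of_variant_windows(self, rhd_scaffold):
        """Cores changed by a substitution all start within the windows the
        substitution can touch."""
        v = eh.parse_hgvs_p("p.Val270Gly")
        mutated = eh.apply_variants(rhd_scaffold, [v], new_id="weakD1")
        k = 9
        ref_calls = [
            eh.HotspotCall(rhd_scaffold.id, s, rhd_scaffold.slice(s, k), 1)
            for s in range(260, 275)
        ]
        cmp_calls = [
            eh.HotspotCall("weakD1", s, mutated.slice(s, k), 1)
            for s in range(260, 275)
        ]
        diff = eh.diff_hotspots(ref_calls, cmp_calls)
        changed_starts = {c.start for c in diff.changed_core}
        assert changed_starts
        assert changed_starts <= set(eh.variant_core_changes(rhd_scaffold, v, k=k))


class TestPackagedMapsAgainstPublishedLabels:
    def test_rhce_map_reproduces_all_labels(self):
        tmap = ds.rhce_topology()
        for locus in (ds.DRB, ds.DQA_DQB, ds.DPA_DPB):
            for call in ds.rh_hotspot_calls(ds.RHCE, locus):
                assert eh.classify_region(call.start, tmap) == call.region, call

    def test_rhd_map_mismatches_only_documented_conflicts(self):
        """The packaged RhD map reproduces every published label except the
        start whose published labels contradict each other across locus
        columns (documented in datasets.KNOWN_LABEL_CONFLICTS)."""
        tmap = ds.rhd_topology()
        conflicts = {
            (group, locus, start)
            for group, locus, start, _label in ds.KNOWN_LABEL_CONFLICTS
        }
        for group in (ds.RHD_NORMAL, ds.RHD_WEAK_D1):
            for locus in (ds.DRB, ds.DQA_DQB, ds.DPA_DPB):
                for call in ds.rh_hotspot_calls(group, locus):
                    predicted = eh.classify_region(call.start, tmap)
                    if (group, locus, call.start) in conflicts:
                        assert predicted != call.region
                    else:
                        assert predicted == call.region, (group, locus, call)
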