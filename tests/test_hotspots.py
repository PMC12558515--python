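"""Strong-binder profiles, hotspot calling, heatmaps and locus summaries."""

import numpy as np
import pytest

import epihotspot as eh
from epihotspot.binding import SB
from epihotspot.errors import ValidationError
from epihotspot.hotspots import PER_RESIDUE, PER_START

from conftest import random_record


def _allele(i):
    return eh.HlaAllele(name=f"SYN-{i:02d}", locus_group="DRB", mhc_class="II")


def _record(allele, start, rank, antigen="ag"):
    return eh.BindingRecord(
        allele=allele, antigen_id=antigen, start=start, core="AAAAAAAAA",
        percent_rank=rank,
    )


class TestBuildProfile:
    def test_single_sb_record(self, thresholds):
        profile = eh.build_profile([_record(_allele(1), 38, 0.2)], thresholds,
                                   antigen_length=60)
        assert profile.count_at(38) == 1
        assert profile.counts.sum() == 1
        assert len(profile.counts) == 52  # 60 - 9 + 1 starts

    def test_two_alleles_same_start(self, thresholds):
        records = [_record(_allele(1), 38, 0.2), _record(_allele(2), 38, 0.4)]
        profile = eh.build_profile(records, thresholds, antigen_length=60)
        assert profile.count_at(38) == 2

    def test_wb_and_nb_do_not_count(self, thresholds):
        records = [_record(_allele(1), 5, 0.5), _record(_allele(2), 5, 60.0)]
        profile = eh.build_profile(records, thresholds, antigen_length=30)
        assert profile.counts.sum() == 0

    def test_matches_nested_loop_oracle(self, rng, thresholds):
        """Random instance equals a brute-force double loop over (start, allele)."""
        alleles = [_allele(i) for i in range(6)]
        records = []
        for a in alleles:
            for start in range(1, 41):
                records.append(_record(a, start, float(rng.uniform(0.01, 5.0))))
        profile = eh.build_profile(records, thresholds, antigen_length=48)
        for start in range(1, 41):
            expected = sum(
                1 for a in alleles for r in records
                if r.allele == a and r.start == start
                and eh.classify_binder(r, thresholds) == SB
            )
            assert profile.count_at(start) == expected

    def test_per_start_conservation(self, rng, thresholds):
        records = [_record(_allele(i), int(rng.integers(1, 40)), float(rng.uniform(0.01, 5)))
                   for i in range(30)]
        # deduplicate (allele, start)
        seen, unique = set(), []
        for r in records:
            key = (r.allele.name, r.start)
            if key not in seen:
                seen.add(key)
                unique.append(r)
        profile = eh.build_profile(unique, thresholds, antigen_length=48)
        n_sb = sum(1 for r in unique if eh.classify_binder(r, thresholds) == SB)
        assert profile.counts.sum() == n_sb

    def test_per_residue_covers_k_positions(self, thresholds):
        profile = eh.build_profile([_record(_allele(1), 10, 0.1)], thresholds,
                                   mode=PER_RESIDUE, antigen_length=40)
        assert profile.counts.sum() == 9
        assert all(profile.count_at(p) == 1 for p in range(10, 19))

    def test_mixed_antigens_rejected(self, thresholds):
        records = [_record(_allele(1), 1, 0.1, "a"), _record(_allele(1), 1, 0.1, "b")]
        with pytest.raises(ValidationError, match="multiple antigens"):
            eh.build_profile(records, thresholds)

    def test_duplicate_allele_start_rejected(self, thresholds):
        records = [_record(_allele(1), 7, 0.1), _record(_allele(1), 7, 0.3)]
        with pytest.raises(ValidationError, match="duplicate.*SYN-01.*7"):
            eh.build_profile(records, thresholds)


class TestCallHotspots:
    def test_all_zero_profile_empty(self, thresholds):
        profile = eh.build_profile([_record(_allele(1), 3, 50.0)], thresholds,
                                   antigen_length=20)
        assert eh.call_hotspots(profile) == []

    def test_min_alleles_filters(self, thresholds):
        profile = eh.build_profile([_record(_allele(1), 4, 0.1)], thresholds,
                                   antigen_length=20)
        assert [c.start for c in eh.call_hotspots(profile, min_alleles=1)] == [4]
        assert eh.call_hotspots(profile, min_alleles=2) == []

    def test_hotspot_set_shrinks_with_min_alleles(self, rng, thresholds):
        records = []
        for i in range(5):
            for start in range(1, 30):
                records.append(_record(_allele(i), start, float(rng.uniform(0.01, 2))))
        profile = eh.build_profile(records, thresholds, antigen_length=37)
        previous = None
        for m in range(1, 7):
            called = {c.start for c in eh.call_hotspots(profile, min_alleles=m)}
            if previous is not None:
                assert called <= previous
            previous = called

    def test_cores_sliced_from_sequence(self, thresholds, rhd_scaffold):
        records = [_record(_allele(1), 269, 0.2, rhd_scaffold.id)]
        profile = eh.build_profile(records, thresholds,
                                   antigen_length=rhd_scaffold.length)
        (call,) = eh.call_hotspots(profile, sequence=rhd_scaffold)
        assert call.core == "YVHSAVLAG"

    def test_per_residue_profile_rejected(self, thresholds):
        profile = eh.build_profile([_record(_allele(1), 1, 0.1)], thresholds,
                                   mode=PER_RESIDUE, antigen_length=20)
        with pytest.raises(ValidationError, match="per_start"):
            eh.call_hotspots(profile)


class TestHeatmapMatrix:
    def test_single_sb_single_nonzero_cell(self, thresholds):
        records = [
            _record(_allele(1), 1, 0.2), _record(_allele(1), 2, 50.0),
            _record(_allele(1), 3, 50.0), _record(_allele(2), 1, 50.0),
            _record(_allele(2), 2, 50.0), _record(_allele(2), 3, 50.0),
        ]
        mat = eh.heatmap_matrix(records, thresholds)
        assert mat.shape == (2, 3)
        assert mat.to_numpy().sum() == 1
        assert mat.loc["SYN-01", 1] == 1

    def test_column_sums_equal_profile(self, rng, thresholds):
        records = []
        for i in range(4):
            for start in range(1, 21):
                records.append(_record(_allele(i), start, float(rng.uniform(0.01, 3))))
        mat = eh.heatmap_matrix(records, thresholds)
        profile = eh.build_profile(records, thresholds, antigen_length=28)
        np.testing.assert_array_equal(
            mat.sum(axis=0).to_numpy(), profile.counts[:20]
        )

    def test_row_order_lexicographic_and_row_count(self, rng, thresholds):
        records = [_record(_allele(i), 1, 1.0) for i in (3, 1, 2)]
        mat = eh.heatmap_matrix(records, thresholds)
        assert list(mat.index) == ["SYN-01", "SYN-02", "SYN-03"]

    def test_empty_records_warn(self, thresholds):
        with pytest.warns(UserWarning):
            mat = eh.heatmap_matrix([], thresholds)
        assert mat.empty

    def test_rank_values_mode(self, thresholds):
        records = [_record(_allele(1), 5, 1.25)]
        mat = eh.heatmap_matrix(records, thresholds, values="rank")
        assert mat.loc["SYN-01", 5] == 1.25


class TestSummarizeByLocus:
    def test_counts_distinct_starts(self):
        calls = [
            eh.HotspotCall("ag", 10, "AAAAAAAAA", 1),
            eh.HotspotCall("ag", 20, "AAAAAAAAA", 2),
        ]
        table = eh.summarize_by_locus({("ag", "DRB"): calls, ("ag", "DPA-DPB"): []})
        assert dict(zip(table["locus_group"], table["n_hotspots"])) == {
            "DRB": 2, "DPA-DPB": 0,
        }

    def test_empty_input_gives_empty_table(self):
        assert eh.summarize_by_locus({}).empty

    def test_duplicate_starts_rejected(self):
        calls = [eh.HotspotCall("ag", 10, "A" * 9, 1), eh.HotspotCall("ag", 10, "C" * 9, 1)]
        with pytest.raises(ValidationError, match="duplicate"):
            eh.summarize_by_locus({("ag", "DRB"): calls})


class TestMergeAdjacent:
    def test_adjacent_starts_merge_into_regions(self):
        calls = [eh.HotspotCall("ag", s, "A" * 9, 1) for s in (3, 4, 5, 20, 22)]
        regions = eh.merge_adjacent(calls, gap=0)
        assert [(a, b) for a, b, _ in regions] == [(3, 5), (20, 20), (22, 22)]
        regions = eh.merge_adjacent(calls, gap=1)
        assert [(a, b) for a, b, _ in regions] == [(3, 5), (20, 22)]
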