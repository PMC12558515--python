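"""Synthetic allele generation, pseudo-%rank calibration, planted truth."""

import numpy as np
import pytest

import epihotspot as eh
from epihotspot.binding import SB
from epihotspot.errors import GenerationError, UnsupportedAlleleError, ValidationError

from conftest import AA, random_peptide


class TestMakeSyntheticAllele:
    def test_deterministic_for_seed(self):
        a, b = eh.make_synthetic_allele(seed=7), eh.make_synthetic_allele(seed=7)
        np.testing.assert_array_equal(a.weights, b.weights)
        np.testing.assert_array_equal(a.background_scores, b.background_scores)
        assert a.anchors == b.anchors

    def test_seeds_differ(self):
        """Across 20 seeds at least one pair of anchor sets differs."""
        anchors = {eh.make_synthetic_allele(seed=s).anchors for s in range(20)}
        assert len(anchors) > 1

    def test_anchor_columns_peaked_nonanchors_flat(self):
        pssm = eh.make_synthetic_allele(seed=3)
        for col in range(pssm.k):
            spread = pssm.weights[col].max() - pssm.weights[col].min()
            if col + 1 in pssm.anchors:
                assert spread > 3.0
            else:
                assert spread < 1.0

    @pytest.mark.parametrize("n_anchors", [0, 10])
    def test_invalid_anchor_count_rejected(self, n_anchors):
        with pytest.raises(ValidationError):
            eh.make_synthetic_allele(seed=1, n_anchors=n_anchors)

    def test_background_size_floor(self):
        with pytest.raises(ValidationError):
            eh.make_synthetic_allele(seed=1, B=50)


class TestPseudoRank:
    def test_consensus_attains_minimum_rank(self):
        pssm = eh.make_synthetic_allele(seed=5, B=1000)
        assert eh.pseudo_rank(pssm, pssm.consensus()) == pytest.approx(100 / 1001)

    def test_score_below_background_ranks_100(self):
        pssm = eh.make_synthetic_allele(seed=5)
        assert eh.pseudo_rank(pssm, "AAAAAAAAA",
                              score=float(pssm.background_scores.min()) - 10) == 100.0

    def test_matches_brute_force_background_recount(self, rng):
        """Rank equals a direct recount of background peptides scoring >= s."""
        pssm = eh.make_synthetic_allele(seed=9, B=500)
        for _ in range(25):
            pep = random_peptide(rng)
            s = pssm.score(pep)
            m = int(np.sum(pssm.background_scores >= s))
            assert eh.pseudo_rank(pssm, pep) == pytest.approx(100 * (1 + m) / 501)

    def test_wrong_length_rejected(self):
        pssm = eh.make_synthetic_allele(seed=5)
        with pytest.raises(ValidationError):
            eh.pseudo_rank(pssm, "ACDEF")

    def test_rank_distribution_approximately_uniform(self, rng):
        """Ranks of random background-like peptides are approximately
        uniform on (0, 100].

        All draws are quantiles against one shared finite background
        sample, so they are conditionally dependent; the empirical CDF is
        therefore compared with the uniform CDF at a tolerance set by the
        background's own sampling error (~1/sqrt(B)), rather than with an
        independence-assuming significance test.
        """
        pssm = eh.make_synthetic_allele(seed=11, B=1000)
        ranks = np.sort(
            [eh.pseudo_rank(pssm, random_peptide(rng)) for _ in range(1500)]
        )
        assert ranks[0] > 0 and ranks[-1] <= 100
        ecdf = np.arange(1, len(ranks) + 1) / len(ranks)
        ks_distance = np.max(np.abs(ecdf - ranks / 100))
        assert ks_distance < 0.10  # ~3x the 1/sqrt(B) background noise floor
        assert 45 < ranks.mean() < 55


class TestSyntheticPredictor:
    def test_cardinality_one_record_per_pair(self, small_panel):
        seq = eh.ProteinSequence(id="ag", residues="ACDEFGHIKLMN")  # 4 windows
        windows = eh.enumerate_peptides(seq)
        records = eh.SyntheticPredictor(small_panel).predict(windows)
        assert len(records) == 4 * 3

    def test_deterministic_with_seed(self, small_panel):
        seq = eh.ProteinSequence(id="ag", residues="ACDEFGHIKLMNPQRS")
        windows = eh.enumerate_peptides(seq)
        p1 = eh.SyntheticPredictor(small_panel, noise_sigma=1.0, seed=4)
        p2 = eh.SyntheticPredictor(small_panel, noise_sigma=1.0, seed=4)
        assert p1.predict(windows) == p2.predict(windows)

    def test_empty_inputs_rejected(self, small_panel):
        seq = eh.ProteinSequence(id="ag", residues="ACDEFGHIKLMN")
        windows = eh.enumerate_peptides(seq)
        with pytest.raises(ValidationError):
            eh.SyntheticPredictor(small_panel).predict([])
        with pytest.raises(ValidationError):
            eh.SyntheticPredictor(small_panel).predict(windows, alleles=[])

    def test_unsupported_allele_rejected(self, small_panel):
        seq = eh.ProteinSequence(id="ag", residues="ACDEFGHIKLMN")
        windows = eh.enumerate_peptides(seq)
        stranger = eh.HlaAllele.from_name("DRB1*15:01")
        with pytest.raises(UnsupportedAlleleError):
            eh.SyntheticPredictor(small_panel).predict(windows, alleles=[stranger])

    def test_ambiguous_windows_skipped_with_warning(self, small_panel):
        seq = eh.ProteinSequence(id="ag", residues="ACDEFGHIKXACDEFGHIK")
        windows = eh.enumerate_peptides(seq)
        with pytest.warns(UserWarning, match="skipping"):
            records = eh.SyntheticPredictor(small_panel).predict(windows)
        clean = sum(1 for w in windows if not w.flagged)
        assert len(records) == clean * 3


class TestPlantMotifs:
    def test_planted_truth_recovered_end_to_end(self, small_panel):
        plants = [(10, small_panel[0]), (40, small_panel[1])]
        truth = eh.plant_motifs(80, plants, seed=21, panel=small_panel)
        records = eh.SyntheticPredictor(small_panel, seed=21).predict(
            eh.enumerate_peptides(truth.antigen)
        )
        for name, starts in truth.planted.items():
            sb = {r.start for r in records
                  if r.allele.name == name and eh.classify_binder(r) == SB}
            assert sb == set(starts)
        profile = eh.build_profile(records, antigen_length=80)
        called = {c.start for c in eh.call_hotspots(profile, sequence=truth.antigen)}
        assert called == {10, 40}

    def test_empty_plants_all_windows_nb(self, small_panel):
        truth = eh.plant_motifs(60, [], seed=3, panel=small_panel)
        records = eh.SyntheticPredictor(small_panel, seed=3).predict(
            eh.enumerate_peptides(truth.antigen)
        )
        assert all(eh.classify_binder(r) == "NB" for r in records)

    def test_same_seed_same_antigen(self, small_panel):
        plants = [(5, small_panel[0])]
        a = eh.plant_motifs(50, plants, seed=8, panel=small_panel)
        b = eh.plant_motifs(50, plants, seed=8, panel=small_panel)
        assert a.antigen.residues == b.antigen.residues

    def test_overlapping_plants_rejected(self, small_panel):
        with pytest.raises(ValidationError, match="overlap"):
            eh.plant_motifs(50, [(5, small_panel[0]), (9, small_panel[1])], seed=1)

    def test_out_of_range_plant_rejected(self, small_panel):
        with pytest.raises(ValidationError):
            eh.plant_motifs(50, [(49, small_panel[0])], seed=1)

    def test_retries_exhausted_raises_generation_error(self, small_panel):
        # an impossibly tight WB band makes every random window a violation
        tight = eh.BinderThresholds(sb_rank=0.05, wb_rank=99.9)
        with pytest.raises(GenerationError):
            eh.plant_motifs(60, [(5, small_panel[0])], seed=1,
                            thresholds=tight, panel=small_panel, max_retries=2)

    def test_noise_degrades_planted_rank_monotonically(self, small_panel):
        """Average planted-window %rank does not improve as score noise grows."""
        plants = [(10, small_panel[0]), (40, small_panel[1])]
        truth = eh.plant_motifs(80, plants, seed=13, panel=small_panel)
        windows = eh.enumerate_peptides(truth.antigen)

        def mean_planted_rank(sigma):
            ranks = []
            for rep in range(5):
                records = eh.SyntheticPredictor(
                    small_panel, noise_sigma=sigma, seed=100 + rep
                ).predict(windows)
                for r in records:
                    if r.start in truth.planted.get(r.allele.name, ()):
                        ranks.append(r.percent_rank)
            return float(np.mean(ranks))

        r0, r_mid, r_big = mean_planted_rank(0.0), mean_planted_rank(3.0), mean_planted_rank(20.0)
        assert r0 <= r_mid <= r_big
        assert r0 < 0.5  # noise-free planted windows are strong binders
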