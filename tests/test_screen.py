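import numpy as np
import pytest

from ectlnc.screen import (
    OverlapAlignment,
    ScreenParams,
    align_overlap,
    global_identity,
    overlap_identity,
    round_half_up,
    screen_pairs,
    summarize_records,
    summarize_screen,
)
from ectlnc.seqio import reverse_complement
from ectlnc.simulate import SimParams, generate_ect_dataset, mutate_sequence, random_sequence

from conftest import FAST_SIM


class TestAlignOverlap:
    def test_self_alignment_is_full_sense(self, rng):
        s = random_sequence(rng, 300)
        aln = align_overlap(s, s)
        assert aln.orientation == "sense"
        assert (aln.matches, aln.aligned_cols) == (300, 300)
        assert (aln.lnc_start, aln.lnc_end) == (0, 300)
        assert (aln.tgt_start, aln.tgt_end) == (0, 300)

    def test_reverse_complement_is_antisense(self, rng):
        s = random_sequence(rng, 250)
        aln = align_overlap(s, reverse_complement(s))
        assert aln.orientation == "antisense"
        assert aln.matches == 250
        assert (aln.tgt_start, aln.tgt_end) == (0, 250)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_overlap("", "ACGT")

    def test_planted_fragment_statistics(self, rng):
        # lncRNA = bases [0, 200) of a 500-nt mRNA with 10% substitutions
        tgt = random_sequence(rng, 500)
        lnc, n_sub = mutate_sequence(tgt[:200], 0.10, rng)
        aln = align_overlap(lnc, tgt)
        assert aln.orientation == "sense"
        assert aln.matches >= 200 - n_sub  # local trimming can only help
        assert aln.tgt_start < 10 and aln.tgt_end > 190


class TestIdentities:
    def _aln(self, matches, cols):
        return OverlapAlignment("l", "t", 0, cols, 0, cols, "sense", matches, cols, 0.0)

    @pytest.mark.parametrize("matches,cols,expected", [(300, 300, 100.0), (0, 50, 0.0)])
    def test_overlap_identity_values(self, matches, cols, expected):
        assert overlap_identity(self._aln(matches, cols)) == expected

    @pytest.mark.parametrize(
        "matches,length,expected", [(300, 300, 100.0), (200, 1000, 20.0)]
    )
    def test_global_identity_values(self, matches, length, expected):
        assert global_identity(self._aln(matches, matches), length) == expected

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            global_identity(self._aln(1, 1), 0)

    def test_planted_divergence_identity_matches_manifest(self):
        """Gap-free planted pairs: measured identity tracks the realized
        substitution count recorded by the generator."""
        ds = generate_ect_dataset(SimParams(rng_seed=23, lnc_divergence=0.10, **FAST_SIM))
        cdnas = {m.transcript_id: c.seq for m, c in ds.species[0].lncrnas()}
        targets = {m.transcript_id: c.seq for m, c in ds.species[0].mrnas()}
        for entry in ds.truth.planted_lncrnas:
            aln = align_overlap(cdnas[entry["lnc_id"]], targets[entry["source_transcript"]])
            measured = overlap_identity(aln)
            # local alignment may trim terminal mismatches, never worse
            assert measured >= entry["expected_overlap_identity_pct"] - 1e-9
            assert measured == pytest.approx(
                entry["expected_overlap_identity_pct"], abs=0.75
            )

    def test_global_at_most_overlap_for_gap_free_pairs(self, default_dataset):
        sp = default_dataset.species[0]
        for pair in screen_pairs(sp.lncrnas(), sp.mrnas()):
            lnc_len = pair.alignment.lnc_end - pair.alignment.lnc_start
            if pair.alignment.aligned_cols == lnc_len:  # gap-free over the lncRNA
                assert pair.global_identity_pct <= pair.overlap_identity_pct + 1e-9


class TestScreenPairs:
    def test_zero_divergence_sense_only(self):
        ds = generate_ect_dataset(
            SimParams(rng_seed=3, lnc_divergence=0.0, lnc_antisense_prob=0.0, **FAST_SIM)
        )
        sp = ds.species[0]
        pairs = screen_pairs(sp.lncrnas(), sp.mrnas())
        recovered = {p.alignment.lnc_id for p in pairs}
        assert recovered == {e["lnc_id"] for e in ds.truth.planted_lncrnas}
        by_source = {
            (p.alignment.lnc_id, p.alignment.target_id): p for p in pairs
        }
        for e in ds.truth.planted_lncrnas:
            pair = by_source[(e["lnc_id"], e["source_transcript"])]
            assert pair.consistency_flag == "+"
            assert pair.overlap_identity_pct == 100.0

    def test_antisense_plants_get_minus_flag(self):
        ds = generate_ect_dataset(
            SimParams(rng_seed=4, lnc_divergence=0.05, lnc_antisense_prob=1.0, **FAST_SIM)
        )
        sp = ds.species[0]
        pairs = screen_pairs(sp.lncrnas(), sp.mrnas())
        assert pairs and all(p.consistency_flag == "-" for p in pairs)

    def test_high_divergence_yields_nothing(self):
        ds = generate_ect_dataset(SimParams(rng_seed=5, lnc_divergence=0.40, **FAST_SIM))
        sp = ds.species[0]
        assert screen_pairs(sp.lncrnas(), sp.mrnas()) == []

    def test_empty_inputs(self, fast_dataset):
        assert screen_pairs([], fast_dataset.species[0].mrnas()) == []

    def test_threshold_predicate_recheckable(self, default_dataset):
        params = ScreenParams()
        sp = default_dataset.species[0]
        for p in screen_pairs(sp.lncrnas(), sp.mrnas(), params):
            assert p.overlap_identity_pct > params.min_overlap_identity_pct
            assert p.alignment.aligned_cols >= params.min_overlap_length
            assert p.consistency_flag == ("+" if p.alignment.orientation == "sense" else "-")


class TestSummary:
    def test_fraction_rounding(self):
        records = [(90.0, 20.0, "+")] * 24
        s = summarize_records(records, n_lncrna=5101, n_trans=2904)
        assert s.fraction_pct == 0.8

    def test_round_half_up(self):
        assert round_half_up(0.85, 1) == 0.9
        assert round_half_up(0.84, 1) == 0.8

    def test_empty_pairs(self):
        s = summarize_screen([], n_lncrna=10, n_trans=5)
        assert s.n_pairs == 0 and s.nat_count == 0 and s.fraction_pct == 0.0
        assert s.overlap_identity_min is None

    def test_pairs_present_with_zero_trans_rejected(self):
        with pytest.raises(ValueError):
            summarize_records([(90.0, 10.0, "+")], 1, 0)
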