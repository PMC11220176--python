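import numpy as np
import pytest
from oracles import brute_triplex, brute_tts

from ectlnc.seqio import reverse_complement
from ectlnc.simulate import SimParams, _mirror_purine_tract, generate_ect_dataset, random_sequence
from ectlnc.triplex import (
    TriplexParams,
    design_probe,
    find_tts,
    match_triplex,
)

from conftest import FAST_SIM

_PYR = str.maketrans("AG", "TC")


def _site_tuples(sites):
    return sorted(
        (s.tts_start, s.tts_end, s.purine_strand, s.tfo_start, s.tfo_end,
         s.motif, s.length, s.errors)
        for s in sites
    )


class TestFindTts:
    def test_pure_purine_run(self):
        dna = "AAGGAAGGAAGGAAGG"
        hits = find_tts(dna, TriplexParams(min_length=15, max_error_rate=0.0))
        plus = [t for t in hits if t.purine_strand == "+"]
        assert any(t.start == 0 and t.end == 16 for t in plus)

    def test_pyrimidine_run_reports_reverse_strand(self):
        dna = "TTCCTTCCTTCCTTCC"
        hits = find_tts(dna, TriplexParams(min_length=15, max_error_rate=0.0))
        assert hits and all(t.purine_strand == "-" for t in hits)
        assert any(t.start == 0 and t.end == 16 for t in hits)

    def test_equals_brute_force_on_random_sequences(self, rng):
        for trial in range(4):
            dna = random_sequence(rng, 150)
            if trial % 2 == 0:
                tract = _mirror_purine_tract(rng, 22)
                dna = dna[:30] + tract + dna[52:]
            for min_len, rate in ((10, 0.1), (15, 0.1), (15, 0.0)):
                params = TriplexParams(min_length=min_len, max_error_rate=rate)
                impl = sorted((t.start, t.end, t.purine_strand) for t in find_tts(dna, params))
                assert impl == brute_tts(dna, min_len, rate)


class TestMatchTriplex:
    def test_y_motif_perfect_site(self):
        # T.A:T / C.G:C code: pyrimidine RNA against the purine strand
        rna = "TTCCTTCCTTCCTTC"
        dna = "AAGGAAGGAAGGAAG"
        sites = match_triplex(rna, dna, TriplexParams(min_length=15, max_error_rate=0.0))
        y = [s for s in sites if s.motif == "Y" and s.purine_strand == "+"]
        assert len(y) == 1
        assert (y[0].tts_start, y[0].tts_end, y[0].errors) == (0, 15, 0)

    def test_no_composable_window_is_empty(self):
        # A-only RNA offers no Y (T/C), M (G/T) windows and pairs A.A only
        # against an A-free DNA
        rna = "A" * 40
        dna = "C" * 40
        assert match_triplex(rna, dna, TriplexParams(min_length=15)) == []

    def test_equals_brute_force_across_grid(self, rng):
        for trial in range(4):
            dlen, rlen = int(rng.integers(50, 110)), int(rng.integers(35, 75))
            dna, rna = random_sequence(rng, dlen), random_sequence(rng, rlen)
            if trial % 2 == 0:
                tract = _mirror_purine_tract(rng, 16)
                p = int(rng.integers(0, dlen - 16))
                dna = dna[:p] + tract + dna[p + 16:]
                q = int(rng.integers(0, rlen - 16))
                rna = rna[:q] + tract.translate(_PYR) + rna[q + 16:]
            for min_len in (10, 15):
                for rate in (0.0, 0.1, 0.2):
                    params = TriplexParams(min_length=min_len, max_error_rate=rate)
                    impl = _site_tuples(match_triplex(rna, dna, params))
                    assert impl == brute_triplex(rna, dna, min_len, rate), (
                        trial, min_len, rate
                    )

    def test_strand_symmetry(self, rng):
        dna = random_sequence(rng, 80)
        tract = _mirror_purine_tract(rng, 20)
        dna = dna[:30] + tract + dna[50:]
        rna = random_sequence(rng, 20) + tract.translate(_PYR) + random_sequence(rng, 20)
        params = TriplexParams(min_length=15, max_error_rate=0.1)
        fwd = match_triplex(rna, dna, params)
        rev = match_triplex(rna, reverse_complement(dna), params)
        n = len(dna)
        mirrored = sorted(
            (n - s.tts_end, n - s.tts_start, "+" if s.purine_strand == "-" else "-",
             s.tfo_start, s.tfo_end, s.motif, s.length, s.errors)
            for s in rev
        )
        assert _site_tuples(fwd) == mirrored

    def test_planted_tract_recovered_at_zero_error(self):
        """The generator's polypurine tract + derived lncRNA TFO is always
        reported as a perfect site, whatever the planted orientation."""
        for seed in range(5):
            ds = generate_ect_dataset(SimParams(rng_seed=seed, **FAST_SIM))
            sp = ds.species[0]
            truth = ds.truth.triplex
            gene = sp.model_index()[truth["transcript_id"]]
            dna = sp.genome[gene.locus.chrom][gene.locus.start : gene.locus.end]
            off = truth["tract_offset_in_gene"]
            lnc_seqs = {m.transcript_id: c.seq for m, c in sp.lncrnas()}
            assert truth["tract_lnc_coords"], "at least one lncRNA carries the tract"
            for lnc_id, (a, b) in truth["tract_lnc_coords"].items():
                sites = match_triplex(lnc_seqs[lnc_id], dna)
                perfect = [
                    s for s in sites
                    if s.errors == 0
                    and s.tts_start <= off and s.tts_end >= off + 20
                    and s.tfo_start <= a and s.tfo_end >= b
                ]
                assert perfect, (seed, lnc_id)


class TestDesignProbe:
    def _perfect_site(self, rng, site_len):
        tract = _mirror_purine_tract(rng, site_len)
        dna = random_sequence(rng, 20) + tract + random_sequence(rng, 20)
        rna = random_sequence(rng, 10) + tract.translate(_PYR) + random_sequence(rng, 10)
        params = TriplexParams(min_length=15, max_error_rate=0.1)
        sites = [s for s in match_triplex(rna, dna, params) if s.motif == "Y"]
        assert sites
        return sites[0], rna, dna

    def test_perfect_site_takes_leftmost_window(self, rng):
        site, rna, dna = self._perfect_site(rng, 30)
        probe = design_probe(site, rna, dna, probe_len=20)
        assert probe.errors == 0
        assert probe.tts_start == site.tts_start  # leftmost tie-break

    def test_probe_spanning_whole_site_is_the_site(self, rng):
        site, rna, dna = self._perfect_site(rng, 20)
        probe = design_probe(site, rna, dna, probe_len=site.length)
        assert (probe.tts_start, probe.tts_end) == (site.tts_start, site.tts_end)
        assert probe.pyrimidine_seq == reverse_complement(probe.purine_seq)

    def test_min_error_window_avoids_planted_error(self, rng):
        tract = _mirror_purine_tract(rng, 30)
        # breaking position 3 of the DNA tract forces the probe window right
        broken = tract[:3] + "C" + tract[4:]
        dna = random_sequence(rng, 15) + broken + random_sequence(rng, 15)
        rna = random_sequence(rng, 8) + tract.translate(_PYR) + random_sequence(rng, 8)
        params = TriplexParams(min_length=15, max_error_rate=0.2)
        sites = [s for s in match_triplex(rna, dna, params) if s.motif == "Y"]
        site = max(sites, key=lambda s: s.length)
        if site.length >= 20 + 4:  # room to dodge the error
            probe = design_probe(site, rna, dna, probe_len=20)
            assert probe.errors == 0

    def test_site_shorter_than_probe_rejected(self, rng):
        site, rna, dna = self._perfect_site(rng, 20)
        with pytest.raises(ValueError):
            design_probe(site, rna, dna, probe_len=25)
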