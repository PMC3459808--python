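import random

import pytest

from mirsitescan import (
    ComplementarityScoring,
    GenomicInterval,
    NucleotideSequence,
    UTRRecord,
    align_complementarity,
    enforce_seed_wobble_rule,
)
from mirsitescan.complement_align import (
    AlignedSite,
    MISMATCH_SYMBOL,
    _best_local_alignment,
    filter_by_energy,
)
from mirsitescan.duplex import PAIR_SYMBOL, WOBBLE_SYMBOL

from .oracles import brute_local_alignment_score

RC = str.maketrans("ACGU", "UGCA")


def revcomp_rna(s):
    return s.translate(RC)[::-1]


def rand_rna(r, n):
    return "".join(r.choice("ACGU") for _ in range(n))


def utr_record(seq_rna, start=1001):
    dna = seq_rna.replace("U", "T")
    return UTRRecord("u", NucleotideSequence(dna, "DNA"),
                     GenomicInterval("chrT", start, start + len(dna) - 1))


class TestAlignment:
    def test_perfect_complement_unscaled_score(self):
        r = random.Random(3)
        m = rand_rna(r, 22)
        sc = ComplementarityScoring(scale_factor=1.0, score_threshold=50)
        utr = utr_record(rand_rna(r, 25) + revcomp_rna(m) + rand_rna(r, 25))
        sites = align_complementarity("mir", m, utr, sc)
        assert sites and sites[0].score == pytest.approx(22 * 5)

    def test_five_prime_scaling_adds_scaled_columns(self):
        r = random.Random(3)
        m = rand_rna(r, 22)
        sc = ComplementarityScoring(scale_factor=4.0)
        utr = utr_record(rand_rna(r, 25) + revcomp_rna(m) + rand_rna(r, 25))
        sites = align_complementarity("mir", m, utr, sc)
        # 7 columns (miRNA 2-8) gain (4-1)*5 each over the unscaled 110
        assert sites and sites[0].score == pytest.approx(110 + 7 * 5 * 3)

    def test_scale_one_means_scaled_equals_raw(self):
        r = random.Random(11)
        sc = ComplementarityScoring(scale_factor=1.0, score_threshold=20)
        for _ in range(10):
            m = rand_rna(r, 15)
            utr = utr_record(rand_rna(r, 20) + revcomp_rna(m[2:12]) + rand_rna(r, 20))
            for s in align_complementarity("mir", m, utr, sc):
                assert s.score == pytest.approx(s.raw_score)

    def test_matches_exhaustive_path_enumeration(self):
        r = random.Random(5)
        sc = ComplementarityScoring()
        for _ in range(40):
            m = rand_rna(r, r.randint(2, 6))
            t = rand_rna(r, r.randint(2, 9))
            res = _best_local_alignment(m[::-1], t, 0, len(t), sc)
            got = res[0] if res else 0.0
            assert got == pytest.approx(
                brute_local_alignment_score(m[::-1], t, sc), abs=1e-9)

    def test_random_utr_below_threshold_gives_nothing(self):
        # a UTR with no pyrimidine cannot pair a purine-free miRNA anywhere
        m = "CCCCCCCCCCCCCCCCCCCCCC"
        utr = utr_record("ACACACACACACACACACACACACACACAC")
        sc = ComplementarityScoring()
        assert align_complementarity("mir", m, utr, sc) == []

    def test_score_invariant_under_flank_shift(self):
        r = random.Random(13)
        m = rand_rna(r, 22)
        site = revcomp_rna(m)
        sc = ComplementarityScoring()
        scores = []
        for pad in (5, 17, 40):
            utr = utr_record(rand_rna(r, pad) + site + rand_rna(r, 60 - pad))
            sites = align_complementarity("mir", m, utr, sc)
            scores.append(max(s.score for s in sites))
        assert scores[0] == scores[1] == scores[2]


def _site_from_symbols(symbols, start_pos=1):
    """AlignedSite whose miRNA positions start at *start_pos*."""
    cols = [(start_pos + i, 100 + i, s) for i, s in enumerate(symbols)]
    mpos = [c[0] for c in cols]
    return AlignedSite("mir", "u", 100, 100 + len(cols) - 1,
                       min(mpos), max(mpos), cols, 0.0, 0.0)


class TestSeedWobbleRule:
    def setup_method(self):
        self.sc = ComplementarityScoring()

    def test_perfect_seed_accepted(self):
        site = _site_from_symbols([PAIR_SYMBOL] * 16, start_pos=1)
        ok, reason = enforce_seed_wobble_rule(site, self.sc)
        assert ok and reason == "ok"

    def test_two_seed_wobbles_rejected(self):
        syms = [PAIR_SYMBOL] * 16
        syms[2] = syms[5] = WOBBLE_SYMBOL  # positions 3 and 6: inside the seed
        ok, reason = enforce_seed_wobble_rule(_site_from_symbols(syms), self.sc)
        assert not ok and reason == "seed wobble count"

    def test_one_wobble_with_three_prime_compensation_accepted(self):
        syms = [PAIR_SYMBOL] * 16
        syms[3] = WOBBLE_SYMBOL  # position 4; positions 13-16 stay Watson-Crick
        ok, _ = enforce_seed_wobble_rule(_site_from_symbols(syms), self.sc)
        assert ok

    def test_one_wobble_without_compensation_rejected(self):
        syms = [PAIR_SYMBOL] * 16
        syms[3] = WOBBLE_SYMBOL
        syms[13] = MISMATCH_SYMBOL  # breaks the 13-16 Watson-Crick run
        ok, reason = enforce_seed_wobble_rule(_site_from_symbols(syms), self.sc)
        assert not ok and reason == "uncompensated seed wobble"

    def test_seed_mismatch_rejected(self):
        syms = [PAIR_SYMBOL] * 16
        syms[4] = MISMATCH_SYMBOL
        ok, reason = enforce_seed_wobble_rule(_site_from_symbols(syms), self.sc)
        assert not ok and reason == "seed mismatch/gap"

    def test_alignment_not_covering_seed_rejected(self):
        # aligned columns start at miRNA position 9: seed 2-8 absent
        site = _site_from_symbols([PAIR_SYMBOL] * 8, start_pos=9)
        ok, reason = enforce_seed_wobble_rule(site, self.sc)
        assert not ok and reason == "seed incomplete"


class TestEnergyFilter:
    def test_planted_perfect_duplex_retained(self, params):
        r = random.Random(17)
        m = rand_rna(r, 22)
        utr = utr_record(rand_rna(r, 20) + revcomp_rna(m) + rand_rna(r, 20))
        sc = ComplementarityScoring()
        sites = align_complementarity("mir", m, utr, sc)
        kept = filter_by_energy(sites, m, utr, params, sc.energy_threshold)
        assert kept and all(s.energy <= -20 for s in kept)
        assert kept[0].genomic is not None

    def test_short_pairing_removed_by_energy(self, params):
        r = random.Random(19)
        m = rand_rna(r, 22)
        # only miRNA positions 1-7 can pair: weak duplex, above -20 kcal/mol
        utr = utr_record(rand_rna(r, 20) + revcomp_rna(m[:7]) + rand_rna(r, 20))
        sc = ComplementarityScoring(score_threshold=20)
        sites = align_complementarity("mir", m, utr, sc)
        assert filter_by_energy(sites, m, utr, params, -20.0) == []

    def test_empty_input_passes_through(self, params):
        utr = utr_record("ACGUACGUACGU")
        assert filter_by_energy([], "ACGUACGU", utr, params) == []
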