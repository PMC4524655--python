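"""Matching engine: reverse complement, budgeted matching, scanning, oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pprescan import (
    MatchPolicy,
    PositionLabel,
    Segment,
    Strand,
    default_scan_policy,
    enumerate_words,
    match_at,
    match_probability,
    motif_cardinality,
    reverse_complement,
    scan_iupac,
    scan_sequence,
)
from pprescan.preference_model import set_from_iupac

H5 = lambda i: PositionLabel(Segment.HEXAD5, i)

iupac_strings = st.text(alphabet="ACGTRYSWKMBDHVN", min_size=1, max_size=30)
dna = st.text(alphabet="ACGT", min_size=0, max_size=60)


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,expected",
        [("AGGTCA", "TGACCT"), ("WAWVT", "ABWTW"), ("N", "N"), ("", "")],
    )
    def test_examples(self, seq, expected):
        assert reverse_complement(seq) == expected

    @settings(deadline=None)
    @given(iupac_strings)
    def test_involution(self, s):
        assert reverse_complement(reverse_complement(s)) == s

    def test_non_iupac_rejected(self):
        with pytest.raises(ValueError):
            reverse_complement("AGX")


class TestMatchAt:
    def test_fig_probe_matches_optimal_exactly(self, optimal_motif):
        r = match_at("AATGTAGGTCAAAGGTCA", 0, optimal_motif, MatchPolicy(budget=0))
        assert r.matched and r.mismatch_positions == ()
        assert r.segments == {
            "ext5": "AATGT",
            "hexad5": "AGGTCA",
            "spacer": "A",
            "hexad3": "AGGTCA",
        }

    def test_cpt1b_core_passes_with_budgeted_mismatch(self, scan_motif, scan_policy):
        r = match_at("AATGTAGGGAAAAGGTCA", 0, scan_motif, scan_policy)
        assert r.matched
        assert r.mismatch_positions == (H5(5),)

    def test_cd36_core_fails_outside_budget(self, scan_motif, scan_policy):
        r = match_at("AATGTAAGTCAGAGGTCA", 0, scan_motif, scan_policy)
        assert not r.matched
        assert H5(2) in r.mismatch_positions

    def test_fatp1_3prime_hexad_fails(self, scan_motif, scan_policy):
        # R+4 admits only T at every tier; AGGAGA can never be rescued
        r = match_at("AATGTAGGGCACAGGAGA", 0, scan_motif, scan_policy)
        assert not r.matched
        assert PositionLabel(Segment.HEXAD3, 4) in r.mismatch_positions

    def test_two_budgeted_mismatches_exceed_budget(self, scan_motif, scan_policy):
        r = match_at("AATGTAGGGAGAAGGTCA", 0, scan_motif, scan_policy)  # +5,+6 both off
        assert not r.matched
        assert set(r.mismatch_positions) == {H5(5), H5(6)}

    def test_sequence_N_is_a_mismatch(self, scan_motif, scan_policy):
        # N at the spacer (motif code N) still mismatches: conservative masking
        r = match_at("AATGTAGGTCANAGGTCA", 0, scan_motif, scan_policy)
        assert r.mismatch_positions == (PositionLabel(Segment.SPACER, 0),)

    def test_window_exceeding_sequence_rejected(self, scan_motif, scan_policy):
        with pytest.raises(ValueError):
            match_at("AATGT", 0, scan_motif, scan_policy)

    def test_case_insensitive(self, optimal_motif):
        r = match_at("aatgtaggtcaaaggtca", 0, optimal_motif, MatchPolicy(budget=0))
        assert r.matched


class TestScanSequence:
    BG = (
        "TCTCCTCTTTCCTCTCTT" * 6
    )  # pyrimidine-rich background with no DR1-like words

    def test_planted_plus_hit(self, optimal_motif):
        site = "AATGTAGGTCAAAGGTCA"
        policy = MatchPolicy(budget=0, strands=Strand.BOTH)
        assert scan_sequence(self.BG[:100], optimal_motif, policy) == []
        seq = self.BG[:10] + site + self.BG[10:82]
        hits = scan_sequence(seq, optimal_motif, policy)
        assert [(h.start, h.strand, h.word) for h in hits] == [(10, "+", site)]
        assert hits[0].end == 28

    def test_planted_minus_hit_reports_plus_coordinates(self, optimal_motif):
        site = "AATGTAGGTCAAAGGTCA"
        policy = MatchPolicy(budget=0, strands=Strand.BOTH)
        seq = self.BG[:40] + reverse_complement(site) + self.BG[40:82]
        hits = scan_sequence(seq, optimal_motif, policy)
        assert [(h.start, h.strand, h.word) for h in hits] == [(40, "-", site)]

    def test_poly_g_has_no_hits(self, optimal_motif, scan_motif, scan_policy):
        policy = MatchPolicy(budget=0, strands=Strand.BOTH)
        assert scan_sequence("G" * 100, optimal_motif, policy) == []
        assert scan_sequence("G" * 100, scan_motif, scan_policy) == []

    def test_strand_filter(self, optimal_motif):
        site = "AATGTAGGTCAAAGGTCA"
        seq = self.BG[:10] + site + self.BG[10:40] + reverse_complement(site) + self.BG[40:80]
        plus = scan_sequence(seq, optimal_motif, MatchPolicy(budget=0, strands=Strand.PLUS))
        minus = scan_sequence(seq, optimal_motif, MatchPolicy(budget=0, strands=Strand.MINUS))
        assert [h.strand for h in plus] == ["+"]
        assert [h.strand for h in minus] == ["-"]

    def test_mask_lowercase_drops_softmasked_hits(self, optimal_motif):
        site = "AATGTAGGTCAAAGGTCA"
        seq = self.BG[:10] + site[:9] + site[9:].lower() + self.BG[10:82]
        policy = MatchPolicy(budget=0, strands=Strand.BOTH)
        assert scan_sequence(seq, optimal_motif, policy) != []
        assert scan_sequence(seq, optimal_motif, policy, mask_lowercase=True) == []

    def test_budget_monotonicity(self, scan_motif):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        prev: set = set()
        for b in (0, 1, 2):
            hits = {
                (h.start, h.strand)
                for h in scan_sequence(seq, scan_motif, default_scan_policy(budget=b))
            }
            assert prev <= hits
            prev = hits

    def test_strand_symmetry_mirror(self, scan_motif, scan_policy):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        L = len(seq)
        fwd = scan_sequence(seq, scan_motif, scan_policy)
        rev = scan_sequence(reverse_complement(seq), scan_motif, scan_policy)
        mirror = {(L - h.end, "-" if h.strand == "+" else "+", h.word) for h in fwd}
        assert {(h.start, h.strand, h.word) for h in rev} == mirror


def brute_force_hits(seq, codes, budget=0, budget_indices=()):
    """Independent oracle: enumerate accepted words, test every window by
    string equality on both strands."""
    accepted = set(enumerate_toy(codes, budget, budget_indices))
    rc_accepted = {reverse_complement(w) for w in accepted}
    n = len(codes)
    out = []
    for i in range(len(seq) - n + 1):
        w = seq[i : i + n]
        if w in accepted:
            out.append((i, "+"))
        if w in rc_accepted:
            out.append((i, "-"))
    return sorted(out)


def enumerate_toy(codes, budget=0, budget_indices=()):
    sets = [sorted(set_from_iupac(c)) for c in codes]
    seen = set()
    for k in range(budget + 1):
        for combo in itertools.combinations(budget_indices, k):
            choices = [
                sorted(set("ACGT") - set(sets[i])) if i in combo else sets[i]
                for i in range(len(sets))
            ]
            for letters in itertools.product(*choices):
                seen.add("".join(letters))
    return seen


class TestOracleEquivalence:
    @pytest.mark.parametrize("codes", ["RGKT", "WSN", "AGGTCA", "BDHV"])
    def test_exhaustive_short_sequences(self, codes):
        n = len(codes) + 2
        for letters in itertools.product("ACGT", repeat=n):
            seq = "".join(letters)
            got = [(h.start, h.strand) for h in scan_iupac(seq, codes)]
            assert sorted(got) == brute_force_hits(seq, codes)

    @pytest.mark.parametrize(
        "codes,budget,budget_indices",
        [("AGGTCA", 1, (3, 4, 5)), ("RGKTYA", 1, (0, 1))],
    )
    def test_random_sequences_with_budget(self, codes, budget, budget_indices):
        rng = np.random.default_rng(17)
        for _ in range(2000):
            seq = "".join(rng.choice(list("ACGT"), size=30))
            got = [
                (h.start, h.strand)
                for h in scan_iupac(seq, codes, budget, budget_indices)
            ]
            assert sorted(got) == brute_force_hits(seq, codes, budget, budget_indices)

    @settings(deadline=None, max_examples=200)
    @given(dna, st.sampled_from(["RGKT", "AGGTCA", "NNW"]))
    def test_property_scan_matches_brute_force(self, seq, codes):
        got = [(h.start, h.strand) for h in scan_iupac(seq, codes)]
        assert sorted(got) == brute_force_hits(seq, codes)


class TestCardinalityAndProbability:
    def test_optimal_cardinality_is_product_of_set_sizes(self, optimal_motif):
        assert motif_cardinality(optimal_motif) == 5184  # 12 * 18 * 3 * 8

    def test_concrete_motif_cardinality_one(self):
        from pprescan import CompositeMotif

        motif = CompositeMotif.from_string("AATGT-AGGTCA-A-AGGTCA")
        assert motif_cardinality(motif) == 1

    def test_toy_NN_cardinality(self):
        assert motif_cardinality("NN") == 16

    def test_budgeted_cardinality_equals_enumeration(self, scan_motif, scan_policy):
        n_enum = sum(1 for _ in enumerate_words(scan_motif, scan_policy))
        assert motif_cardinality(scan_motif, scan_policy) == n_enum

    def test_uniform_probability_is_cardinality_over_4_to_18(self, optimal_motif):
        assert match_probability(optimal_motif) == pytest.approx(5184 / 4**18)

    def test_toy_single_position(self):
        assert match_probability("A") == pytest.approx(0.25)

    def test_gc_skewed_toy_equals_enumeration_weighted_sum(self):
        freqs = {"A": 0.1, "C": 0.4, "G": 0.4, "T": 0.1}
        codes = "RSY"
        expected = sum(
            np.prod([freqs[b] for b in word])
            for word in map("".join, itertools.product("ACGT", repeat=3))
            if all(b in set_from_iupac(c) for b, c in zip(word, codes))
        )
        assert match_probability(codes, base_freqs=freqs) == pytest.approx(expected)

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError):
            match_probability("A", base_freqs={"A": 0.5, "C": 0.2, "G": 0.2, "T": 0.2})

    def test_empirical_hit_rate_within_binomial_interval(self, scan_motif, scan_policy):
        """Hit frequency on uniform random sequence sits inside the 99%
        binomial interval of 2 * p * (L-17) per sequence."""
        from scipy import stats

        rng = np.random.default_rng(23)
        p = match_probability(scan_motif, scan_policy)
        n_seq, L = 400, 1500
        trials = n_seq * (L - 17) * 2
        count = 0
        for _ in range(n_seq):
            seq = "".join(rng.choice(list("ACGT"), size=L))
            count += len(scan_sequence(seq, scan_motif, scan_policy))
        lo, hi = stats.binom.interval(0.99, trials, p)
        assert lo <= count <= hi
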