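import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import jensenshannon

from afdist import (
    DNA,
    ContractError,
    Pattern,
    PatternSet,
    Sequence,
    SpacedWordProfile,
    build_profile,
    distance_matrix,
    euclidean_distance,
    extract_spaced_words,
    format_spaced_word,
    jensen_shannon_distance,
    pairwise_distance,
)

dna_text = st.text(alphabet="ACGT", min_size=1, max_size=60)


def reference_profile(residues: str, pattern: Pattern) -> dict:
    """Independent spaced-word counter: dict of word -> relative frequency."""
    pos = pattern.positions
    words = [
        "".join(residues[i + p] for p in pos)
        for i in range(len(residues) - pattern.length + 1)
    ]
    counts = Counter(words)
    total = sum(counts.values())
    return {w: c / total for w, c in counts.items()}


class TestExtraction:
    def test_worked_example_words_in_order(self, worked_example):
        seq, pat = worked_example
        words = extract_spaced_words(seq, pat)
        assert words == ["ATT", "TTG", "TAC", "ATT", "TGA", "GCG"]
        assert [format_spaced_word(w, pat) for w in words] == [
            "AT**T", "TT**G", "TA**C", "AT**T", "TG**A", "GC**G",
        ]

    def test_sequence_shorter_than_pattern(self):
        assert extract_spaced_words(Sequence("x", "ACG"), Pattern("11001")) == []

    def test_ambiguity_at_match_position_skips_window(self):
        words = extract_spaced_words(Sequence("x", "ANAT"), Pattern("11"), DNA)
        assert words == ["AT"]

    def test_ambiguity_at_dont_care_position_kept(self):
        # N sits at the don't-care of the first window (kept) and at a match
        # position of the second (skipped).
        words = extract_spaced_words(Sequence("x", "ANAT"), Pattern("101"), DNA)
        assert words == ["AA"]


class TestProfiles:
    def test_worked_example_frequencies(self, worked_example):
        seq, pat = worked_example
        prof = build_profile(seq, pat)
        assert prof.total == 6
        assert prof.frequency("ATT") == pytest.approx(2 / 6)
        for w in ("TTG", "TAC", "TGA", "GCG"):
            assert prof.frequency(w) == pytest.approx(1 / 6)
        assert prof.frequency("AAA") == 0.0

    def test_single_word_profile(self):
        prof = build_profile(Sequence("x", "AAAA"), Pattern("11"))
        assert prof.frequencies() == {"AA": 1.0}

    def test_too_short_sequence_is_an_error(self):
        with pytest.raises(ContractError, match="too short"):
            build_profile(Sequence("x", "AC"), Pattern("11001"))

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(residues=st.text(alphabet="ACGT", min_size=5, max_size=80))
    def test_clean_sequence_total_is_window_count(self, residues):
        pat = Pattern("11001")
        prof = build_profile(Sequence("x", residues), pat, DNA)
        assert prof.total == len(residues) - pat.length + 1
        assert sum(prof.frequencies().values()) == pytest.approx(1.0)


def _profile(pattern, counts):
    return SpacedWordProfile(pattern, dict(counts), sum(counts.values()))


class TestEuclidean:
    def test_identity(self, worked_example):
        seq, pat = worked_example
        prof = build_profile(seq, pat)
        assert euclidean_distance(prof, prof) == 0.0

    def test_disjoint_unit_masses(self):
        p = Pattern("11")
        a = _profile(p, {"AA": 1})
        b = _profile(p, {"CC": 1})
        assert euclidean_distance(a, b) == pytest.approx(math.sqrt(2))

    def test_point_mutation_against_reference_counter(self):
        pat = Pattern("11001")
        x, y = "ATTATGCTAG", "ATTATGCTAA"
        fa, fb = reference_profile(x, pat), reference_profile(y, pat)
        keys = set(fa) | set(fb)
        expected = math.sqrt(
            sum((fa.get(k, 0.0) - fb.get(k, 0.0)) ** 2 for k in keys)
        )
        got = euclidean_distance(
            build_profile(Sequence("x", x), pat), build_profile(Sequence("y", y), pat)
        )
        assert got == pytest.approx(expected, abs=1e-12)

    def test_pattern_mismatch_rejected(self):
        a = _profile(Pattern("11"), {"AA": 1})
        b = _profile(Pattern("101"), {"AA": 1})
        with pytest.raises(ContractError):
            euclidean_distance(a, b)


class TestJensenShannon:
    def test_identity(self, worked_example):
        seq, pat = worked_example
        prof = build_profile(seq, pat)
        assert jensen_shannon_distance(prof, prof) == 0.0

    def test_disjoint_supports_maximal(self):
        p = Pattern("11")
        a = _profile(p, {"AA": 3})
        b = _profile(p, {"CC": 2, "GG": 2})
        assert jensen_shannon_distance(a, b) == pytest.approx(1.0)

    def test_closed_form_two_point(self):
        # A=(1,0), B=(0.5,0.5): JS = H(0.75,0.25) - (0 + 1)/2
        p = Pattern("11")
        a = _profile(p, {"AA": 2})
        b = _profile(p, {"AA": 1, "CC": 1})
        expected = (-(0.75 * math.log2(0.75) + 0.25 * math.log2(0.25))) - 0.5
        assert jensen_shannon_distance(a, b) == pytest.approx(expected, abs=1e-12)

    def test_sqrt_variant(self):
        p = Pattern("11")
        a = _profile(p, {"AA": 2})
        b = _profile(p, {"AA": 1, "CC": 1})
        js = jensen_shannon_distance(a, b)
        assert jensen_shannon_distance(a, b, sqrt=True) == pytest.approx(math.sqrt(js))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(xres=dna_text, yres=dna_text)
    def test_matches_scipy_and_stays_in_range(self, xres, yres):
        p = Pattern("11")
        if len(xres) < 2 or len(yres) < 2:
            return
        a = build_profile(Sequence("x", xres), p, DNA)
        b = build_profile(Sequence("y", yres), p, DNA)
        js = jensen_shannon_distance(a, b)
        assert 0.0 <= js <= 1.0
        assert js == pytest.approx(jensen_shannon_distance(b, a), abs=1e-12)
        keys = sorted(set(a.counts) | set(b.counts))
        fa = np.array([a.frequency(k) for k in keys])
        fb = np.array([b.frequency(k) for k in keys])
        assert js == pytest.approx(jensenshannon(fa, fb, base=2) ** 2, abs=1e-9)


class TestPairwiseDistance:
    def test_identical_sequences_zero(self, rng, pattern_set):
        s = Sequence("x", "".join(rng.choice(list("ACGT"), 50)))
        t = Sequence("y", s.residues)
        assert pairwise_distance(s, t, pattern_set) == 0.0

    def test_singleton_set_equals_single_pattern(self, rng):
        x = Sequence("x", "".join(rng.choice(list("ACGT"), 60)))
        y = Sequence("y", "".join(rng.choice(list("ACGT"), 60)))
        p = Pattern("11001")
        single = euclidean_distance(build_profile(x, p, DNA), build_profile(y, p, DNA))
        assert pairwise_distance(x, y, PatternSet([p]), "euclidean") == pytest.approx(
            single
        )

    def test_two_pattern_mean(self, rng):
        x = Sequence("x", "".join(rng.choice(list("ACGT"), 60)))
        y = Sequence("y", "".join(rng.choice(list("ACGT"), 60)))
        p1, p2 = Pattern("11001"), Pattern("111")
        d1 = euclidean_distance(build_profile(x, p1, DNA), build_profile(y, p1, DNA))
        d2 = euclidean_distance(build_profile(x, p2, DNA), build_profile(y, p2, DNA))
        ps = PatternSet([p1, p2])
        assert pairwise_distance(x, y, ps) == pytest.approx((d1 + d2) / 2)

    def test_pattern_order_invariance(self, rng, pattern_set):
        x = Sequence("x", "".join(rng.choice(list("ACGT"), 80)))
        y = Sequence("y", "".join(rng.choice(list("ACGT"), 80)))
        shuffled = PatternSet(list(pattern_set)[::-1])
        assert pairwise_distance(x, y, pattern_set, "js") == pytest.approx(
            pairwise_distance(x, y, shuffled, "js")
        )

    def test_pattern_longer_than_sequence_is_an_error(self):
        x = Sequence("x", "ACG")
        y = Sequence("y", "ACGTACGT")
        with pytest.raises(ContractError, match="11001"):
            pairwise_distance(x, y, PatternSet([Pattern("11001")]))


class TestDistanceMatrix:
    def test_duplicate_sequences_give_zero_matrix(self, pattern_set):
        s = "ACGTACGTACGT"
        seqs = [Sequence(f"s{i}", s) for i in range(3)]
        m = distance_matrix(seqs, pattern_set)
        assert np.all(m.values == 0.0)

    def test_permutation_equivariance(self, rng, pattern_set):
        seqs = [
            Sequence(f"s{i}", "".join(rng.choice(list("ACGT"), 70))) for i in range(4)
        ]
        m = distance_matrix(seqs, pattern_set)
        perm = [2, 0, 3, 1]
        m2 = distance_matrix([seqs[i] for i in perm], pattern_set)
        np.testing.assert_allclose(
            m2.values, m.values[np.ix_(perm, perm)], atol=1e-12
        )

    def test_entries_match_pairwise_calls(self, rng, pattern_set):
        seqs = [
            Sequence(f"s{i}", "".join(rng.choice(list("ACGT"), 70))) for i in range(3)
        ]
        m = distance_matrix(seqs, pattern_set, "js")
        for i in range(3):
            for j in range(3):
                expected = (
                    0.0
                    if i == j
                    else pairwise_distance(seqs[i], seqs[j], pattern_set, "js")
                )
                assert m.values[i, j] == pytest.approx(expected, abs=1e-12)


class TestContiguousEquivalence:
    def test_all_ones_pattern_reproduces_kmer_distances(self, rng):
        """An all-'1' pattern must equal an ordinary k-mer frequency distance."""
        w = 4
        x = "".join(rng.choice(list("ACGT"), 200))
        y = "".join(rng.choice(list("ACGT"), 180))

        def kmer_freqs(s):
            counts = Counter(s[i : i + w] for i in range(len(s) - w + 1))
            total = sum(counts.values())
            return {km: c / total for km, c in counts.items()}

        fa, fb = kmer_freqs(x), kmer_freqs(y)
        keys = set(fa) | set(fb)
        expected = math.sqrt(
            sum((fa.get(k, 0.0) - fb.get(k, 0.0)) ** 2 for k in keys)
        )
        ps = PatternSet([Pattern("1" * w)])
        got = pairwise_distance(Sequence("x", x), Sequence("y", y), ps)
        assert got == pytest.approx(expected, abs=1e-12)
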