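"""TIR/TSD/ORF annotation and the four-way functional classification."""

import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tepaleo as tp
from tepaleo.annotate import Orf, TirAnnotation, conservation_matrix
from tepaleo.simulate import random_sequence


class TestDetectTirs:
    def test_perfect_tirs_found_exactly(self, element):
        tir = tp.detect_tirs(element.sequence)
        assert tir is not None
        assert tir.five_prime == (0, 28)
        assert tir.three_prime == (1300 - 28, 28)
        assert tir.mismatches == 0 and tir.identity == 1.0

    def test_two_substitutions_reduce_identity(self, element):
        seq = list(element.sequence)
        seq[3] = "A" if seq[3] != "A" else "C"
        seq[10] = "A" if seq[10] != "A" else "C"
        tir = tp.detect_tirs("".join(seq))
        assert tir is not None
        assert tir.mismatches == 2
        assert abs(tir.identity - 26 / 28) < 1e-9

    def test_false_positive_rate_on_random_sequence(self):
        hits = 0
        for seed in range(100):
            s = random_sequence(1000, 0.5, np.random.default_rng(seed))
            if tp.detect_tirs(s) is not None:
                hits += 1
        assert hits < 5

    def test_revcomp_swaps_tir_coordinates(self, mite, rng):
        seq = tp.evolve_sequence(mite.sequence, 0.05, seed=rng)
        fwd = tp.detect_tirs(seq)
        rev = tp.detect_tirs(tp.revcomp(seq))
        assert fwd is not None and rev is not None
        assert fwd.mismatches == rev.mismatches
        L = len(seq)
        s5, l5 = fwd.five_prime
        assert rev.three_prime == (L - s5 - l5, l5)

    def test_too_short_sequence_raises(self):
        with pytest.raises(ValueError):
            tp.detect_tirs("ACGTACGT")


class TestDetectTsd:
    def test_ta_duplication_found(self):
        assert tp.detect_tsd("GGGGTA", "TACCCC") == "TA"

    def test_absent_duplication_none(self):
        assert tp.detect_tsd("GGGGGC", "TACCCC") is None

    def test_generalised_target(self):
        assert tp.detect_tsd("XXACGT", "ACGTYY", tsd="ACGT") == "ACGT"

    def test_case_insensitive(self):
        assert tp.detect_tsd("ggta", "taCC") == "TA"


class TestFindOrfs:
    def test_constructed_orf_at_threshold_boundary(self, rng):
        codons = ["ATG"]
        sense = [c for c in ("GCT", "GAA", "TGC", "CTG", "AAA") ]
        for i in range(299):
            codons.append(sense[i % len(sense)])
        codons.append("TAA")
        orf_seq = "".join(codons)
        seq = "TAATAA" + orf_seq + "TAGTAG"
        orfs = tp.find_orfs(seq, min_aa=300)
        assert len(orfs) == 1
        o = orfs[0]
        assert o.aa_length == 300
        assert o.starts_with_methionine
        assert (o.end - o.start) % 3 == 0
        assert o.aa_length == (o.end - o.start - 3) // 3

    def test_short_random_sequence_has_no_long_orf(self, rng):
        s = random_sequence(500, 0.5, rng)
        assert tp.find_orfs(s, min_aa=300) == []

    def test_reverse_frame_orf_reported_on_input_coordinates(self):
        codons = ["ATG"] + ["GCT"] * 30 + ["TAA"]
        fwd = "TAA" + "".join(codons) + "TAA"
        rev = tp.revcomp(fwd)
        orfs = tp.find_orfs(rev, min_aa=30)
        assert any(o.frame < 0 for o in orfs)
        o = next(o for o in orfs if o.frame < 0)
        assert tp.revcomp(rev[o.start : o.end]).startswith("ATG")

    def test_agrees_with_regex_translation_oracle(self, rng):
        """Six-frame oracle: regex over Biopython-style translations."""
        from Bio.Seq import Seq

        for _ in range(30):
            s = random_sequence(2000, 0.5, rng)
            min_aa = 20
            expected = set()
            for strand, seq in (("+", s), ("-", tp.revcomp(s))):
                for off in range(3):
                    frame = seq[off : off + 3 * ((len(seq) - off) // 3)]
                    aa = str(Seq(frame).translate())
                    for m in re.finditer(r"M[^*]*\*", aa):
                        length = m.end() - m.start() - 1
                        if length >= min_aa:
                            # trim to the first M of the span (greedy regex
                            # starts at the first M already)
                            expected.add((strand, off, length))
            got = set()
            for o in tp.find_orfs(s, min_aa=min_aa):
                if not o.has_stop:
                    continue
                strand = "+" if o.frame > 0 else "-"
                off = abs(o.frame) - 1
                got.add((strand, off, o.aa_length))
            # regex is non-overlapping per frame; ours reports the same spans
            for item in expected:
                assert item in got, item


class TestClassifyCopy:
    TIR = TirAnnotation((0, 28), (1272, 28), 0, 1.0)
    ORF = Orf(1, 0, 1053, 350, True)

    def test_four_way_rules(self):
        assert tp.classify_copy(self.TIR, [self.ORF], 1300) == (
            "potential_autonomous", "full_length",
        )
        assert tp.classify_copy(self.TIR, [], 560) == (
            "potential_non_autonomous", "mite",
        )
        assert tp.classify_copy(None, [self.ORF], 1100) == (
            "potential_coding", "partial_size",
        )
        assert tp.classify_copy(None, [], 300) == ("partial", "partial_size")

    def test_300_aa_tie_goes_to_coding(self):
        orf = Orf(1, 0, 903, 300, True)
        assert tp.classify_copy(None, [orf], 1000)[0] == "potential_coding"
        orf299 = Orf(1, 0, 900, 299, True)
        assert tp.classify_copy(None, [orf299], 1000)[0] == "partial"

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            tp.classify_copy(None, [], -1)

    @given(
        has_tir=st.booleans(),
        aa=st.integers(0, 600),
        length=st.integers(0, 3000),
    )
    @settings(max_examples=80, deadline=None)
    def test_classification_is_a_partition(self, has_tir, aa, length):
        tir = self.TIR if has_tir else None
        orfs = [Orf(1, 0, 3 * aa + 3, aa, True)] if aa else []
        functional, size = tp.classify_copy(tir, orfs, length)
        assert functional in (
            "potential_autonomous", "potential_non_autonomous",
            "potential_coding", "partial",
        )
        assert size in ("full_length", "mite", "partial_size")


class TestConservationMatrix:
    def test_uniform_column_has_zero_information(self):
        counts, freqs, ic = conservation_matrix(["A", "C", "G", "T"])
        assert ic[0] == pytest.approx(0.0)

    def test_invariant_column_has_two_bits(self):
        counts, freqs, ic = conservation_matrix(["A", "A", "A"])
        assert ic[0] == pytest.approx(2.0)

    def test_half_half_column_has_one_bit(self):
        counts, freqs, ic = conservation_matrix(["A", "A", "C", "C"])
        assert ic[0] == pytest.approx(1.0)

    def test_gaps_excluded_from_column_total(self):
        counts, freqs, ic = conservation_matrix(["A-", "A-", "AN"])
        assert counts[0].tolist() == [3, 0, 0, 0]
        assert counts[1].sum() == 0

    def test_bounds_and_input_validation(self, rng):
        segs = [random_sequence(40, 0.5, rng) for _ in range(10)]
        _, _, ic = conservation_matrix(segs)
        assert np.all(ic >= 0) and np.all(ic <= 2)
        with pytest.raises(ValueError):
            conservation_matrix(["ACGT"])
        with pytest.raises(ValueError):
            conservation_matrix(["ACGT", "ACG"])
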