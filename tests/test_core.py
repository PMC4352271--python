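"""Normalization layer: signed lengths, left alignment, complex splitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from exindel.core import (
    DictReference,
    IndelRecord,
    NotAnIndelError,
    ReferenceMismatchError,
    indel_key,
    is_frameshift,
    left_align,
    signed_length,
    split_complex,
)

from conftest import apply_indel, leftmost_anchor


class TestSignedLength:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [("A", "AT", 1), ("ACAG", "A", -3), ("AT", "ATTTT", 3), ("GGG", "G", -2)],
    )
    def test_examples(self, ref, alt, expected):
        assert signed_length(ref, alt) == expected

    def test_equal_length_rejected(self):
        with pytest.raises(NotAnIndelError):
            signed_length("A", "A")
        with pytest.raises(NotAnIndelError):
            signed_length("AC", "AG")

    @given(
        ref=st.text(alphabet="ACGT", min_size=1, max_size=8),
        alt=st.text(alphabet="ACGT", min_size=1, max_size=8),
    )
    @settings(derandomize=True, deadline=None)
    def test_antisymmetric(self, ref, alt):
        if len(ref) == len(alt):
            return
        assert signed_length(ref, alt) == -signed_length(alt, ref)


class TestFrameshift:
    @pytest.mark.parametrize(
        "length,expected",
        [(3, False), (1, True), (-84, False), (-1, True), (6, False), (-7, True)],
    )
    def test_examples(self, length, expected):
        assert is_frameshift(length) is expected

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            is_frameshift(0)


class TestLeftAlign:
    def test_deletion_in_homopolymer_run(self):
        # deleting the rightmost T of ACTTTG must re-anchor just left of
        # the run: same haplotype, minimal anchor
        ref = DictReference({"1": "ACTTTG"})
        record = IndelRecord("1", 4, "TT", "T")  # delete the T at pos 5
        aligned = left_align(record, ref)
        assert aligned.pos == 2
        assert (aligned.ref_allele, aligned.alt_allele) == ("CT", "C")
        assert apply_indel("ACTTTG", aligned) == apply_indel("ACTTTG", record)
        assert aligned.pos == leftmost_anchor("ACTTTG", record)

    def test_insertion_in_dinucleotide_run(self):
        seq = "CAGAGT"
        ref = DictReference({"1": seq})
        record = IndelRecord("1", 5, "G", "GAG")  # AG inserted after ...AGAG
        aligned = left_align(record, ref)
        assert aligned.pos == leftmost_anchor(seq, record)
        assert apply_indel(seq, aligned) == apply_indel(seq, record)

    def test_already_leftmost_unchanged(self):
        ref = DictReference({"1": "ACGTACGT"})
        record = IndelRecord("1", 2, "C", "CTT")
        assert left_align(record, ref) == record

    def test_reference_mismatch_raises(self):
        ref = DictReference({"1": "ACGTACGT"})
        with pytest.raises(ReferenceMismatchError):
            left_align(IndelRecord("1", 2, "G", "GT"), ref)

    def test_fuzzed_idempotence_and_haplotype_identity(self, uniform_reference):
        seq = uniform_reference.fetch("1", 0, 60_000)
        rng = np.random.default_rng(42)
        for _ in range(500):
            length = int(rng.choice([-4, -3, -2, -1, 1, 2, 3]))
            pos = int(rng.integers(10, 59_000))
            anchor = seq[pos - 1]
            if length > 0:
                ins = "".join(rng.choice(list("ACGT"), size=length))
                record = IndelRecord("1", pos, anchor, anchor + ins)
            else:
                record = IndelRecord(
                    "1", pos, anchor + seq[pos : pos - length], anchor
                )
            aligned = left_align(record, uniform_reference)
            assert left_align(aligned, uniform_reference) == aligned
            assert apply_indel(seq, aligned) == apply_indel(seq, record)
            assert aligned.pos == leftmost_anchor(seq, record)


class TestSplitComplex:
    def test_pure_snp_yields_no_indel(self):
        snps, indel = split_complex("1", 10, "ACGT", "ATGT")
        assert indel is None
        assert [(s.pos, s.ref_base, s.alt_base) for s in snps] == [(11, "C", "T")]

    def test_already_simple_insertion(self):
        snps, indel = split_complex("1", 7, "A", "ATT")
        assert snps == []
        assert (indel.pos, indel.ref_allele, indel.alt_allele) == (7, "A", "ATT")

    def test_substitution_plus_deletion(self):
        # CTTG -> CAG: one mismatching base plus a net 1 bp deletion
        snps, indel = split_complex("1", 20, "CTTG", "CAG")
        assert indel is not None and indel.length == -1
        assert len(snps) == 1
        # joint application reconstructs the alternate haplotype
        ref_seq = "X" * 19 + "CTTG" + "AAAA"
        hap = apply_indel(ref_seq, indel)
        shift = indel.length
        for s in snps:
            p = s.pos - 1 if s.pos <= indel.pos else s.pos - 1 + shift
            assert hap[p] == s.ref_base
            hap = hap[:p] + s.alt_base + hap[p + 1 :]
        assert hap == "X" * 19 + "CAG" + "AAAA"

    def test_identical_alleles_noop(self):
        assert split_complex("1", 5, "ACG", "ACG") == ([], None)

    def test_fuzzed_reconstruction(self, uniform_reference):
        """Components of random complex events rebuild the haplotype."""
        seq = uniform_reference.fetch("1", 0, 60_000)
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(400):
            pos = int(rng.integers(10, 59_000))
            ref_len = int(rng.integers(1, 7))
            ref = seq[pos - 1 : pos - 1 + ref_len]
            alt = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 7))))
            snps, indel = split_complex("1", pos, ref, alt, uniform_reference)
            expected = seq[: pos - 1] + alt + seq[pos - 1 + ref_len :]
            hap = apply_indel(seq, indel) if indel is not None else seq
            shift = indel.length if indel is not None else 0
            anchor = indel.pos if indel is not None else -1
            for s in snps:
                p = s.pos - 1 if s.pos <= anchor or indel is None else s.pos - 1 + shift
                assert hap[p] == s.ref_base
                hap = hap[:p] + s.alt_base + hap[p + 1 :]
            assert hap == expected
            checked += 1
        assert checked == 400


class TestIndelKey:
    def test_shifted_encodings_share_key(self, uniform_reference):
        seq = uniform_reference.fetch("1", 0, 60_000)
        # build a deletion inside a synthetic run, encoded two ways
        ref = DictReference({"1": seq[:100] + "GTTTTC" + seq[106:]})
        left_rec = IndelRecord("1", 101, "GT", "G")
        right_rec = IndelRecord("1", 104, "TT", "T")
        k1 = indel_key(left_align(left_rec, ref))
        k2 = indel_key(left_align(right_rec, ref))
        assert k1 == k2

    def test_distinct_chromosomes_and_alleles(self):
        a = IndelRecord("1", 50, "A", "AT")
        b = IndelRecord("2", 50, "A", "AT")
        c = IndelRecord("1", 50, "A", "AG")
        assert indel_key(a) != indel_key(b)
        assert indel_key(a) != indel_key(c)


class TestRecordInvariants:
    def test_oversized_allele_rejected(self):
        with pytest.raises(ValueError):
            IndelRecord("1", 5, "A", "A" + "T" * 100)

    def test_complex_allele_pair_rejected(self):
        with pytest.raises(NotAnIndelError):
            IndelRecord("1", 5, "AC", "AGT")

    def test_allele_seq_and_length_agree(self):
        rec = IndelRecord("1", 5, "ACCG", "A")
        assert rec.length == -3
        assert rec.allele_seq == "CCG"
        assert len(rec.allele_seq) == abs(rec.length)
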