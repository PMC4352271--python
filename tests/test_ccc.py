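"""Slippage (CCC) classification and the random length-matched null."""

import numpy as np
import pytest
from scipy.stats import chisquare

from exindel.ccc import (
    ccc_profile,
    classify_ccc,
    repeat_context,
    simulate_random_indels,
    smallest_motif,
)
from exindel.core import DictReference, GenotypeMatrix, IndelRecord, left_align
from exindel.regions import Regions
from exindel.simulate import right_shift

from conftest import ccc_oracle, smallest_period


class TestSmallestMotif:
    @pytest.mark.parametrize(
        "seq,motif",
        [("AGAG", "AG"), ("AAA", "A"), ("AGC", "AGC"), ("CAGCAGCAG", "CAG"),
         ("ACACAC", "AC"), ("T", "T"), ("AAAT", "AAAT")],
    )
    def test_examples(self, seq, motif):
        assert smallest_motif(seq) == motif
        assert smallest_period(seq) == motif  # oracle agrees

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            smallest_motif("AGN")
        with pytest.raises(ValueError):
            smallest_motif("")


class TestClassify:
    def test_homopolymer_insertion_is_ccc(self):
        ref = DictReference({"1": "AAATTGCC"})
        # insert T after the A at pos 3; a T sits immediately right
        rec = IndelRecord("1", 3, "A", "AT")
        assert classify_ccc(rec, ref) == "CCC"

    def test_triplet_contraction_is_ccc(self):
        ref = DictReference({"1": "TTCAGCAGTAA"})
        rec = IndelRecord("1", 2, "TCAG", "T")  # delete first CAG, one remains
        assert classify_ccc(rec, ref) == "CCC"

    def test_non_repeat_insertion_is_nccc(self):
        ref = DictReference({"1": "ACGTACGTAC"})
        rec = IndelRecord("1", 4, "T", "TGTC")  # neither neighbor 3-mer is GTC
        assert classify_ccc(rec, ref) == "NCCC"

    def test_n_in_context_is_ambiguous_nccc(self):
        # right neighbor matches the motif but an N sits in the inspected
        # left window: the verdict must fall back to NCCC (ambiguous)
        ref = DictReference({"1": "ANAGAGC"})
        rec = IndelRecord("1", 2, "N", "NAG")
        ctx = repeat_context(rec, ref)
        assert ctx.ambiguous
        assert ctx.right_adjacent_copy
        assert classify_ccc(rec, ref) == "NCCC"

    def test_motif_copy_bookkeeping(self):
        ref = DictReference({"1": "GGCAGCAGCAGCAGTT"})
        rec = IndelRecord("1", 2, "GCAGCAG", "G")  # delete two CAG copies
        ctx = repeat_context(rec, ref)
        assert ctx.motif == "CAG"
        assert ctx.allele_copies == 2
        assert ctx.is_ccc

    def test_invariant_under_representation_shift(self, small_study):
        """The verdict must not depend on the anchoring of the record."""
        reference = small_study.reference
        checked = 0
        for rec in small_study.truth.loci[:300]:
            shifted = right_shift(rec, reference, steps=3)
            assert classify_ccc(rec, reference) == classify_ccc(
                left_align(shifted, reference), reference
            )
            if shifted.pos != rec.pos:
                checked += 1
        assert checked > 10  # some records actually moved

    def test_agrees_with_tandem_scan_oracle(self, small_study):
        reference = small_study.reference
        seq = reference.fetch("1", 0, reference.length("1"))
        for rec in small_study.truth.loci:
            assert (classify_ccc(rec, reference) == "CCC") == ccc_oracle(rec, seq), rec

    def test_planted_ccc_fraction_recovered(self, small_study):
        flags = np.array(
            [classify_ccc(r, small_study.reference) == "CCC"
             for r in small_study.truth.loci]
        )
        planted = small_study.truth_ccc_flags
        # construction guarantees CCC plants classify CCC; NCCC rejections
        # guarantee the converse
        assert np.array_equal(flags, planted)
        assert abs(flags.mean() - small_study.config.ccc_fraction) < 0.02


class TestProfile:
    def _matrix(self, records, genotypes):
        return GenotypeMatrix(
            records, [f"S{i}" for i in range(genotypes.shape[1])], genotypes
        )

    def test_population_split(self):
        ref = DictReference({"1": "AATTGCGTACCGGATCGATCGA" * 4})
        ccc_ins = [IndelRecord("1", 1, "A", "AA"), IndelRecord("1", 3, "T", "TT")]
        nccc_del = [
            IndelRecord("1", 5, "GC", "G"),
            IndelRecord("1", 8, "TA", "T"),
        ]
        records = ccc_ins + nccc_del
        flags = [classify_ccc(r, ref) for r in records]
        assert flags == ["CCC", "CCC", "NCCC", "NCCC"]
        gts = np.ones((4, 2), dtype=np.int8)
        pop, ind = ccc_profile(self._matrix(records, gts), ref)
        assert pop.ccc_insertion_pct == pytest.approx(50.0)
        assert pop.nccc_deletion_pct == pytest.approx(50.0)
        assert pop.ccc_deletion_pct == pop.nccc_insertion_pct == 0.0

    def test_single_carrier_individual_equals_population(self):
        ref = DictReference({"1": "AATTGCGTACCGGATCGATCGA" * 4})
        records = [IndelRecord("1", 1, "A", "AA"), IndelRecord("1", 5, "GC", "G")]
        gts = np.array([[1], [1]], dtype=np.int8)
        pop, ind = ccc_profile(self._matrix(records, gts), ref)
        assert pop == ind

    def test_empty_rejected(self):
        ref = DictReference({"1": "ACGT"})
        with pytest.raises(ValueError):
            ccc_profile(self._matrix([], np.zeros((0, 1), dtype=np.int8)), ref)


class TestRandomIndels:
    def test_length_histogram_matches_input(self, uniform_reference):
        targets = Regions([("1", 100, 59_000)])
        hist = {-3: 0.2, -1: 0.4, 1: 0.3, 2: 0.1}
        calls = simulate_random_indels(hist, targets, uniform_reference,
                                       n=10_000, seed=5)
        lengths, counts = np.unique([c.length for c in calls], return_counts=True)
        expected = np.array([hist[int(l)] * 10_000 for l in lengths])
        assert chisquare(counts, expected).pvalue > 0.01

    def test_zero_n_empty(self, uniform_reference):
        targets = Regions([("1", 100, 1000)])
        assert simulate_random_indels({1: 1.0}, targets, uniform_reference,
                                      n=0, seed=1) == []

    def test_deletions_stay_inside_targets_and_match_reference(
        self, uniform_reference
    ):
        targets = Regions([("1", 100, 2000), ("1", 3000, 4000)])
        calls = simulate_random_indels({-4: 1.0}, targets, uniform_reference,
                                       n=300, seed=2)
        seq = uniform_reference.fetch("1", 0, 60_000)
        for rec in calls:
            assert seq[rec.pos - 1 : rec.pos + 4] == rec.ref_allele

    def test_reproducible_by_seed(self, uniform_reference):
        targets = Regions([("1", 100, 59_000)])
        a = simulate_random_indels({1: 0.6, -1: 0.4}, targets,
                                   uniform_reference, n=200, seed=9)
        b = simulate_random_indels({1: 0.6, -1: 0.4}, targets,
                                   uniform_reference, n=200, seed=9)
        assert a == b

    def test_one_bp_insertion_null_rate_near_seven_sixteenths(
        self, uniform_reference
    ):
        # closed form: P(either neighbor equals the inserted base)
        # = 1 - (3/4)^2 = 7/16 on an i.i.d. uniform reference
        targets = Regions([("1", 100, 59_000)])
        calls = simulate_random_indels({1: 1.0}, targets, uniform_reference,
                                       n=12_000, seed=3)
        rate = np.mean(
            [classify_ccc(r, uniform_reference) == "CCC" for r in calls]
        )
        se = np.sqrt(7 / 16 * 9 / 16 / 12_000)
        assert abs(rate - 7 / 16) < 4 * se
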