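"""Canonical short-INDEL representation and normalization.

Every downstream stage (union merging, consensus scoring, slippage
classification, validation matching) operates on :class:`IndelRecord`
objects in VCF anchored convention: ``pos`` is the 1-based coordinate of
the anchor base preceding the inserted/deleted sequence, ``ref_allele``
and ``alt_allele`` both include that anchor base, and exactly one of the
two alleles has length 1 (pure INDELs only — complex events are split
before reaching this layer).

Two call sets agree on an allele iff their records have equal
:func:`indel_key` after left-alignment, so normalization correctness is
the foundation of the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AUTOSOMES",
    "MAX_INDEL_LENGTH",
    "IndelRecord",
    "GenotypeMatrix",
    "DictReference",
    "NotAnIndelError",
    "ReferenceMismatchError",
    "signed_length",
    "is_frameshift",
    "left_align",
    "split_complex",
    "indel_key",
    "is_autosome",
]

#: Autosome names accepted for pipeline output (with or without "chr" prefix).
AUTOSOMES = frozenset(str(i) for i in range(1, 23)) | frozenset(
    f"chr{i}" for i in range(1, 23)
)

#: Alleles at or above this absolute length are structural, not short INDELs.
MAX_INDEL_LENGTH = 100

_VALID_BASES = frozenset("ACGTN")


class NotAnIndelError(ValueError):
    """Raised when a ref/alt pair does not describe a length change."""


class ReferenceMismatchError(ValueError):
    """Raised when a record's ref allele disagrees with the reference genome."""


def is_autosome(chrom: str) -> bool:
    return chrom in AUTOSOMES


def signed_length(ref_allele: str, alt_allele: str) -> int:
    """Signed length of an INDEL: insertions positive, deletions negative.

    Raises :class:`NotAnIndelError` for equal-length alleles (SNP/MNP/ref).
    """
    if not ref_allele or not alt_allele:
        raise ValueError("alleles must be non-empty")
    for allele in (ref_allele, alt_allele):
        bad = set(allele.upper()) - _VALID_BASES
        if bad:
            raise ValueError(f"invalid bases {sorted(bad)} in allele {allele!r}")
    length = len(alt_allele) - len(ref_allele)
    if length == 0:
        raise NotAnIndelError(
            f"ref {ref_allele!r} / alt {alt_allele!r} have equal length"
        )
    return length


def is_frameshift(length: int) -> bool:
    """True iff the allele length is not a multiple of three bases."""
    if length == 0:
        raise ValueError("length 0 is not an INDEL")
    return length % 3 != 0


@dataclass
class IndelRecord:
    """One normalized INDEL allele.

    ``caller_support`` and ``caller_quals`` carry provenance through the
    union merge; they are empty for truth-set or simulated records.
    """

    chrom: str
    pos: int  # 1-based anchor base position
    ref_allele: str
    alt_allele: str
    caller_support: frozenset[str] = frozenset()
    caller_quals: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ref_allele = self.ref_allele.upper()
        self.alt_allele = self.alt_allele.upper()
        length = signed_length(self.ref_allele, self.alt_allele)
        if min(len(self.ref_allele), len(self.alt_allele)) != 1:
            raise NotAnIndelError(
                "not a pure INDEL (neither allele is a single anchor base): "
                f"{self.ref_allele!r}/{self.alt_allele!r}"
            )
        if self.ref_allele[0] != self.alt_allele[0]:
            raise NotAnIndelError(
                "alleles do not share an anchor base: "
                f"{self.ref_allele!r}/{self.alt_allele!r}"
            )
        if abs(length) >= MAX_INDEL_LENGTH:
            raise ValueError(f"|length| {abs(length)} >= {MAX_INDEL_LENGTH} bp")

    @property
    def length(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)

    @property
    def allele_seq(self) -> str:
        """The inserted or deleted bases, without the anchor."""
        longer = self.alt_allele if self.length > 0 else self.ref_allele
        return longer[1:]

    @property
    def is_insertion(self) -> bool:
        return self.length > 0

    @property
    def is_deletion(self) -> bool:
        return self.length < 0

    def key(self) -> tuple[str, int, str, str]:
        return indel_key(self)


def indel_key(record: IndelRecord) -> tuple[str, int, str, str]:
    """Matching key (chrom, pos, ref, alt) for a left-aligned record.

    Records from different callers denote the same allele iff their keys
    are equal after :func:`left_align`.
    """
    return (record.chrom, record.pos, record.ref_allele, record.alt_allele)


class DictReference:
    """In-memory reference genome backed by plain strings.

    Implements the minimal ``fetch(chrom, start0, end0)`` interface
    (0-based half-open, clipped at contig edges) shared with the
    pysam-backed file reader.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {c: s.upper() for c, s in sequences.items()}

    @property
    def contigs(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start0: int, end0: int) -> str:
        seq = self._seqs[chrom]
        return seq[max(start0, 0) : max(end0, 0)]

    def base(self, chrom: str, pos1: int) -> str:
        """Single base at a 1-based position, '' outside the contig."""
        return self.fetch(chrom, pos1 - 1, pos1)


def _check_reference(record: IndelRecord, reference) -> None:
    expected = reference.fetch(
        record.chrom, record.pos - 1, record.pos - 1 + len(record.ref_allele)
    ).upper()
    if expected != record.ref_allele:
        raise ReferenceMismatchError(
            f"{record.chrom}:{record.pos} ref allele {record.ref_allele!r} "
            f"!= reference {expected!r}"
        )


def left_align(record: IndelRecord, reference, max_shift: int = 300) -> IndelRecord:
    """Shift an INDEL to its leftmost equivalent anchored representation.

    A pure INDEL anchored at ``pos`` with event sequence ``S`` is
    equivalent to one anchored at ``pos - 1`` with sequence
    ``ref[pos] + S[:-1]`` whenever the anchor base equals the last base
    of ``S`` (rotating the event leftward preserves the alternate
    haplotype). Shifting repeats until that condition fails, the contig
    start is reached, an ``N`` blocks the window, or ``max_shift`` steps
    have been taken. Idempotent.
    """
    _check_reference(record, reference)
    pos = record.pos
    seq = record.allele_seq
    if "N" in seq:
        return record  # ambiguous event sequence: leave representation as-is
    shifted = 0
    while shifted < max_shift and pos > 1:
        anchor = reference.fetch(record.chrom, pos - 1, pos).upper()
        if anchor != seq[-1] or anchor == "N":
            break
        seq = anchor + seq[:-1]
        pos -= 1
        shifted += 1
    if pos == record.pos:
        return record
    anchor = reference.fetch(record.chrom, pos - 1, pos).upper()
    if record.is_deletion:
        ref_allele, alt_allele = anchor + seq, anchor
    else:
        ref_allele, alt_allele = anchor, anchor + seq
    return replace(record, pos=pos, ref_allele=ref_allele, alt_allele=alt_allele)


@dataclass(frozen=True)
class SnpComponent:
    """A mismatching aligned base emitted by complex-event splitting."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str


def split_complex(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    reference=None,
    caller_support: frozenset[str] = frozenset(),
    caller_quals: Mapping[str, float] | None = None,
) -> tuple[list[SnpComponent], IndelRecord | None]:
    """Decompose a complex ref/alt pair into SNPs plus at most one pure INDEL.

    End-anchored trimming: equal bases are trimmed from both ends, the
    remaining cores are aligned from their right edge (placing the
    length difference as far left as possible, consistent with left
    alignment), mismatching aligned bases become :class:`SnpComponent` s,
    and the length difference becomes one INDEL anchored at the base
    preceding the cores. Applying all components jointly reconstructs
    the alternate haplotype.

    ``reference`` is consulted only when the INDEL needs an anchor base
    that neither allele provides (no common prefix); downstream the SNP
    components are discarded — this pipeline is INDEL-only.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        return [], None
    # trim common suffix, then common prefix (tracking the position offset)
    n_suffix = 0
    while (
        n_suffix < min(len(ref), len(alt))
        and ref[len(ref) - 1 - n_suffix] == alt[len(alt) - 1 - n_suffix]
    ):
        n_suffix += 1
    r_core = ref[: len(ref) - n_suffix]
    a_core = alt[: len(alt) - n_suffix]
    n_prefix = 0
    while (
        n_prefix < min(len(r_core), len(a_core))
        and r_core[n_prefix] == a_core[n_prefix]
    ):
        n_prefix += 1
    r_core, a_core = r_core[n_prefix:], a_core[n_prefix:]
    core_start = pos + n_prefix  # 1-based position of first core ref base

    r_len, a_len = len(r_core), len(a_core)
    k = min(r_len, a_len)
    if r_len == a_len:
        snps = [
            SnpComponent(chrom, core_start + i, r_core[i], a_core[i])
            for i in range(k)
            if r_core[i] != a_core[i]
        ]
        return snps, None  # SNP/MNP only

    # align the last k bases of each core; the leading excess is the INDEL
    excess = r_len - k if r_len > k else a_len - k
    snp_ref_offset = r_len - k  # where R's aligned tail starts
    snps = [
        SnpComponent(
            chrom,
            core_start + snp_ref_offset + i,
            r_core[snp_ref_offset + i],
            a_core[a_len - k + i],
        )
        for i in range(k)
        if r_core[snp_ref_offset + i] != a_core[a_len - k + i]
    ]
    event_seq = r_core[:excess] if r_len > a_len else a_core[:excess]
    anchor_pos = core_start - 1
    if n_prefix > 0:
        anchor_base = ref[n_prefix - 1]
    elif reference is not None:
        anchor_base = reference.fetch(chrom, anchor_pos - 1, anchor_pos).upper()
        if len(anchor_base) != 1:
            raise ValueError(f"no anchor base available at {chrom}:{anchor_pos}")
    else:
        raise ValueError(
            f"{chrom}:{pos} {ref}/{alt}: INDEL component needs a reference "
            "anchor base but no reference was provided"
        )
    if len(r_core) > k:
        ref_allele, alt_allele = anchor_base + event_seq, anchor_base
    else:
        ref_allele, alt_allele = anchor_base, anchor_base + event_seq
    indel = IndelRecord(
        chrom,
        anchor_pos,
        ref_allele,
        alt_allele,
        caller_support=caller_support,
        caller_quals=dict(caller_quals or {}),
    )
    return snps, indel


# genotype codes in GenotypeMatrix arrays
GT_MISSING = -1
GT_HOM_REF = 0
GT_HET = 1
GT_HOM_ALT = 2


class GenotypeMatrix:
    """Per-sample genotypes plus read evidence for an ordered set of loci.

    ``genotypes`` is an (n_loci, n_samples) int8 array coded 0 = 0/0,
    1 = 0/1, 2 = 1/1, -1 = missing. ``depth`` and ``variant_reads`` are
    optional int arrays of the same shape.
    """

    def __init__(
        self,
        loci: Sequence[IndelRecord],
        samples: Sequence[str],
        genotypes: np.ndarray,
        depth: np.ndarray | None = None,
        variant_reads: np.ndarray | None = None,
    ):
        self.loci = list(loci)
        self.samples = list(samples)
        self.genotypes = np.asarray(genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.loci), len(self.samples)):
            raise ValueError("genotype array shape does not match loci × samples")
        self.depth = None if depth is None else np.asarray(depth, dtype=np.int64)
        self.variant_reads = (
            None if variant_reads is None else np.asarray(variant_reads, dtype=np.int64)
        )
        if (
            self.depth is not None
            and self.variant_reads is not None
            and np.any(self.variant_reads > self.depth)
        ):
            raise ValueError("variant_reads exceeds depth")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def keys(self) -> list[tuple[str, int, str, str]]:
        return [indel_key(r) for r in self.loci]

    def carriers(self, locus_index: int) -> np.ndarray:
        """Indices of samples with a non-reference genotype at a locus."""
        row = self.genotypes[locus_index]
        return np.flatnonzero(row > 0)

    def subset_loci(self, indices: Iterable[int]) -> "GenotypeMatrix":
        idx = np.fromiter(indices, dtype=np.int64)
        return GenotypeMatrix(
            [self.loci[i] for i in idx],
            self.samples,
            self.genotypes[idx],
            None if self.depth is None else self.depth[idx],
            None if self.variant_reads is None else self.variant_reads[idx],
        )
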