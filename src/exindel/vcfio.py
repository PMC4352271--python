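"""File-format adapters: VCF read/write, FASTA, evidence tables.

VCF ingest performs the full normalization contract at the boundary:
multi-allelic lines are decomposed into one candidate per alternate
allele, complex events are split (SNP components discarded), records
are left-aligned against the reference, and non-INDELs and alleles of
|length| >= 100 bp are dropped. Every VCF written here is sorted and
re-parseable with no record loss.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pysam

from .core import (
    GT_MISSING,
    GenotypeMatrix,
    IndelRecord,
    MAX_INDEL_LENGTH,
    NotAnIndelError,
    split_complex,
    left_align,
)

logger = logging.getLogger("exindel")

__all__ = [
    "FastaReference",
    "write_reference_fasta",
    "read_callset",
    "write_callset_vcf",
    "write_genotype_vcf",
    "read_evidence_tsv",
    "write_evidence_tsv",
]


class FastaReference:
    """Indexed FASTA reader with the shared fetch interface."""

    def __init__(self, path: str | Path):
        self._fa = pysam.FastaFile(str(path))

    @property
    def contigs(self) -> list[str]:
        return list(self._fa.references)

    def length(self, chrom: str) -> int:
        return self._fa.get_reference_length(chrom)

    def fetch(self, chrom: str, start0: int, end0: int) -> str:
        n = self._fa.get_reference_length(chrom)
        return self._fa.fetch(chrom, max(start0, 0), min(max(end0, 0), n)).upper()

    def base(self, chrom: str, pos1: int) -> str:
        return self.fetch(chrom, pos1 - 1, pos1)


def write_reference_fasta(reference, path: str | Path, width: int = 70) -> None:
    """Write a reference to FASTA and build its .fai index."""
    path = Path(path)
    with open(path, "w") as fh:
        for chrom in reference.contigs:
            fh.write(f">{chrom}\n")
            seq = reference.fetch(chrom, 0, reference.length(chrom))
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    pysam.faidx(str(path))


def _alt_count(gt: tuple, allele_index: int) -> int:
    if gt is None or all(a is None for a in gt):
        return GT_MISSING
    return sum(1 for a in gt if a == allele_index)


def read_callset(
    vcf_path: str | Path,
    reference,
    caller: str | None = None,
) -> tuple[list[IndelRecord], dict, list[str]]:
    """Parse and normalize one VCF into INDEL records plus genotypes.

    Returns (records, genotypes, samples) where ``genotypes`` maps each
    record's indel key to an int8 array of per-sample alternate-allele
    counts (-1 missing). Multi-allelics are decomposed, complex events
    split, records left-aligned; SNPs and |length| >= 100 alleles are
    dropped (logged). Contigs absent from the reference are an error.
    """
    vcf = pysam.VariantFile(str(vcf_path))
    samples = list(vcf.header.samples)
    contigs = set(reference.contigs)
    records: list[IndelRecord] = []
    genotypes: dict = {}
    n_dropped = 0
    for line_no, variant in enumerate(vcf.fetch() if vcf.index else vcf, 1):
        if variant.chrom not in contigs:
            raise ValueError(
                f"{vcf_path}: contig {variant.chrom!r} absent from the reference"
            )
        if variant.alts is None:
            continue
        qual = variant.qual
        for alt_index, alt in enumerate(variant.alts, start=1):
            if alt is None or alt.startswith("<") or "*" in alt:
                continue
            try:
                _, indel = split_complex(
                    variant.chrom,
                    variant.pos,
                    variant.ref,
                    alt,
                    reference=reference,
                    caller_support=frozenset([caller] if caller else []),
                    caller_quals={caller: qual} if caller else {},
                )
            except NotAnIndelError:
                n_dropped += 1
                continue
            except ValueError as exc:
                if "length" in str(exc):
                    n_dropped += 1
                    logger.info("%s: dropped oversized allele: %s", vcf_path, exc)
                    continue
                raise ValueError(
                    f"{vcf_path} line {line_no}: {exc}"
                ) from exc
            if indel is None:
                n_dropped += 1
                continue
            indel = left_align(indel, reference)
            if abs(indel.length) >= MAX_INDEL_LENGTH:
                n_dropped += 1
                continue
            records.append(indel)
            if samples:
                codes = np.array(
                    [
                        _alt_count(variant.samples[s].get("GT"), alt_index)
                        for s in samples
                    ],
                    dtype=np.int8,
                )
                genotypes[indel.key()] = codes
    if n_dropped:
        logger.info("%s: dropped %d non-INDEL/oversized alleles", vcf_path, n_dropped)
    return records, genotypes, samples


def _base_header(reference, samples=()) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom in reference.contigs:
        header.contigs.add(chrom, length=reference.length(chrom))
    header.formats.add("GT", 1, "String", "Genotype")
    for sample in samples:
        header.add_sample(sample)
    return header


def write_callset_vcf(
    records,
    reference,
    path: str | Path,
    info_fields: dict | None = None,
) -> None:
    """Write site-only records with optional per-key INFO annotations.

    ``info_fields`` maps an INFO tag to {"meta": (number, type, descr),
    "values": {key: value}}.
    """
    header = _base_header(reference)
    info_fields = info_fields or {}
    for tag, spec in info_fields.items():
        header.info.add(tag, *spec["meta"])
    out = pysam.VariantFile(str(path), "w", header=header)
    for rec in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref_allele, r.alt_allele)):
        v = out.new_record(
            contig=rec.chrom,
            start=rec.pos - 1,
            alleles=(rec.ref_allele, rec.alt_allele),
        )
        for tag, spec in info_fields.items():
            value = spec["values"].get(rec.key())
            if value is not None:
                v.info[tag] = value
        out.write(v)
    out.close()


_GT_TUPLES = {GT_MISSING: (None, None), 0: (0, 0), 1: (0, 1), 2: (1, 1)}


def write_genotype_vcf(
    matrix: GenotypeMatrix,
    reference,
    path: str | Path,
    info_fields: dict | None = None,
) -> None:
    """Write a genotype matrix as a multi-sample VCF with GT."""
    header = _base_header(reference, matrix.samples)
    info_fields = info_fields or {}
    for tag, spec in info_fields.items():
        header.info.add(tag, *spec["meta"])
    out = pysam.VariantFile(str(path), "w", header=header)
    order = sorted(
        range(matrix.n_loci),
        key=lambda i: (matrix.loci[i].chrom, matrix.loci[i].pos,
                       matrix.loci[i].ref_allele, matrix.loci[i].alt_allele),
    )
    for i in order:
        rec = matrix.loci[i]
        v = out.new_record(
            contig=rec.chrom,
            start=rec.pos - 1,
            alleles=(rec.ref_allele, rec.alt_allele),
        )
        for tag, spec in info_fields.items():
            value = spec["values"].get(rec.key())
            if value is not None:
                v.info[tag] = value
        for s, sample in enumerate(matrix.samples):
            v.samples[sample]["GT"] = _GT_TUPLES[int(matrix.genotypes[i, s])]
        out.write(v)
    out.close()


def write_evidence_tsv(evidences, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tpos\tref\talt\tvariant_reads\ttotal_reads"
            "\tmean_base_quality\tdesign_failed\n"
        )
        for e in evidences:
            s = e.site
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.ref_allele}\t{s.alt_allele}\t"
                f"{e.variant_reads}\t{e.total_reads}\t"
                f"{e.mean_base_quality:.3f}\t{int(e.design_failed)}\n"
            )


def read_evidence_tsv(path: str | Path):
    from .validation import ValidationEvidence

    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            site = IndelRecord(f[idx["chrom"]], int(f[idx["pos"]]),
                               f[idx["ref"]], f[idx["alt"]])
            out.append(
                ValidationEvidence(
                    site=site,
                    variant_reads=int(f[idx["variant_reads"]]),
                    total_reads=int(f[idx["total_reads"]]),
                    mean_base_quality=float(f[idx["mean_base_quality"]]),
                    design_failed=bool(int(f[idx["design_failed"]])),
                )
            )
    return out
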