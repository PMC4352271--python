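"""Merge per-caller call sets into an annotated union.

The union is the high-sensitivity / low-specificity starting point of
the consensus procedure: every distinct normalized allele reported by at
least one caller, restricted to autosomes and to the exome target
regions, annotated with which callers reported it and with a
scale-free summary of the quality scores they assigned.

Caller quality scores live on incomparable, heavy-tailed scales
(phred-like, odds-like, ad hoc), so they are made comparable by a
per-caller rank transform to the empirical CDF in (0, 1] before
averaging across supporting callers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .core import IndelRecord, is_autosome
from .regions import Regions

__all__ = ["UnionRecord", "ReadEvidence", "normalize_qualities", "merge_union"]


@dataclass
class UnionRecord:
    """One union allele with its cross-caller support annotation."""

    indel: IndelRecord
    n_callers: int
    norm_qual_mean: float  # mean per-caller ECDF quality, in (0, 1]
    site_depth: float = 0.0  # mean total depth over carrier samples
    variant_read_ratio: float = 0.0  # aggregate alt reads / aggregate depth

    def key(self):
        return self.indel.key()


@dataclass
class ReadEvidence:
    """Per-site read support aggregated over carrier samples.

    ``depth`` and ``variant_reads`` map an indel key to per-carrier read
    counts; produced by the synthetic generator or extracted from VCF
    DP/AD fields at ingest.
    """

    depth: dict
    variant_reads: dict

    def site_summary(self, key) -> tuple[float, float]:
        d = np.asarray(self.depth.get(key, ()), dtype=float)
        v = np.asarray(self.variant_reads.get(key, ()), dtype=float)
        if d.size == 0 or d.sum() == 0:
            return 0.0, 0.0
        return float(d.mean()), float(v.sum() / d.sum())


def normalize_qualities(qualities) -> np.ndarray:
    """Rank-transform one caller's quality scores to ECDF values in (0, 1].

    Ties share the mean rank; a missing (None/NaN) quality is flagged by
    assignment to 0.5, the median prior. A single-record call set maps
    to [1.0].
    """
    quals = np.array(
        [np.nan if q is None else float(q) for q in qualities], dtype=float
    )
    if quals.size == 0:
        return quals
    out = np.full(quals.size, 0.5)
    ok = ~np.isnan(quals)
    if ok.any():
        out[ok] = rankdata(quals[ok], method="average") / ok.sum()
    return out


def merge_union(
    callsets: dict[str, list[IndelRecord]],
    target_regions: Regions | None = None,
    evidence: ReadEvidence | None = None,
) -> list[UnionRecord]:
    """Merge normalized per-caller call sets into one union call set.

    Each input list must already be normalized (complex events split,
    left-aligned); records are matched across callers by indel key. One
    :class:`UnionRecord` is emitted per distinct key whose anchor base
    lies on an autosome and (if ``target_regions`` is given) inside a
    target interval. Quality normalization is computed per caller over
    that caller's *kept* records, then averaged over supporting callers.
    """
    if not callsets:
        raise ValueError("at least one call set is required")

    kept: dict[str, list[IndelRecord]] = {}
    for caller, records in callsets.items():
        kept[caller] = [
            r
            for r in records
            if is_autosome(r.chrom)
            and (target_regions is None or target_regions.contains(r.chrom, r.pos))
        ]

    # per-caller ECDF quality per key
    norm_qual: dict[str, dict] = {}
    for caller, records in kept.items():
        quals = [r.caller_quals.get(caller) for r in records]
        ecdf = normalize_qualities(quals)
        norm_qual[caller] = {r.key(): q for r, q in zip(records, ecdf)}

    merged: dict[tuple, dict] = {}
    for caller, records in kept.items():
        for record in records:
            key = record.key()
            entry = merged.setdefault(key, {"record": record, "callers": {}, "raw": {}})
            entry["callers"][caller] = norm_qual[caller][key]
            raw = record.caller_quals.get(caller)
            entry["raw"][caller] = float("nan") if raw is None else float(raw)

    out: list[UnionRecord] = []
    for key in sorted(merged, key=lambda k: (k[0], k[1], k[2], k[3])):
        entry = merged[key]
        callers = entry["callers"]
        base = entry["record"]
        indel = IndelRecord(
            base.chrom,
            base.pos,
            base.ref_allele,
            base.alt_allele,
            caller_support=frozenset(callers),
            caller_quals=dict(entry["raw"]),
        )
        site_depth, vr_ratio = (0.0, 0.0)
        if evidence is not None:
            site_depth, vr_ratio = evidence.site_summary(key)
        out.append(
            UnionRecord(
                indel=indel,
                n_callers=len(callers),
                norm_qual_mean=float(np.mean(list(callers.values()))),
                site_depth=site_depth,
                variant_read_ratio=vr_ratio,
            )
        )
    return out
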