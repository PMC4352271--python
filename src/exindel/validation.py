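"""Validation matching rules, site-status classification, and summary
formulas for evaluating INDEL call sets against orthogonal evidence.

A validated site is assessed from amplicon-resequencing style evidence
(variant reads, total reads, mean base quality) with stricter thresholds
for 1-bp INDELs, which are the dominant artifact mode:

===============  ==========  ===========
quantity         >1 bp        1 bp
===============  ==========  ===========
confirm ratio    >= 20%       >= 40%
confirm quality  >= 10        >= 20
FP ratio         < 3%         < 5%
min coverage     20 reads     20 reads
===============  ==========  ===========

Ratios between the FP and confirmation thresholds are AMBIGUOUS; design
failure or <20 reads is FAILED (no conclusion). From the resulting
tallies: FDR = FP / (TP + FP), relative sensitivity of the consensus =
TP_consensus / TP_union, and the number of INDELs actually detectable
in the data is TP_union + (AMBG_consensus + FAIL_consensus) x
(1 - S_consensus).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .core import IndelRecord
from .popstats import af_bin

__all__ = [
    "Status",
    "ValidationEvidence",
    "ValidationCounts",
    "match_indel",
    "validation_status",
    "tally",
    "estimate_fdr",
    "relative_sensitivity",
    "detectable_indels",
    "insilico_rates",
    "select_validation_sites",
]


class Status(str, Enum):
    CONFIRMED = "CONFIRMED"
    FALSE_POSITIVE = "FALSE_POSITIVE"
    AMBIGUOUS = "AMBIGUOUS"
    FAILED = "FAILED"


@dataclass
class ValidationEvidence:
    """Read evidence for one validated site."""

    site: IndelRecord
    variant_reads: int
    total_reads: int
    mean_base_quality: float
    design_failed: bool = False

    def __post_init__(self):
        if self.variant_reads > self.total_reads:
            raise ValueError("variant_reads exceeds total_reads")


@dataclass
class ValidationCounts:
    """TP/FP/ambiguous/failed tallies for one call-set scope."""

    TP: int
    FP: int
    AMBG: int
    FAIL: int
    scope: str = ""

    @property
    def assessed(self) -> int:
        return self.TP + self.FP + self.AMBG + self.FAIL


def match_indel(candidate: IndelRecord, validated: IndelRecord) -> bool:
    """Positional matching of a candidate against a validated INDEL.

    True iff both records are on the same chromosome, have the exact
    same signed length, and their anchors lie within 30 bp of each
    other (5 bp for 1-bp INDELs).
    """
    if candidate.chrom != validated.chrom:
        return False
    if candidate.length != validated.length:
        return False
    window = 5 if abs(candidate.length) == 1 else 30
    return abs(candidate.pos - validated.pos) <= window


def validation_status(evidence: ValidationEvidence) -> Status:
    """Classify one validated site from its read evidence.

    FAILED on design failure or fewer than 20 covering reads; otherwise
    CONFIRMED / FALSE_POSITIVE / AMBIGUOUS by the variant-read-ratio and
    base-quality thresholds (1-bp INDELs use the stricter column). A
    site meeting the confirmation ratio but failing the quality floor is
    AMBIGUOUS: the FP rule is stated purely in terms of the ratio.
    """
    if evidence.design_failed or evidence.total_reads < 20:
        return Status.FAILED
    one_bp = abs(evidence.site.length) == 1
    ratio = evidence.variant_reads / evidence.total_reads
    confirm_ratio = 0.40 if one_bp else 0.20
    confirm_quality = 20.0 if one_bp else 10.0
    fp_ratio = 0.05 if one_bp else 0.03
    if ratio >= confirm_ratio and evidence.mean_base_quality >= confirm_quality:
        return Status.CONFIRMED
    if ratio < fp_ratio:
        return Status.FALSE_POSITIVE
    return Status.AMBIGUOUS


def tally(evidences, scope: str = "") -> ValidationCounts:
    """Partition assessed sites into the four statuses."""
    counts = Counter(validation_status(e) for e in evidences)
    return ValidationCounts(
        TP=counts[Status.CONFIRMED],
        FP=counts[Status.FALSE_POSITIVE],
        AMBG=counts[Status.AMBIGUOUS],
        FAIL=counts[Status.FAILED],
        scope=scope,
    )


def estimate_fdr(counts: ValidationCounts) -> float:
    """False discovery rate among conclusively validated sites."""
    denom = counts.TP + counts.FP
    if denom == 0:
        raise ValueError("FDR undefined: no conclusively validated site")
    return counts.FP / denom


def relative_sensitivity(tp_consensus: int, tp_union: int) -> float:
    """S_consensus: consensus true positives over union true positives."""
    if tp_union <= 0:
        raise ValueError("tp_union must be positive")
    if tp_consensus > tp_union:
        raise ValueError("consensus TPs cannot exceed union TPs")
    return tp_consensus / tp_union


def detectable_indels(
    tp_union: int,
    ambg_consensus: int,
    fail_consensus: int,
    s_consensus: float,
    consensus_fdr: float | None = None,
    include_fdr_term: bool = False,
) -> float:
    """Estimated number of INDELs actually detectable in the data.

    Default: TP_union + (AMBG_consensus + FAIL_consensus) x
    (1 - S_consensus). With ``include_fdr_term`` the inconclusive sites
    are additionally discounted by (1 - consensus FDR) before the
    sensitivity correction (an alternate reading of the estimator).
    """
    if min(tp_union, ambg_consensus, fail_consensus) < 0:
        raise ValueError("counts must be non-negative")
    if not 0.0 <= s_consensus <= 1.0:
        raise ValueError("s_consensus outside [0, 1]")
    inconclusive = ambg_consensus + fail_consensus
    if include_fdr_term:
        if consensus_fdr is None:
            raise ValueError("include_fdr_term requires consensus_fdr")
        inconclusive *= 1.0 - consensus_fdr
    return tp_union + inconclusive * (1.0 - s_consensus)


def insilico_rates(
    query: dict[str, list[IndelRecord]],
    reference_set: dict[str, list[IndelRecord]],
) -> tuple[float, float]:
    """Per-individual confirmation and rediscovery rates, averaged.

    ``query`` and ``reference_set`` map sample name -> that individual's
    INDEL records. For every individual present in both, confirmation =
    fraction of the query records matching a reference record, and
    rediscovery = fraction of the reference records matched by a query
    record, using :func:`match_indel` positional matching; rates are
    averaged over overlapping individuals.
    """
    shared = sorted(set(query) & set(reference_set))
    if not shared:
        raise ValueError("no overlapping individuals between the call sets")
    confirmations, rediscoveries = [], []
    for sample in shared:
        q, r = query[sample], reference_set[sample]
        if not q and not r:
            continue
        matched_q = sum(any(match_indel(c, v) for v in r) for c in q)
        matched_r = sum(any(match_indel(v, c) for c in q) for v in r)
        if q:
            confirmations.append(matched_q / len(q))
        if r:
            rediscoveries.append(matched_r / len(r))
    if not confirmations or not rediscoveries:
        raise ValueError("no individual has records to compare")
    return float(np.mean(confirmations)), float(np.mean(rediscoveries))


def select_validation_sites(
    union_keys: list,
    union_aafs: list[float],
    carriers: dict,
    n: int,
    max_carriers: int = 5,
    seed: int = 0,
) -> list[tuple[object, list]]:
    """Random site selection preserving the allele-frequency distribution.

    Sites are stratified by AF bin and sampled so the selected bin
    proportions match the union's (largest-remainder apportionment of
    ``n``), then up to ``max_carriers`` carrier samples are drawn
    uniformly per site. Returns (key, [selected samples]) pairs,
    reproducible by seed.
    """
    if n > len(union_keys):
        raise ValueError("n exceeds the union size")
    if len(union_keys) != len(union_aafs):
        raise ValueError("keys and AAFs must align")
    rng = np.random.default_rng(seed)
    bins = np.array([af_bin(a) for a in union_aafs])
    n_bins = 7
    totals = np.bincount(bins, minlength=n_bins)
    quotas_f = totals / totals.sum() * n
    quotas = np.floor(quotas_f).astype(int)
    remainder = n - quotas.sum()
    if remainder > 0:
        order = np.argsort(-(quotas_f - quotas))
        for b in order[:remainder]:
            quotas[b] += 1
    quotas = np.minimum(quotas, totals)
    # if rounding against small bins lost picks, refill from bins with room
    short = n - quotas.sum()
    while short > 0:
        room = np.flatnonzero(quotas < totals)
        quotas[room[0]] += 1
        short -= 1

    picks: list[tuple[object, list]] = []
    for b in range(n_bins):
        idx = np.flatnonzero(bins == b)
        if quotas[b] == 0 or idx.size == 0:
            continue
        chosen = rng.choice(idx, size=quotas[b], replace=False)
        for i in sorted(chosen):
            key = union_keys[int(i)]
            site_carriers = list(carriers.get(key, ()))
            if len(site_carriers) > max_carriers:
                sel = rng.choice(
                    len(site_carriers), size=max_carriers, replace=False
                )
                site_carriers = [site_carriers[int(j)] for j in sorted(sel)]
            picks.append((key, site_carriers))
    return picks
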