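"""Synthetic study generator: reference, truth set, caller call sets,
and validation read evidence, with ground truth known throughout.

The generator emulates the shape of a high-coverage multi-sample exome
INDEL study:

* a reference contig with tunable homopolymer / short-tandem-repeat
  content and exome-like target intervals;
* a multi-sample truth call set with a length distribution heavy at
  1 bp and enriched at multiples of 3, a configurable fraction of
  slippage-like (CCC) events planted inside repeat tracts, and a
  rare-skewed site-frequency spectrum;
* three caller call sets with caller-specific sensitivity, false-call
  rate (repeat-biased), and quality-score distributions, some records
  deliberately emitted right-shifted or as complex events to exercise
  normalization;
* per-site amplicon-style validation evidence (variant reads, total
  reads, mean base quality).

Everything is bit-reproducible given (config, seed). The truth set
doubles as the classifier-training truth standard and as the validation
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ccc import classify_ccc
from .core import DictReference, GenotypeMatrix, IndelRecord, left_align
from .regions import Regions
from .union import ReadEvidence
from .validation import ValidationEvidence

__all__ = [
    "CallerProfile",
    "SimulationConfig",
    "RawCall",
    "SimulatedStudy",
    "make_reference",
    "simulate_truth",
    "simulate_callers",
    "simulate_validation_evidence",
    "simulate_study",
    "right_shift",
]

#: Signed-length histogram of the truth set: deletions outnumber
#: insertions ~1.6:1, mass concentrated at +/-1 bp with clear
#: enrichment at multiples of three (in-frame events).
DEFAULT_LENGTH_DISTRIBUTION: dict[int, float] = {
    -1: 0.25, 1: 0.18,
    -2: 0.06, 2: 0.03,
    -3: 0.12, 3: 0.08,
    -4: 0.035, 4: 0.015,
    -5: 0.02, 5: 0.01,
    -6: 0.05, 6: 0.03,
    -8: 0.01, -9: 0.03, 9: 0.01,
    -10: 0.005, -12: 0.02, 12: 0.005,
    -15: 0.01,
}


@dataclass
class CallerProfile:
    """Error/quality profile of one simulated variant caller."""

    name: str
    sensitivity: float  # P(report | true site)
    fp_rate: float  # expected false alleles per target Mb
    repeat_fp_multiplier: float = 3.0  # FP enrichment inside repeat tracts
    qual_tp_mean: float = 50.0
    qual_tp_sd: float = 12.0
    qual_fp_mean: float = 32.0
    qual_fp_sd: float = 12.0
    right_shift_frac: float = 0.25  # TPs emitted in a right-shifted encoding
    complex_frac: float = 0.10  # TPs emitted as complex (SNP-joined) events
    shared_fp_frac: float = 0.3  # FPs drawn from the cross-caller artifact pool

    def __post_init__(self):
        if not 0.0 < self.sensitivity <= 1.0:
            raise ValueError("sensitivity must be in (0, 1]")
        if self.fp_rate < 0:
            raise ValueError("fp_rate must be non-negative")


def default_caller_profiles() -> list[CallerProfile]:
    """Three callers sized so the union operates at ~35% false alleles."""
    return [
        CallerProfile("callerA", sensitivity=0.90, fp_rate=820.0),
        CallerProfile("callerB", sensitivity=0.85, fp_rate=820.0),
        CallerProfile("callerC", sensitivity=0.80, fp_rate=820.0),
    ]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic pipeline (defaults sized for CI)."""

    reference_length: int = 1_000_000
    chrom: str = "1"
    repeat_tracts_per_kb: float = 6.0
    n_samples: int = 50
    n_true_indels: int = 2000
    length_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DISTRIBUTION)
    )
    ccc_fraction: float = 0.6
    sfs_alpha: float = 1.9  # site-frequency spectrum P(count=c) ~ c^-alpha
    target_fraction: float = 0.5
    target_interval_bp: int = 400
    mean_depth: float = 60.0  # sequencing depth for caller read evidence
    read_error_rate: float = 0.02
    caller_profiles: list[CallerProfile] = field(
        default_factory=default_caller_profiles
    )
    validation_depth: float = 100.0
    validation_error_rate: float = 0.01
    design_fail_frac: float = 0.05
    truth_dropout: float = 0.0  # fraction of truth sites hidden from training

    def __post_init__(self):
        if self.reference_length < 10_000:
            raise ValueError("reference must be at least 10 kb")
        for p in (
            self.ccc_fraction,
            self.target_fraction,
            self.design_fail_frac,
            self.truth_dropout,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        total = sum(self.length_distribution.values())
        if total <= 0 or 0 in self.length_distribution:
            raise ValueError("length distribution must be positive and indel-only")


@dataclass(frozen=True)
class RepeatTract:
    """A planted tandem tract: ``motif`` repeated ``copies`` times."""

    chrom: str
    start1: int  # 1-based first base of the tract
    motif: str
    copies: int

    @property
    def end1(self) -> int:
        return self.start1 + len(self.motif) * self.copies - 1


@dataclass(frozen=True)
class RawCall:
    """One un-normalized caller output line (possibly shifted/complex)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float


_TRACT_COPY_RANGE = {1: (5, 12), 2: (3, 8), 3: (3, 8), 4: (2, 6)}
_TRACT_MOTIF_PROBS = {1: 0.40, 2: 0.20, 3: 0.25, 4: 0.15}


class _Occupancy:
    """Sorted non-overlapping spans used to keep planted events apart."""

    def __init__(self):
        self._spans: list[tuple[int, int]] = []

    def clashes(self, start: int, end: int) -> bool:
        import bisect

        i = bisect.bisect_left(self._spans, (start, end))
        for j in (i - 1, i):
            if 0 <= j < len(self._spans):
                s, e = self._spans[j]
                if s <= end and start <= e:
                    return True
        return False

    def add(self, start: int, end: int) -> None:
        import bisect

        bisect.insort(self._spans, (start, end))


def make_reference(
    config: SimulationConfig, seed: int
) -> tuple[DictReference, Regions, list[RepeatTract]]:
    """Reference contig with planted repeat tracts plus target intervals.

    Background bases are i.i.d. uniform over {A, C, G, T}; homopolymer
    and short-tandem tracts (motif length 1-4) are written over the
    background at ``repeat_tracts_per_kb``, kept >= 20 bp apart. Target
    intervals of ``target_interval_bp`` tile the contig to cover
    ``target_fraction`` of it. Deterministic by seed.
    """
    rng = np.random.default_rng(seed)
    n = config.reference_length
    bases = np.frombuffer(b"ACGT", dtype="S1")
    seq = rng.choice(bases, size=n).astype("U1")

    n_tracts = int(round(config.repeat_tracts_per_kb * n / 1000))
    occupancy = _Occupancy()
    tracts: list[RepeatTract] = []
    motif_lens = np.array(list(_TRACT_MOTIF_PROBS))
    motif_probs = np.array(list(_TRACT_MOTIF_PROBS.values()))
    max_attempts = n_tracts * 50
    attempts = 0
    while len(tracts) < n_tracts:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "could not place the requested repeat density; lower "
                "repeat_tracts_per_kb or lengthen the reference"
            )
        d = int(rng.choice(motif_lens, p=motif_probs))
        lo, hi = _TRACT_COPY_RANGE[d]
        copies = int(rng.integers(lo, hi + 1))
        motif = "".join(rng.choice(list("ACGT"), size=d))
        if d > 1 and len(set(motif)) == 1:
            continue  # a homopolymer in disguise; resample for motif purity
        tract_len = d * copies
        start1 = int(rng.integers(100, n - tract_len - 100))
        if occupancy.clashes(start1 - 20, start1 + tract_len + 20):
            continue
        occupancy.add(start1 - 20, start1 + tract_len + 20)
        seq[start1 - 1 : start1 - 1 + tract_len] = list(motif * copies)
        tracts.append(RepeatTract(config.chrom, start1, motif, copies))

    reference = DictReference({config.chrom: "".join(seq)})
    period = int(round(config.target_interval_bp / config.target_fraction))
    intervals = [
        (config.chrom, s, min(s + config.target_interval_bp, n))
        for s in range(200, n - config.target_interval_bp, period)
    ]
    tracts.sort(key=lambda t: t.start1)
    return reference, Regions(intervals), tracts


def _sample_allele_counts(rng, n_sites: int, n_chrom: int, alpha: float) -> np.ndarray:
    counts = np.arange(1, n_chrom)
    probs = counts.astype(float) ** -alpha
    probs /= probs.sum()
    return rng.choice(counts, size=n_sites, p=probs)


def _genotypes_from_counts(rng, allele_counts, n_samples: int) -> np.ndarray:
    """Drop alt alleles onto 2N chromosomes uniformly; code per sample."""
    gts = np.zeros((len(allele_counts), n_samples), dtype=np.int8)
    for i, c in enumerate(allele_counts):
        chroms = rng.choice(2 * n_samples, size=int(c), replace=False)
        np.add.at(gts[i], chroms // 2, 1)
    return gts


def simulate_truth(
    reference: DictReference,
    targets: Regions,
    tracts: list[RepeatTract],
    config: SimulationConfig,
    seed: int,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Place the truth INDEL set and sample per-individual genotypes.

    A ``ccc_fraction`` share of sites is planted inside repeat tracts as
    motif expansions (insertions) or contractions (deletions, leaving at
    least one adjacent copy), guaranteeing the slippage signature; the
    remainder is placed on unique sequence and rejection-sampled to be
    NCCC. Sites are left-aligned, kept apart, and assigned genotypes
    from a rare-skewed frequency spectrum. Returns the truth genotype
    matrix (loci sorted by position) and the planted CCC flags.
    """
    rng = np.random.default_rng(seed)
    chrom = config.chrom
    lengths = np.array(sorted(config.length_distribution))
    weights = np.array([config.length_distribution[int(l)] for l in lengths])
    weights = weights / weights.sum()

    usable = [
        t
        for t in tracts
        if targets.contains_span(t.chrom, t.start1 - 1, t.end1)
        and t.start1 >= 3
    ]
    by_motif_len: dict[int, list[RepeatTract]] = {}
    for t in usable:
        by_motif_len.setdefault(len(t.motif), []).append(t)

    n_ccc = int(round(config.ccc_fraction * config.n_true_indels))
    drawn = rng.choice(lengths, size=config.n_true_indels, p=weights)
    occupancy = _Occupancy()
    records: list[IndelRecord] = []
    ccc_flags: list[bool] = []

    def place_ccc(length: int) -> IndelRecord | None:
        abs_len = abs(int(length))
        # prefer the largest motif that tiles the allele: 3 bp events sit in
        # triplet repeats, 1 bp events in homopolymers, as slippage does
        divisors = [d for d in (4, 3, 2, 1) if abs_len % d == 0 and d in by_motif_len]
        for d in divisors:
            pool = by_motif_len[d]
            order = rng.permutation(len(pool))
            for j in order[: min(len(order), 60)]:
                tract = pool[j]
                copies_needed = abs_len // d
                if length < 0 and tract.copies < copies_needed + 1:
                    continue
                anchor = tract.start1 - 1
                span = (anchor - 40, tract.end1 + 5)
                if occupancy.clashes(*span):
                    continue
                anchor_base = reference.base(chrom, anchor)
                if length > 0:
                    seq = tract.motif * copies_needed
                    rec = IndelRecord(chrom, anchor, anchor_base, anchor_base + seq)
                else:
                    seq = reference.fetch(chrom, anchor, anchor + abs_len)
                    rec = IndelRecord(chrom, anchor, anchor_base + seq, anchor_base)
                occupancy.add(*span)
                return rec
        return None

    def place_nccc(length: int) -> IndelRecord | None:
        abs_len = abs(int(length))
        intervals = targets.intervals()
        for _ in range(300):
            chrom_i, s0, e0 = intervals[int(rng.integers(len(intervals)))]
            pos = int(rng.integers(max(s0 + 1, 3), e0))
            span = (pos - 40, pos + abs_len + 5)
            if occupancy.clashes(*span):
                continue
            anchor_base = reference.base(chrom_i, pos)
            if anchor_base in ("", "N"):
                continue
            if length > 0:
                seq = "".join(rng.choice(list("ACGT"), size=abs_len))
                rec = IndelRecord(chrom_i, pos, anchor_base, anchor_base + seq)
            else:
                if pos + abs_len > e0:
                    continue
                seq = reference.fetch(chrom_i, pos, pos + abs_len)
                if "N" in seq:
                    continue
                rec = IndelRecord(chrom_i, pos, anchor_base + seq, anchor_base)
            if classify_ccc(rec, reference) == "CCC":
                continue
            occupancy.add(*span)
            return rec
        return None

    for i, length in enumerate(drawn):
        want_ccc = i < n_ccc
        rec = None
        for _ in range(40):
            candidate = (
                place_ccc(int(length)) if want_ccc else place_nccc(int(length))
            )
            if candidate is None:
                break
            candidate = left_align(candidate, reference)
            # left alignment may slide the anchor just past an interval
            # edge, and the classifier's verdict is defined on the
            # left-aligned representation — re-check both here
            if not targets.contains(candidate.chrom, candidate.pos):
                continue
            if (classify_ccc(candidate, reference) == "CCC") != want_ccc:
                continue
            rec = candidate
            break
        if rec is None:
            raise RuntimeError(
                f"could not place a {'CCC' if want_ccc else 'NCCC'} "
                f"{int(length):+d} bp site: repeat density or target size "
                "too low for the requested configuration"
            )
        records.append(rec)
        ccc_flags.append(want_ccc)

    order = np.argsort([r.pos for r in records], kind="stable")
    records = [records[i] for i in order]
    flags = np.array(ccc_flags)[order]
    keys = {r.key() for r in records}
    if len(keys) != len(records):
        raise RuntimeError("truth placement produced duplicate alleles")

    counts = _sample_allele_counts(
        rng, len(records), 2 * config.n_samples, config.sfs_alpha
    )
    gts = _genotypes_from_counts(rng, counts, config.n_samples)
    samples = [f"S{i:03d}" for i in range(config.n_samples)]
    return GenotypeMatrix(records, samples, gts), flags


def right_shift(record: IndelRecord, reference, steps: int = 1) -> IndelRecord:
    """Re-encode an INDEL shifted rightward (inverse of left alignment).

    Used to emit deliberately denormalized caller records; stops early
    when no further equivalent representation exists.
    """
    pos, seq = record.pos, record.allele_seq
    abs_len = abs(record.length)
    for _ in range(steps):
        nxt_pos = pos + 1 if record.is_insertion else pos + abs_len + 1
        nxt = reference.base(record.chrom, nxt_pos)
        if nxt == "" or nxt == "N" or nxt != seq[0]:
            break
        seq = seq[1:] + nxt
        pos += 1
    if pos == record.pos:
        return record
    anchor = reference.base(record.chrom, pos)
    if record.is_deletion:
        ref_allele, alt_allele = anchor + seq, anchor
    else:
        ref_allele, alt_allele = anchor, anchor + seq
    return replace(record, pos=pos, ref_allele=ref_allele, alt_allele=alt_allele)


_OTHER_BASE = {"A": "C", "C": "G", "G": "T", "T": "A", "N": "A"}

#: False calls are short, dominated by 1 bp events.
FP_LENGTH_DISTRIBUTION = {-1: 0.45, 1: 0.35, -2: 0.10, 2: 0.10}


@dataclass
class SimulatedStudy:
    """Everything the pipeline consumes, with ground truth attached."""

    reference: DictReference
    targets: Regions
    truth: GenotypeMatrix
    truth_ccc_flags: np.ndarray
    training_truth_keys: set
    raw_callsets: dict[str, list[RawCall]]
    evidence: ReadEvidence
    depth_matrix: dict  # key -> (n_samples,) read depth
    variant_read_matrix: dict  # key -> (n_samples,) alt-supporting reads
    fp_keys: set
    samples: list[str]
    config: SimulationConfig
    seed: int

    def label(self, key) -> bool:
        """Ground-truth label of a union key: True iff a planted site."""
        return key in self.truth_key_set

    @property
    def truth_key_set(self) -> set:
        return {r.key() for r in self.truth.loci}


def _complex_encoding(rec: IndelRecord, reference, rng) -> RawCall | None:
    """Join a fake adjacent SNP onto an INDEL to form a complex event.

    Returns None when no unambiguous encoding exists: if the event
    sequence starts with the following reference base (or the mutated
    base could be absorbed into the event), parsimonious decomposition
    of the joined event would legitimately yield a different simple
    INDEL, so such records are emitted in plain form instead.
    """
    end1 = rec.pos + len(rec.ref_allele) - 1
    follow = reference.base(rec.chrom, end1 + 1)
    if follow in ("", "N"):
        return None
    seq = rec.allele_seq
    if rec.is_insertion and seq[0] == follow:
        return None  # prefix trimming would re-anchor the event
    banned = {follow, seq[0]}
    mutated = next(b for b in "ACGT" if b not in banned)
    return RawCall(
        rec.chrom, rec.pos, rec.ref_allele + follow, rec.alt_allele + mutated, 0.0
    )


def simulate_callers(
    truth: GenotypeMatrix,
    reference: DictReference,
    targets: Regions,
    config: SimulationConfig,
    seed: int,
    tracts: list[RepeatTract] | None = None,
) -> tuple[dict[str, list[RawCall]], set, dict, dict]:
    """Emit per-caller raw call sets plus shared read evidence.

    Each caller reports each true site independently with its
    sensitivity (quality ~ its TP distribution) and adds false calls at
    ``fp_rate`` per target Mb, biased toward repeat tracts by
    ``repeat_fp_multiplier`` (quality ~ its FP distribution). A fraction
    of true records is emitted right-shifted or as complex events.

    Returns (raw call sets, FP key set, per-key depth rows, per-key
    variant-read rows); the read rows cover every sample and are shared
    by all callers, mimicking one underlying pool of sequencing data.
    """
    profiles = config.caller_profiles
    if len(profiles) < 2:
        raise ValueError("at least two caller profiles are required")
    if all(p.sensitivity == 0 for p in profiles):
        raise ValueError("all callers have zero sensitivity")
    rng = np.random.default_rng(seed)
    chrom = config.chrom
    n_samples = truth.n_samples
    e = config.read_error_rate

    # shared read evidence at truth sites, driven by the true genotypes
    depth_matrix: dict = {}
    vr_matrix: dict = {}
    truth_keys = []
    for i, rec in enumerate(truth.loci):
        key = rec.key()
        truth_keys.append(key)
        depth = rng.poisson(config.mean_depth, size=n_samples)
        gts = truth.genotypes[i]
        p = np.where(gts == 2, 1.0 - e, np.where(gts == 1, 0.5, e))
        vr = rng.binomial(depth, p)
        depth_matrix[key] = depth
        vr_matrix[key] = vr

    target_mb = targets.total_bp() / 1e6
    tract_list = tracts or []
    eligible_tracts = [
        t for t in tract_list if targets.contains_span(t.chrom, t.start1 - 1, t.end1)
    ]
    repeat_bp_fraction = (
        sum(t.end1 - t.start1 + 1 for t in eligible_tracts) / targets.total_bp()
        if eligible_tracts
        else 0.0
    )
    fp_lengths = np.array(sorted(FP_LENGTH_DISTRIBUTION))
    fp_weights = np.array([FP_LENGTH_DISTRIBUTION[int(l)] for l in fp_lengths])
    fp_weights = fp_weights / fp_weights.sum()
    truth_key_set = set(truth_keys)
    intervals = targets.intervals()

    def make_fp_record(repeat_multiplier: float) -> IndelRecord | None:
        p_repeat = min(0.9, repeat_multiplier * repeat_bp_fraction)
        length = int(rng.choice(fp_lengths, p=fp_weights))
        abs_len = abs(length)
        for _ in range(100):
            if eligible_tracts and rng.random() < p_repeat:
                t = eligible_tracts[int(rng.integers(len(eligible_tracts)))]
                pos = int(rng.integers(t.start1, t.end1 + 1)) - 1
                if pos < 2:
                    continue
            else:
                ci, s0, e0 = intervals[int(rng.integers(len(intervals)))]
                pos = int(rng.integers(max(s0 + 1, 3), e0))
            anchor = reference.base(chrom, pos)
            if anchor in ("", "N"):
                continue
            if length > 0:
                seq = "".join(rng.choice(list("ACGT"), size=abs_len))
                rec = IndelRecord(chrom, pos, anchor, anchor + seq)
            else:
                seq = reference.fetch(chrom, pos, pos + abs_len)
                if len(seq) != abs_len or "N" in seq:
                    continue
                rec = IndelRecord(chrom, pos, anchor + seq, anchor)
            rec = left_align(rec, reference)
            if rec.key() in truth_key_set or not targets.contains(chrom, rec.pos):
                continue
            return rec
        return None

    def ensure_fp_evidence(key) -> None:
        if key in depth_matrix:
            return
        depth = rng.poisson(config.mean_depth, size=n_samples)
        n_carriers = int(rng.integers(1, 4))
        carrier_idx = rng.choice(n_samples, size=n_carriers, replace=False)
        ratio = rng.uniform(0.05, 0.45)
        p = np.full(n_samples, e)
        p[carrier_idx] = ratio
        vr_matrix[key] = rng.binomial(depth, p)
        depth_matrix[key] = depth

    # recurrent artifact sites reported by more than one caller
    mean_multiplier = float(np.mean([p.repeat_fp_multiplier for p in profiles]))
    mean_fp_rate = float(np.mean([p.fp_rate for p in profiles]))
    pool_target = int(round(mean_fp_rate * target_mb))
    artifact_pool: list[IndelRecord] = []
    pool_keys: set = set()
    while len(artifact_pool) < pool_target:
        rec = make_fp_record(mean_multiplier)
        if rec is None:
            raise RuntimeError("could not build the shared artifact pool")
        if rec.key() in pool_keys:
            continue
        pool_keys.add(rec.key())
        ensure_fp_evidence(rec.key())
        artifact_pool.append(rec)

    callsets: dict[str, list[RawCall]] = {}
    fp_keys: set = set()
    for profile in profiles:
        calls: list[RawCall] = []
        # true sites
        reported = rng.random(truth.n_loci) < profile.sensitivity
        quals = rng.normal(profile.qual_tp_mean, profile.qual_tp_sd, truth.n_loci)
        for i in np.flatnonzero(reported):
            rec = truth.loci[i]
            qual = float(max(quals[i], 1.0))
            u = rng.random()
            raw = None
            if u < profile.complex_frac:
                raw = _complex_encoding(rec, reference, rng)
                if raw is not None:
                    raw = replace(raw, qual=qual)
            if raw is None and u < profile.complex_frac + profile.right_shift_frac:
                shifted = right_shift(rec, reference, steps=int(rng.integers(1, 4)))
                raw = RawCall(
                    shifted.chrom, shifted.pos, shifted.ref_allele,
                    shifted.alt_allele, qual,
                )
            if raw is None:
                raw = RawCall(rec.chrom, rec.pos, rec.ref_allele, rec.alt_allele, qual)
            calls.append(raw)
        # false calls: a share recurs from the cross-caller artifact pool
        n_fp = int(rng.poisson(profile.fp_rate * target_mb))
        made = 0
        caller_fp_keys: set = set()
        while made < n_fp:
            if artifact_pool and rng.random() < profile.shared_fp_frac:
                rec = artifact_pool[int(rng.integers(len(artifact_pool)))]
            else:
                rec = make_fp_record(profile.repeat_fp_multiplier)
                if rec is None:
                    raise RuntimeError(
                        f"could not place false calls for {profile.name}"
                    )
            key = rec.key()
            if key in caller_fp_keys:
                continue
            caller_fp_keys.add(key)
            ensure_fp_evidence(key)
            fp_keys.add(key)
            qual = float(max(rng.normal(profile.qual_fp_mean, profile.qual_fp_sd), 1.0))
            calls.append(RawCall(rec.chrom, rec.pos, rec.ref_allele, rec.alt_allele, qual))
            made += 1
        callsets[profile.name] = calls
    return callsets, fp_keys, depth_matrix, vr_matrix


def build_read_evidence(
    depth_matrix: dict,
    vr_matrix: dict,
    carrier_map: dict,
) -> ReadEvidence:
    """Carrier-restricted evidence summaries from the full read rows."""
    depth = {}
    variant_reads = {}
    for key, carriers in carrier_map.items():
        if key not in depth_matrix or len(carriers) == 0:
            continue
        depth[key] = np.asarray(depth_matrix[key])[carriers]
        variant_reads[key] = np.asarray(vr_matrix[key])[carriers]
    return ReadEvidence(depth=depth, variant_reads=variant_reads)


def simulate_validation_evidence(
    sites: list[IndelRecord],
    is_true: np.ndarray,
    genotype_codes: np.ndarray,
    depth: float,
    error_rate: float,
    seed: int,
    design_fail_frac: float = 0.0,
) -> list[ValidationEvidence]:
    """Amplicon-style read evidence for a list of selected sites.

    True sites draw variant reads as binomial(depth, 0.5 x (1 - e)) for
    a heterozygous carrier or (1 - e) for a homozygous one; false sites
    as binomial(depth, e). Mean base quality is drawn high for real
    signal and low for noise; a ``design_fail_frac`` share of sites is
    flagged as assay design failures.
    """
    if depth < 1:
        raise ValueError("validation depth must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[ValidationEvidence] = []
    for rec, true, gt in zip(sites, is_true, genotype_codes):
        total = int(rng.poisson(depth))
        if true:
            p = (1.0 - error_rate) if gt == 2 else 0.5 * (1.0 - error_rate)
            bq = float(rng.normal(30.0, 3.0))
        else:
            p = error_rate
            bq = float(rng.normal(8.0, 3.0))
        vr = int(rng.binomial(total, p)) if total > 0 else 0
        out.append(
            ValidationEvidence(
                site=rec,
                variant_reads=vr,
                total_reads=total,
                mean_base_quality=bq,
                design_failed=bool(rng.random() < design_fail_frac),
            )
        )
    return out


def simulate_study(config: SimulationConfig | None = None, seed: int = 0) -> SimulatedStudy:
    """Run every generator stage and bundle the results.

    Sub-seeds for the reference, truth, and caller stages are derived
    from ``seed`` so the stages are individually reproducible.
    """
    config = config or SimulationConfig()
    ss = np.random.SeedSequence(seed)
    ref_seed, truth_seed, caller_seed, dropout_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    )
    reference, targets, tracts = make_reference(config, ref_seed)
    truth, ccc_flags = simulate_truth(reference, targets, tracts, config, truth_seed)
    callsets, fp_keys, depth_matrix, vr_matrix = simulate_callers(
        truth, reference, targets, config, caller_seed, tracts
    )
    truth_keys = {r.key() for r in truth.loci}
    training_keys = truth_keys
    if config.truth_dropout > 0:
        drng = np.random.default_rng(dropout_seed)
        keep = drng.random(len(truth.loci)) >= config.truth_dropout
        training_keys = {
            r.key() for r, k in zip(truth.loci, keep) if k
        }
    carrier_map = {}
    truth_carriers = {
        rec.key(): truth.carriers(i) for i, rec in enumerate(truth.loci)
    }
    for key in depth_matrix:
        if key in truth_carriers:
            carrier_map[key] = truth_carriers[key]
        else:
            vr = np.asarray(vr_matrix[key])
            d = np.asarray(depth_matrix[key])
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(d > 0, vr / np.maximum(d, 1), 0.0)
            carrier_map[key] = np.flatnonzero(ratio > 0.04)
    evidence = build_read_evidence(depth_matrix, vr_matrix, carrier_map)
    return SimulatedStudy(
        reference=reference,
        targets=targets,
        truth=truth,
        truth_ccc_flags=ccc_flags,
        training_truth_keys=training_keys,
        raw_callsets=callsets,
        evidence=evidence,
        depth_matrix=depth_matrix,
        variant_read_matrix=vr_matrix,
        fp_keys=fp_keys,
        samples=truth.samples,
        config=config,
        seed=seed,
    )
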