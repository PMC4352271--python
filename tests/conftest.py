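"""Shared fixtures and independent oracles for the test suite.

The oracle helpers here deliberately avoid the library's own
normalization code paths: haplotypes are built by direct string
surgery, leftmost representations by exhaustive enumeration, and repeat
context by regex tandem-array scanning, so they can arbitrate the
implementation.
"""

from __future__ import annotations

import numpy as np
import pytest

from exindel.core import DictReference, IndelRecord
from exindel.simulate import SimulationConfig, simulate_study


def apply_indel(ref_seq: str, record: IndelRecord) -> str:
    """Alternate haplotype from direct string surgery (oracle)."""
    pos = record.pos  # 1-based anchor
    assert (
        ref_seq[pos - 1 : pos - 1 + len(record.ref_allele)] == record.ref_allele
    ), "record inconsistent with reference"
    if record.is_insertion:
        return ref_seq[:pos] + record.allele_seq + ref_seq[pos:]
    return ref_seq[:pos] + ref_seq[pos + abs(record.length) :]


def local_haplotype(ref_seq: str, record: IndelRecord, lo: int, hi: int) -> str:
    """Haplotype restricted to the reference window [lo, hi) (0-based).

    Valid whenever the event lies strictly inside the window; two
    records are haplotype-identical iff their local haplotypes over a
    common enclosing window are equal.
    """
    assert lo < record.pos - 1 and record.pos + abs(record.length) < hi
    sub = ref_seq[lo:hi]
    shifted = IndelRecord(
        record.chrom, record.pos - lo, record.ref_allele, record.alt_allele
    )
    return apply_indel(sub, shifted)


def same_haplotype(ref_seq: str, a: IndelRecord, b: IndelRecord,
                   margin: int = 450) -> bool:
    lo = max(0, min(a.pos, b.pos) - margin)
    hi = min(len(ref_seq), max(a.pos, b.pos) + abs(a.length) + margin)
    return local_haplotype(ref_seq, a, lo, hi) == local_haplotype(
        ref_seq, b, lo, hi
    )


def leftmost_anchor(ref_seq: str, record: IndelRecord, window: int = 400) -> int:
    """Smallest anchor position yielding the same haplotype (oracle).

    Brute-force enumeration of candidate anchors within ``window`` bp
    left of the record (equivalent representations are bounded by the
    run structure, far shorter than the window in these references).
    """
    lo = max(0, record.pos - window)
    hi = min(len(ref_seq), record.pos + abs(record.length) + 50)
    sub = ref_seq[lo:hi]
    rec = IndelRecord(
        record.chrom, record.pos - lo, record.ref_allele, record.alt_allele
    )
    target = apply_indel(sub, rec)
    length = abs(rec.length)
    for p in range(1, rec.pos + 1):
        if rec.is_insertion:
            candidate = sub[:p] + target[p : p + length] + sub[p:]
        else:
            if p + length > len(sub):
                continue
            candidate = sub[:p] + sub[p + length :]
        if candidate == target:
            assert p > 1 or lo == 0, "window too small for enumeration"
            return p + lo
    raise AssertionError("no equivalent representation found")


def smallest_period(seq: str) -> str:
    """Minimal tiling motif by direct period scan (oracle)."""
    for d in range(1, len(seq) + 1):
        if all(seq[i] == seq[i % d] for i in range(len(seq))):
            if len(seq) % d == 0:
                return seq[:d]
    return seq


def _copies_at(ref_seq: str, start1: int, motif: str) -> int:
    """Consecutive copies of ``motif`` starting at 1-based ``start1``."""
    d = len(motif)
    i = start1 - 1
    copies = 0
    while ref_seq[i : i + d] == motif:
        copies += 1
        i += d
    return copies


def ccc_oracle(record: IndelRecord, ref_seq: str, radius: int = 150) -> bool:
    """Slippage verdict by exhaustive tandem-array scanning (oracle).

    Enumerates every candidate array start around the event (``radius``
    bp each side — far wider than any tandem array in these references)
    and checks geometric adjacency/containment: an insertion must touch
    an array copy at its insertion point; a deletion must sit, in copy
    phase, inside an array at least one copy longer than the deleted
    run.
    """
    seq = record.allele_seq
    if "N" in seq:
        return False
    m = smallest_period(seq)
    d = len(m)
    k = len(seq) // d
    pos = record.pos  # anchor, 1-based
    if record.is_insertion:
        return (
            _copies_at(ref_seq, pos - d + 1, m) >= 1
            or _copies_at(ref_seq, pos + 1, m) >= 1
        )
    del_start, del_end = pos + 1, pos + abs(record.length)
    for s in range(max(1, del_start - radius), del_start + 1):
        if (del_start - s) % d != 0:
            continue
        c = _copies_at(ref_seq, s, m)
        if c >= k + 1 and s + c * d - 1 >= del_end:
            return True
    return False


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        reference_length=200_000,
        n_samples=20,
        n_true_indels=400,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """One modest simulated study shared across read-only tests."""
    return simulate_study(small_config, seed=11)


@pytest.fixture(scope="session")
def uniform_reference():
    """A 60 kb i.i.d. uniform reference (no planted repeats)."""
    rng = np.random.default_rng(505)
    seq = "".join(rng.choice(list("ACGT"), size=60_000))
    return DictReference({"1": seq})
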