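"""Target-region intervals (exome capture targets).

BED input is 0-based half-open; all queries here take 1-based positions,
matching the VCF anchored coordinates used everywhere else. Membership
is a point test on the anchor base: a variant is in-target iff its
anchor lies inside an interval.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["Regions", "read_bed", "write_bed"]


class Regions:
    """Sorted, disjoint genomic intervals with fast point membership."""

    def __init__(self, intervals: list[tuple[str, int, int]]):
        """``intervals`` are (chrom, start0, end0), 0-based half-open."""
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if end <= start:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged: list[list[int]] = []
            for start, end in ivs:
                if merged and start <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], end)
                else:
                    merged.append([start, end])
            self._starts[chrom] = np.array([m[0] for m in merged], dtype=np.int64)
            self._ends[chrom] = np.array([m[1] for m in merged], dtype=np.int64)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._starts)

    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in self.chroms:
            out.extend(
                (chrom, int(s), int(e))
                for s, e in zip(self._starts[chrom], self._ends[chrom])
            )
        return out

    def total_bp(self) -> int:
        return int(
            sum((self._ends[c] - self._starts[c]).sum() for c in self._starts)
        )

    def contains(self, chrom: str, pos1: int) -> bool:
        """True iff the 1-based position lies in an interval."""
        starts = self._starts.get(chrom)
        if starts is None:
            return False
        p0 = pos1 - 1
        i = int(np.searchsorted(starts, p0, side="right")) - 1
        return i >= 0 and p0 < self._ends[chrom][i]

    def contains_span(self, chrom: str, start1: int, end1: int) -> bool:
        """True iff the whole 1-based inclusive span fits in one interval."""
        starts = self._starts.get(chrom)
        if starts is None:
            return False
        p0 = start1 - 1
        i = int(np.searchsorted(starts, p0, side="right")) - 1
        return i >= 0 and end1 <= self._ends[chrom][i]


def read_bed(path: str | Path) -> Regions:
    intervals = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{line_no}: BED line has <3 fields")
            intervals.append((fields[0], int(fields[1]), int(fields[2])))
    return Regions(intervals)


def write_bed(regions: Regions, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in regions.intervals():
            fh.write(f"{chrom}\t{start}\t{end}\n")
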