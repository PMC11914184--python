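"""Copy-number derived metrics and microsatellite-instability scoring.

* ``gistic_transform``: log2(CN + 0.01) - 1, centring the diploid state near 0.
* ``join_small_segments``: merges segments with fewer than 50 markers into the
  flanking neighbour of closer total copy number (marker-weighted mean CN).
* ``percent_genome_altered``: fraction of covered autosomal genome whose total
  CN deviates from the rounded sample ploidy by more than 0.5.
* ``msi_score``: microsatellite indels per megabase; MSI when strictly > 4.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

__all__ = [
    "CNSegment",
    "MsiInput",
    "gistic_transform",
    "join_small_segments",
    "percent_genome_altered",
    "msi_score",
    "MSI_THRESHOLD",
]

MSI_THRESHOLD = 4.0
GISTIC_OFFSET = 0.01

_AUTOSOME_RE = re.compile(r"^(chr)?([1-9]|1[0-9]|2[0-2])$")


@dataclass(frozen=True)
class CNSegment:
    """Allele-specific copy-number interval (1-based, inclusive ends)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_markers: int
    major_cn: float
    minor_cn: float
    purity: float = 1.0
    sample_ploidy: float = 2.0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start exceeds end")
        if not (self.major_cn >= self.minor_cn >= 0):
            raise ValueError("require major >= minor >= 0")
        if not 0 <= self.purity <= 1:
            raise ValueError("purity must be in [0, 1]")
        if self.sample_ploidy <= 0:
            raise ValueError("ploidy must be positive")
        if self.n_markers < 0:
            raise ValueError("marker count must be non-negative")

    @property
    def total_cn(self) -> float:
        return self.major_cn + self.minor_cn

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos <= self.end


@dataclass(frozen=True)
class MsiInput:
    sample_id: str
    microsatellite_indel_count: int
    callable_megabases: float

    def __post_init__(self) -> None:
        if self.microsatellite_indel_count < 0:
            raise ValueError("indel count must be non-negative")


def gistic_transform(total_cn: float, offset: float = GISTIC_OFFSET) -> float:
    """log2(CN + offset) - 1; CN=0 is valid and maps to log2(offset) - 1."""
    if total_cn < 0:
        raise ValueError("copy number must be non-negative")
    return math.log2(total_cn + offset) - 1.0


def _merge(a: CNSegment, b: CNSegment) -> CNSegment:
    """Marker-weighted merge of two adjacent segments (union span)."""
    w = a.n_markers + b.n_markers
    if w == 0:
        major = (a.major_cn + b.major_cn) / 2
        minor = (a.minor_cn + b.minor_cn) / 2
    else:
        major = (a.major_cn * a.n_markers + b.major_cn * b.n_markers) / w
        minor = (a.minor_cn * a.n_markers + b.minor_cn * b.n_markers) / w
    lo, hi = (a, b) if a.start <= b.start else (b, a)
    # weighted means can transiently order major below minor at equal weight
    major, minor = max(major, minor), min(major, minor)
    return replace(
        a,
        start=lo.start,
        end=hi.end,
        n_markers=w,
        major_cn=major,
        minor_cn=minor,
    )


def join_small_segments(
    segments: Sequence[CNSegment],
    min_markers: int = 50,
) -> list[CNSegment]:
    """Merge segments with fewer than ``min_markers`` markers into the
    flanking neighbour with nearer total CN (ties go left), per chromosome.

    Input must be sorted by (chrom, start).  A chromosome reduced to a single
    segment is retained regardless of its marker count.  Marker totals and
    the marker-weighted mean CN per chromosome are conserved.
    """
    for prev, cur in zip(segments, segments[1:]):
        if prev.chrom == cur.chrom and prev.start > cur.start:
            raise ValueError("segments must be sorted by coordinate")

    out: list[CNSegment] = []
    by_chrom: dict[str, list[CNSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)

    for chrom in by_chrom:
        segs = list(by_chrom[chrom])
        while len(segs) > 1:
            small = [i for i, s in enumerate(segs) if s.n_markers < min_markers]
            if not small:
                break
            # merge the smallest first for stability
            i = min(small, key=lambda j: (segs[j].n_markers, j))
            left = segs[i - 1] if i > 0 else None
            right = segs[i + 1] if i < len(segs) - 1 else None
            if left is not None and right is not None:
                d_left = abs(left.total_cn - segs[i].total_cn)
                d_right = abs(right.total_cn - segs[i].total_cn)
                target = i - 1 if d_left <= d_right else i + 1
            elif left is not None:
                target = i - 1
            else:
                target = i + 1
            merged = _merge(segs[target], segs[i])
            lo, hi = min(i, target), max(i, target)
            segs[lo:hi + 1] = [merged]
        out.extend(segs)
    return out


def percent_genome_altered(
    segments: Iterable[CNSegment],
    deviation: float = 0.5,
    autosomes_only: bool = True,
) -> float:
    """Percentage of covered genome whose total CN deviates from the rounded
    sample ploidy by strictly more than ``deviation``."""
    covered = 0
    altered = 0
    for seg in segments:
        if autosomes_only and not _AUTOSOME_RE.match(seg.chrom):
            continue
        covered += seg.length
        baseline = round(seg.sample_ploidy)
        if abs(seg.total_cn - baseline) > deviation:
            altered += seg.length
    if covered == 0:
        raise ValueError("no covered genome length")
    return 100.0 * altered / covered


def msi_score(
    inp: MsiInput,
    threshold: float = MSI_THRESHOLD,
) -> tuple[float, bool]:
    """(indels per megabase, MSI iff score strictly above threshold)."""
    if inp.callable_megabases <= 0:
        raise ValueError("callable megabases must be positive")
    score = inp.microsatellite_indel_count / inp.callable_megabases
    return score, score > threshold
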