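"""Structural-variant artifact filters: cohort recurrence blacklist and
read-support filter.

An SV key (both breakpoints with orientations, exact coordinates) observed in
strictly more than ``max_samples`` distinct patients — pooling passed and
rejected calls, counting multiple samples of one patient once — is
blacklisted.  A call passes the support filter with >=3 split reads, or >=3
paired reads, or at least one of each.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "Breakpoint",
    "SVCall",
    "build_sv_recurrence_blacklist",
    "sv_support_filter",
]

Breakpoint = tuple[str, int, str]  # (chrom, pos, orientation "+"/"-")
SVKey = tuple[Breakpoint, Breakpoint]


def _canonical_key(bp1: Breakpoint, bp2: Breakpoint) -> SVKey:
    return (bp1, bp2) if (bp1[0], bp1[1]) <= (bp2[0], bp2[1]) else (bp2, bp1)


@dataclass(frozen=True)
class SVCall:
    sample_id: str
    patient_id: str
    bp1: Breakpoint
    bp2: Breakpoint
    split_reads: int = 0
    paired_reads: int = 0
    caller_status: str = "pass"  # "pass" | "reject"

    def __post_init__(self) -> None:
        if self.split_reads < 0 or self.paired_reads < 0:
            raise ValueError("read counts must be non-negative")
        if self.caller_status not in ("pass", "reject"):
            raise ValueError(f"unknown caller status {self.caller_status!r}")

    @property
    def key(self) -> SVKey:
        return _canonical_key(self.bp1, self.bp2)


def build_sv_recurrence_blacklist(
    all_calls: Iterable[SVCall],
    max_samples: int = 2,
) -> set[SVKey]:
    """SV keys seen (pass or reject) in strictly more than ``max_samples``
    distinct patients."""
    patients: dict[SVKey, set[str]] = defaultdict(set)
    for call in all_calls:
        patients[call.key].add(call.patient_id)
    return {key for key, pats in patients.items() if len(pats) > max_samples}


def sv_support_filter(call: SVCall) -> bool:
    """Pass iff split >= 3, or paired >= 3, or (split >= 1 and paired >= 1)."""
    s, p = call.split_reads, call.paired_reads
    if s < 0 or p < 0:
        raise ValueError("read counts must be non-negative")
    return s >= 3 or p >= 3 or (s >= 1 and p >= 1)
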