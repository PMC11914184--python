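"""Consensus acceptance of multi-caller somatic small variants and the two
cohort-level blacklists (normal-panel recurrence and reject:pass ratio),
plus tumour mutation burden.

A variant is accepted when at least two of the three configured callers marked
it ``pass``.  Two blacklists remove recurrent technical artifacts:

* *normal panel*: a variant supported by ``min_reads`` or more reads in
  strictly more than ``min_normals`` normal controls is removed;
* *reject ratio*: pooling every observation of a variant across all samples
  and callers, a variant whose reject count exceeds its pass count is removed
  (a variant never passed anywhere but rejected somewhere is also removed).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

__all__ = [
    "CallStatus",
    "VariantKey",
    "VariantObservation",
    "BlacklistEntry",
    "DEFAULT_CALLERS",
    "normalize_variant",
    "consensus_accept",
    "build_normal_panel_blacklist",
    "build_reject_ratio_blacklist",
    "apply_filters",
    "tumour_mutation_burden",
]

DEFAULT_CALLERS = ("mutect2", "strelka2", "vardict")


class CallStatus(str, Enum):
    PASS = "pass"
    REJECT = "reject"
    NOT_CALLED = "not_called"


VariantKey = tuple[str, int, str, str]


def normalize_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    reference: Mapping[str, str] | None = None,
) -> VariantKey:
    """Return the normalized (chrom, 1-based pos, ref, alt) identity.

    Shared trailing then leading bases are trimmed; if ``reference`` maps
    chromosome name to its full sequence, indels are additionally
    left-aligned.  ``ref == alt`` is rejected.
    """
    if pos < 1:
        raise ValueError(f"position must be >= 1, got {pos}")
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise ValueError("ref and alt alleles are identical")
    # trim shared suffix, keeping at least one base per allele
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim shared prefix
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if reference is not None and (len(ref) != len(alt)):
        seq = reference[chrom]
        # left-align: while both alleles end in the same base and the base
        # preceding the event equals that base, shift one position left
        while (
            len(ref) != len(alt)
            and ref[0] == alt[0]
            and ref[-1] == alt[-1]
            and pos > 1
        ):
            prev = seq[pos - 2].upper()
            if ref[-1] != prev and alt[-1] != prev:
                break
            ref = prev + ref[:-1]
            alt = prev + alt[:-1]
            pos -= 1
            while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
                ref, alt = ref[:-1], alt[:-1]
    return (chrom, pos, ref, alt)


@dataclass(frozen=True)
class VariantObservation:
    """One candidate somatic variant in one tumour sample.

    ``caller_calls`` maps caller name to its status for this observation;
    ``normal_support`` maps normal-control id to supporting read count from
    pileup of that normal.
    """

    variant_key: VariantKey
    sample_id: str
    caller_calls: Mapping[str, CallStatus] = field(default_factory=dict)
    normal_support: Mapping[str, int] = field(default_factory=dict)
    tumour_alt_reads: int = 0
    tumour_depth: int = 0

    def __post_init__(self) -> None:
        chrom, pos, ref, alt = self.variant_key
        if pos < 1:
            raise ValueError("variant position must be >= 1")
        if ref == alt:
            raise ValueError("ref and alt alleles must differ")
        if self.tumour_alt_reads > self.tumour_depth:
            raise ValueError("alt reads exceed depth")
        for status in self.caller_calls.values():
            CallStatus(status)
        for n, reads in self.normal_support.items():
            if reads < 0:
                raise ValueError(f"negative read count for normal {n!r}")


@dataclass(frozen=True)
class BlacklistEntry:
    variant_key: VariantKey
    source: str  # "normal_panel" | "reject_ratio"
    evidence: str


def consensus_accept(
    obs: VariantObservation,
    callers: tuple[str, ...] = DEFAULT_CALLERS,
) -> bool:
    """True iff at least 2 of the 3 configured callers marked the variant pass."""
    if len(callers) != 3:
        raise ValueError("exactly three callers must be configured")
    for caller in obs.caller_calls:
        if caller not in callers:
            raise ValueError(f"unknown caller {caller!r}")
    n_pass = sum(
        1
        for c in callers
        if CallStatus(obs.caller_calls.get(c, CallStatus.NOT_CALLED)) is CallStatus.PASS
    )
    return n_pass >= 2


def build_normal_panel_blacklist(
    all_obs: Iterable[VariantObservation],
    min_reads: int = 3,
    min_normals: int = 2,
) -> set[BlacklistEntry]:
    """Blacklist variants supported by >= min_reads reads in more than
    min_normals normal controls (strict inequality on the normal count)."""
    support: dict[VariantKey, dict[str, int]] = defaultdict(dict)
    for obs in all_obs:
        for normal_id, reads in obs.normal_support.items():
            if reads < 0:
                raise ValueError("negative read count")
            prev = support[obs.variant_key].get(normal_id, 0)
            support[obs.variant_key][normal_id] = max(prev, reads)
    entries: set[BlacklistEntry] = set()
    for key, per_normal in support.items():
        hits = sorted(n for n, r in per_normal.items() if r >= min_reads)
        if len(hits) > min_normals:
            entries.add(
                BlacklistEntry(
                    variant_key=key,
                    source="normal_panel",
                    evidence=f"{len(hits)} normals with >={min_reads} reads",
                )
            )
    return entries


def build_reject_ratio_blacklist(
    all_obs: Iterable[VariantObservation],
) -> set[BlacklistEntry]:
    """Blacklist variants whose pooled reject:pass ratio exceeds one.

    Observations are pooled over all samples and callers; ``not_called``
    contributes to neither count.  A variant with zero passes and at least
    one reject has infinite ratio and is blacklisted; a ratio of exactly one
    is kept.
    """
    passes: dict[VariantKey, int] = defaultdict(int)
    rejects: dict[VariantKey, int] = defaultdict(int)
    for obs in all_obs:
        for status in obs.caller_calls.values():
            status = CallStatus(status)
            if status is CallStatus.PASS:
                passes[obs.variant_key] += 1
            elif status is CallStatus.REJECT:
                rejects[obs.variant_key] += 1
    entries: set[BlacklistEntry] = set()
    for key in set(passes) | set(rejects):
        p, r = passes[key], rejects[key]
        if r > p:
            entries.add(
                BlacklistEntry(
                    variant_key=key,
                    source="reject_ratio",
                    evidence=f"reject={r},pass={p}",
                )
            )
    return entries


def apply_filters(
    accepted: Iterable[VariantObservation],
    blacklists: Iterable[set[BlacklistEntry]],
) -> tuple[list[VariantObservation], dict[VariantKey, list[str]]]:
    """Remove consensus-accepted observations whose variant key is on any
    blacklist.  Returns (kept observations, removal provenance keyed by
    variant, listing each triggering rule)."""
    removed_by: dict[VariantKey, list[str]] = defaultdict(list)
    for bl in blacklists:
        for entry in bl:
            if entry.source not in removed_by[entry.variant_key]:
                removed_by[entry.variant_key].append(entry.source)
    kept = [obs for obs in accepted if obs.variant_key not in removed_by]
    seen = {obs.variant_key for obs in accepted}
    provenance = {
        k: sorted(v) for k, v in removed_by.items() if k in seen
    }
    return kept, provenance


def tumour_mutation_burden(
    n_variants: int,
    effective_genome_mb: float = 3100.0,
) -> float:
    """Somatic mutations per megabase for one sample."""
    if effective_genome_mb <= 0:
        raise ValueError("effective_genome_mb must be positive")
    if n_variants < 0:
        raise ValueError("variant count must be non-negative")
    return n_variants / effective_genome_mb
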