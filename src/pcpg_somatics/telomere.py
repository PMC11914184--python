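"""Telomere content, tumour:blood enrichment classification, and
telomere-variant-repeat (TVR) differential-usage statistics.

Telomere content is intratelomeric reads per million GC-matched reads; the
same formula serves genome and transcriptome (TERRA) counts.  A tumour is
telomere-enriched when the log2 tumour:blood content ratio strictly exceeds
0.5.  TVR usage is compared between C-circle-positive and -negative tumour
groups on normalized tumour/normal count ratios with a two-tailed two-sample
t-test and Benjamini-Hochberg correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CANONICAL_TVR",
    "ENRICHMENT_LOG2_THRESHOLD",
    "TelomereProfile",
    "telomere_content",
    "enrichment_ratio",
    "canonical_tvr_proportion",
    "bh_adjust",
    "tvr_differential",
]

CANONICAL_TVR = "TTAGGG"
ENRICHMENT_LOG2_THRESHOLD = 0.5


@dataclass(frozen=True)
class TelomereProfile:
    """Per-sample read-class counts from a telomere read-counting tool."""

    sample_id: str
    role: str  # "tumour" | "blood" | "rna"
    intratelomeric_reads: int
    gc_matched_total_reads: int
    total_reads: int
    tvr_counts: Mapping[str, int] = field(default_factory=dict)
    ccircle_status: str = "unknown"  # "positive" | "negative" | "unknown"

    def __post_init__(self) -> None:
        if self.role not in ("tumour", "blood", "rna"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.ccircle_status not in ("positive", "negative", "unknown"):
            raise ValueError(f"unknown c-circle status {self.ccircle_status!r}")
        if min(self.intratelomeric_reads, self.gc_matched_total_reads,
               self.total_reads) < 0:
            raise ValueError("read counts must be non-negative")
        if self.gc_matched_total_reads > self.total_reads:
            raise ValueError("GC-matched reads exceed total reads")
        if any(v < 0 for v in self.tvr_counts.values()):
            raise ValueError("TVR counts must be non-negative")


def telomere_content(p: TelomereProfile) -> float:
    """Intratelomeric reads x 1e6 / GC-matched total reads."""
    if p.gc_matched_total_reads <= 0:
        raise ValueError("GC-matched total must be positive")
    return p.intratelomeric_reads * 1e6 / p.gc_matched_total_reads


def enrichment_ratio(
    tumour: TelomereProfile,
    blood: TelomereProfile,
    threshold: float = ENRICHMENT_LOG2_THRESHOLD,
) -> tuple[float, bool]:
    """(log2 tumour:blood content ratio, enriched iff ratio > threshold)."""
    ct = telomere_content(tumour)
    cn = telomere_content(blood)
    if cn <= 0 or ct <= 0:
        raise ValueError("telomere contents must be positive for a log ratio")
    ratio = math.log2(ct / cn)
    return ratio, ratio > threshold


def canonical_tvr_proportion(p: TelomereProfile) -> float:
    """Proportion of canonical TTAGGG repeats among intratelomeric reads."""
    if p.intratelomeric_reads <= 0:
        raise ValueError("no intratelomeric reads")
    prop = p.tvr_counts.get(CANONICAL_TVR, 0) / p.intratelomeric_reads
    if not 0.0 <= prop <= 1.0:
        raise ValueError("TVR count exceeds intratelomeric reads")
    return prop


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1).

    NaN inputs propagate to NaN outputs and are excluded from the adjustment.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # step-up: running minimum from the largest p downwards
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    result = np.empty(m)
    result[order] = adj
    out[mask] = result
    return out


def _normalizer(p: TelomereProfile, normalization: str) -> int:
    if normalization == "intratelomeric":
        return p.intratelomeric_reads
    if normalization == "total":
        return p.total_reads
    raise ValueError(f"unknown normalization {normalization!r}")


def tvr_differential(
    pairs: Iterable[tuple[TelomereProfile, TelomereProfile]],
    normalization: str = "total",
    alpha_raw: float = 0.05,
    alpha_bh: float = 0.1,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-TVR differential usage between C-circle positive and negative pairs.

    For each (tumour, normal) pair and each TVR pattern, the TVR count is
    normalized by the chosen denominator in each sample and the tumour/normal
    ratio of normalized counts is formed.  Ratios are compared between
    C-circle positive and negative groups (tumour annotation) with a
    two-tailed t-test (Welch by default), then Benjamini-Hochberg adjusted
    across TVRs.  Returns a table with columns
    (tvr, normalization, n_pos, n_neg, t, p, p_bh, significant_raw,
    significant_bh); degenerate TVRs get NaN statistics.
    """
    pairs = list(pairs)
    groups: dict[str, list[TelomereProfile]] = {"positive": [], "negative": []}
    ratios: dict[str, dict[str, list[float]]] = {}
    patterns: list[str] = []
    for tumour, normal in pairs:
        for prof in (tumour, normal):
            for pat in prof.tvr_counts:
                if pat not in patterns:
                    patterns.append(pat)
    for tumour, normal in pairs:
        status = tumour.ccircle_status
        if status not in ("positive", "negative"):
            continue
        groups[status].append(tumour)
        dt = _normalizer(tumour, normalization)
        dn = _normalizer(normal, normalization)
        if dt <= 0 or dn <= 0:
            raise ValueError("normalization denominator must be positive")
        for pat in patterns:
            nt = tumour.tvr_counts.get(pat, 0) / dt
            nn = normal.tvr_counts.get(pat, 0) / dn
            ratio = nt / nn if nn > 0 else np.nan
            ratios.setdefault(pat, {"positive": [], "negative": []})
            ratios[pat][status].append(ratio)
    if not groups["positive"] or not groups["negative"]:
        raise ValueError("both C-circle groups must be non-empty")

    rows = []
    for pat in patterns:
        pos = np.array([r for r in ratios[pat]["positive"] if not np.isnan(r)])
        neg = np.array([r for r in ratios[pat]["negative"] if not np.isnan(r)])
        if len(pos) < 2 or len(neg) < 2:
            t_stat, p_val = np.nan, np.nan
        elif pos.std(ddof=1) == 0 and neg.std(ddof=1) == 0:
            # zero-variance degenerate case: p=1 on equal means, else NA
            t_stat = 0.0 if pos.mean() == neg.mean() else np.nan
            p_val = 1.0 if pos.mean() == neg.mean() else np.nan
        else:
            t_stat, p_val = stats.ttest_ind(pos, neg, equal_var=equal_var)
        rows.append(
            {
                "tvr": pat,
                "normalization": normalization,
                "n_pos": len(pos),
                "n_neg": len(neg),
                "t": t_stat,
                "p": p_val,
            }
        )
    table = pd.DataFrame(rows)
    table["p_bh"] = bh_adjust(table["p"].to_numpy())
    table["significant_raw"] = table["p"] < alpha_raw
    table["significant_bh"] = table["p_bh"] < alpha_bh
    return table
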