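"""Plain-text readers and writers for the pipeline's exchange formats.

All writers are deterministic (sorted records, fixed float formatting) so
that identical inputs yield byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cn_msi import CNSegment, MsiInput, gistic_transform
from .snv_consensus import CallStatus, DEFAULT_CALLERS, VariantObservation
from .sv_filter import SVCall
from .telomere import TelomereProfile

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_seg",
    "read_seg",
    "write_gistic_seg",
    "write_telomere_table",
    "read_telomere_table",
    "write_catalog",
    "read_catalog",
    "write_signature_matrix",
    "read_signature_matrix",
    "write_sv_table",
    "read_sv_table",
    "write_blacklist",
    "write_msi_table",
    "read_msi_table",
    "write_recall_grid",
    "read_recall_grid",
]

_VCF_CHROM_ORDER = {str(c): c for c in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25}


def _chrom_rank(chrom: str) -> tuple[int, str]:
    return (_VCF_CHROM_ORDER.get(chrom.removeprefix("chr"), 99), chrom)


def write_vcf(path: str | Path, observations: Sequence[VariantObservation]) -> None:
    """Minimal VCF 4.2: one record per observation, caller statuses in INFO
    (CALLER_<name>), sample read support as AD/DP."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Tumour sample id">',
    ]
    for caller in DEFAULT_CALLERS:
        lines.append(
            f'##INFO=<ID=CALLER_{caller.upper()},Number=1,Type=String,'
            f'Description="Status from {caller}">'
        )
    lines.append(
        '##INFO=<ID=NSUP,Number=.,Type=String,'
        'Description="Normal panel support normal:reads">'
    )
    lines.append(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">'
    )
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    chroms = sorted({o.variant_key[0] for o in observations}, key=_chrom_rank)
    for chrom in chroms:
        lines.append(f"##contig=<ID={chrom}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOUR")
    records = sorted(
        observations,
        key=lambda o: (_chrom_rank(o.variant_key[0]), o.variant_key[1],
                       o.variant_key[2], o.variant_key[3], o.sample_id),
    )
    for obs in records:
        chrom, pos, ref, alt = obs.variant_key
        info = [f"SAMPLE={obs.sample_id}"]
        for caller in DEFAULT_CALLERS:
            status = CallStatus(
                obs.caller_calls.get(caller, CallStatus.NOT_CALLED)
            ).value
            info.append(f"CALLER_{caller.upper()}={status}")
        if obs.normal_support:
            sup = ",".join(
                f"{n}:{r}" for n, r in sorted(obs.normal_support.items())
            )
            info.append(f"NSUP={sup}")
        ref_reads = obs.tumour_depth - obs.tumour_alt_reads
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t{';'.join(info)}\t"
            f"AD:DP\t{ref_reads},{obs.tumour_alt_reads}:{obs.tumour_depth}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> list[VariantObservation]:
    """Parse VCFs produced by :func:`write_vcf`."""
    observations = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        chrom, pos, _, ref, alt = fields[0], int(fields[1]), fields[2], fields[3], fields[4]
        info = dict(
            kv.split("=", 1) for kv in fields[7].split(";") if "=" in kv
        )
        caller_calls = {}
        for caller in DEFAULT_CALLERS:
            raw = info.get(f"CALLER_{caller.upper()}", "not_called")
            caller_calls[caller] = CallStatus(raw)
        normal_support = {}
        if "NSUP" in info:
            for item in info["NSUP"].split(","):
                nid, reads = item.rsplit(":", 1)
                normal_support[nid] = int(reads)
        ad, dp = fields[9].split(":")
        alt_reads = int(ad.split(",")[1])
        observations.append(
            VariantObservation(
                variant_key=(chrom, pos, ref, alt),
                sample_id=info.get("SAMPLE", "TUMOUR"),
                caller_calls=caller_calls,
                normal_support=normal_support,
                tumour_alt_reads=alt_reads,
                tumour_depth=int(dp),
            )
        )
    return observations


_SEG_COLUMNS = [
    "sample", "chrom", "start", "end", "n_markers",
    "major_cn", "minor_cn", "purity", "ploidy",
]


def write_seg(path: str | Path, segments: Iterable[CNSegment]) -> None:
    rows = [
        (s.sample_id, s.chrom, s.start, s.end, s.n_markers,
         repr(s.major_cn), repr(s.minor_cn),
         repr(s.purity), repr(s.sample_ploidy))
        for s in sorted(
            segments, key=lambda s: (s.sample_id, _chrom_rank(s.chrom), s.start)
        )
    ]
    df = pd.DataFrame(rows, columns=_SEG_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_seg(path: str | Path) -> list[CNSegment]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        CNSegment(
            sample_id=str(r["sample"]),
            chrom=str(r["chrom"]),
            start=int(r["start"]),
            end=int(r["end"]),
            n_markers=int(r["n_markers"]),
            major_cn=float(r["major_cn"]),
            minor_cn=float(r["minor_cn"]),
            purity=float(r["purity"]),
            sample_ploidy=float(r["ploidy"]),
        )
        for _, r in df.iterrows()
    ]


def write_gistic_seg(path: str | Path, segments: Iterable[CNSegment]) -> None:
    """Six-column SEG file with the log2(CN + 0.01) - 1 transformed value."""
    rows = [
        (s.sample_id, s.chrom, s.start, s.end, s.n_markers,
         f"{gistic_transform(s.total_cn):.6f}")
        for s in sorted(
            segments, key=lambda s: (s.sample_id, _chrom_rank(s.chrom), s.start)
        )
    ]
    df = pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "n_markers", "seg_value"]
    )
    df.to_csv(path, sep="\t", index=False)


def write_telomere_table(
    path: str | Path, profiles: Sequence[TelomereProfile]
) -> None:
    patterns = sorted({p for prof in profiles for p in prof.tvr_counts})
    rows = []
    for prof in sorted(profiles, key=lambda p: (p.sample_id, p.role)):
        row = {
            "sample": prof.sample_id,
            "role": prof.role,
            "intratelomeric": prof.intratelomeric_reads,
            "gc_matched_total": prof.gc_matched_total_reads,
            "total_reads": prof.total_reads,
            "ccircle": prof.ccircle_status,
        }
        for pat in patterns:
            row[f"tvr_{pat}"] = prof.tvr_counts.get(pat, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_telomere_table(path: str | Path) -> list[TelomereProfile]:
    df = pd.read_csv(path, sep="\t")
    tvr_cols = [c for c in df.columns if c.startswith("tvr_")]
    return [
        TelomereProfile(
            sample_id=str(r["sample"]),
            role=str(r["role"]),
            intratelomeric_reads=int(r["intratelomeric"]),
            gc_matched_total_reads=int(r["gc_matched_total"]),
            total_reads=int(r["total_reads"]),
            tvr_counts={c[4:]: int(r[c]) for c in tvr_cols},
            ccircle_status=str(r["ccircle"]),
        )
        for _, r in df.iterrows()
    ]


def write_catalog(path: str | Path, catalogs: pd.DataFrame | pd.Series) -> None:
    df = catalogs.to_frame() if isinstance(catalogs, pd.Series) else catalogs
    df.to_csv(path, sep="\t", index_label="context")


def read_catalog(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="context")


def write_signature_matrix(path: str | Path, signatures: pd.DataFrame) -> None:
    signatures.to_csv(path, sep="\t", index_label="context", float_format="%.10g")


def read_signature_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="context")


_SV_COLUMNS = [
    "sample", "patient", "chrom1", "pos1", "strand1",
    "chrom2", "pos2", "strand2", "split_reads", "paired_reads", "status",
]


def write_sv_table(path: str | Path, calls: Sequence[SVCall]) -> None:
    rows = [
        (c.sample_id, c.patient_id, c.bp1[0], c.bp1[1], c.bp1[2],
         c.bp2[0], c.bp2[1], c.bp2[2], c.split_reads, c.paired_reads,
         c.caller_status)
        for c in sorted(calls, key=lambda c: (c.sample_id, c.key))
    ]
    pd.DataFrame(rows, columns=_SV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sv_table(path: str | Path) -> list[SVCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom1": str, "chrom2": str})
    return [
        SVCall(
            sample_id=str(r["sample"]),
            patient_id=str(r["patient"]),
            bp1=(str(r["chrom1"]), int(r["pos1"]), str(r["strand1"])),
            bp2=(str(r["chrom2"]), int(r["pos2"]), str(r["strand2"])),
            split_reads=int(r["split_reads"]),
            paired_reads=int(r["paired_reads"]),
            caller_status=str(r["status"]),
        )
        for _, r in df.iterrows()
    ]


def write_blacklist(path: str | Path, entries) -> None:
    rows = sorted(
        (f"{e.variant_key[0]}:{e.variant_key[1]}:{e.variant_key[2]}:"
         f"{e.variant_key[3]}", e.source, e.evidence)
        for e in entries
    )
    pd.DataFrame(rows, columns=["variant", "source", "evidence"]).to_csv(
        path, sep="\t", index=False
    )


def write_msi_table(path: str | Path, inputs: Sequence[MsiInput]) -> None:
    rows = [
        (m.sample_id, m.microsatellite_indel_count, f"{m.callable_megabases:.6g}")
        for m in sorted(inputs, key=lambda m: m.sample_id)
    ]
    pd.DataFrame(rows, columns=["sample", "ms_indels", "callable_mb"]).to_csv(
        path, sep="\t", index=False
    )


def read_msi_table(path: str | Path) -> list[MsiInput]:
    df = pd.read_csv(path, sep="\t")
    return [
        MsiInput(
            sample_id=str(r["sample"]),
            microsatellite_indel_count=int(r["ms_indels"]),
            callable_megabases=float(r["callable_mb"]),
        )
        for _, r in df.iterrows()
    ]


def write_recall_grid(path: str | Path, matrix) -> None:
    """Per-patient recall grid: variant_key, sample, alt, total (+ omega)."""
    rows = []
    for i, key in enumerate(matrix.variant_keys):
        vid = f"{key[0]}:{key[1]}:{key[2]}:{key[3]}"
        for j, sample in enumerate(matrix.sample_ids):
            row = {
                "variant": vid,
                "sample": sample,
                "alt": int(matrix.alt[i, j]),
                "total": int(matrix.total[i, j]),
            }
            if matrix.vrp is not None:
                row["omega"] = f"{matrix.vrp[i, j]:.6g}"
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_recall_grid(path: str | Path) -> dict[str, dict[tuple, tuple[int, int]]]:
    df = pd.read_csv(path, sep="\t")
    counts: dict[str, dict[tuple, tuple[int, int]]] = {}
    for _, r in df.iterrows():
        chrom, pos, ref, alt = str(r["variant"]).split(":")
        key = (chrom, int(pos), ref, alt)
        counts.setdefault(str(r["sample"]), {})[key] = (int(r["alt"]), int(r["total"]))
    return counts


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
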