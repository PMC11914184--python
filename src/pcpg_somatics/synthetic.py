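"""Seeded synthetic-cohort generator with recorded ground truth.

Every fixture the pipeline stages consume is generated here: three-caller
somatic call sets with panel-recurrent artifacts, clone trees with binomial
read counts, allele-specific copy-number segments under known purity/ploidy,
telomere / TVR count tables for normal vs enriched vs ALT-like samples,
signature-mixture mutation catalogs, and microsatellite indel burdens.

Determinism contract: identical (seed, config) pairs produce byte-identical
outputs.  The root seed is expanded into fixed per-stream substreams so that
adding one generator never shifts another.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clonal import ClonalVariantMatrix, variant_read_probability
from .cn_msi import CNSegment, MsiInput
from .snv_consensus import CallStatus, DEFAULT_CALLERS, VariantObservation
from .sv_filter import SVCall
from .telomere import CANONICAL_TVR, TelomereProfile

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "simulate_caller_calls",
    "simulate_cn_segments",
    "simulate_clonal_reads",
    "simulate_telomere_profiles",
    "simulate_signature_catalog",
    "simulate_sv_calls",
    "simulate_msi_inputs",
    "toy_signature_matrix",
]

# fixed substream ids: appending new streams must not renumber existing ones
_STREAMS = {
    "calls": 1,
    "reads": 2,
    "telomere": 3,
    "catalog": 4,
    "segments": 5,
    "sv": 6,
    "msi": 7,
}

_CHROMS = [str(c) for c in range(1, 23)]
_CHROM_LEN = 50_000_000  # synthetic coordinate space per chromosome

DEFAULT_TVR_PATTERNS = (
    CANONICAL_TVR, "TGAGGG", "TCAGGG", "TTGGGG", "GTAGGG", "TAAGGG", "TTCGGG",
)


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[name]])


@dataclass(frozen=True)
class CohortConfig:
    """Knobs for the synthetic cohort; free parameters, not cohort estimates."""

    seed: int = 0
    n_patients: int = 4
    samples_per_patient: int = 2
    n_true_variants: int = 100
    n_artifact_variants: int = 40
    n_normals: int = 8
    caller_sensitivity: tuple[float, float, float] = (0.95, 0.95, 0.95)
    artifact_reject_prob: float = 0.7
    depth_mean: float = 60.0
    purity_range: tuple[float, float] = (0.4, 0.9)
    ploidy_choices: tuple[float, ...] = (2.0, 3.0, 4.0)
    clone_tree_depth: int = 2
    signature_mix: Mapping[str, float] = field(
        default_factory=lambda: {"SIG1": 0.7, "SIG2": 0.3}
    )
    n_catalog_mutations: int = 5000
    telomere_scenarios: Mapping[str, int] = field(
        default_factory=lambda: {"normal": 4, "enriched": 2, "alt_like": 2}
    )
    msi_rate_range: tuple[float, float] = (0.0, 2.0)
    # artifact plumbing beyond the headline knobs
    artifact_detect_prob: float = 0.9
    artifact_panel_fraction: float = 0.6
    telomere_gc_total: int = 1_000_000
    telomere_base_content: float = 500.0  # reads per GC-matched million
    telomere_enriched_log2: float = 1.0
    telomere_noise: float = 1.0  # 0 disables count noise entirely
    alt_canonical_depletion: float = 0.5
    tvr_patterns: tuple[str, ...] = DEFAULT_TVR_PATTERNS

    def __post_init__(self) -> None:
        counts = {
            "n_patients": self.n_patients,
            "samples_per_patient": self.samples_per_patient,
            "n_normals": self.n_normals,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.n_true_variants < 0 or self.n_artifact_variants < 0:
            raise ValueError("variant counts must be non-negative")
        probs = list(self.caller_sensitivity) + [
            self.artifact_reject_prob,
            self.artifact_detect_prob,
            self.artifact_panel_fraction,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if len(self.caller_sensitivity) != 3:
            raise ValueError("three caller sensitivities required")
        if abs(sum(self.signature_mix.values()) - 1.0) > 1e-9:
            raise ValueError("signature_mix weights must sum to 1")
        if any(w < 0 for w in self.signature_mix.values()):
            raise ValueError("signature_mix weights must be non-negative")
        lo, hi = self.purity_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("purity_range must be an interval within [0, 1]")
        if any(p <= 0 for p in self.ploidy_choices):
            raise ValueError("ploidy choices must be positive")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        for scen in self.telomere_scenarios:
            if scen not in ("normal", "enriched", "alt_like"):
                raise ValueError(f"unknown telomere scenario {scen!r}")

    @property
    def tumour_sample_ids(self) -> list[str]:
        return [
            f"P{p:03d}-T{s}"
            for p in range(self.n_patients)
            for s in range(self.samples_per_patient)
        ]

    @property
    def normal_ids(self) -> list[str]:
        return [f"N{n:03d}" for n in range(self.n_normals)]


@dataclass
class GroundTruth:
    true_variant_ids: set = field(default_factory=set)
    artifact_ids: set = field(default_factory=set)
    panel_artifact_ids: set = field(default_factory=set)
    clone_fractions: np.ndarray | None = None  # clones x samples
    variant_clone_assignment: dict = field(default_factory=dict)
    true_exposures: Mapping[str, float] = field(default_factory=dict)
    telomere_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.true_variant_ids & self.artifact_ids:
            raise ValueError("true and artifact id sets must be disjoint")


def _random_variant_keys(rng: np.random.Generator, n: int) -> list[tuple]:
    keys: set[tuple] = set()
    bases = np.array(list("ACGT"))
    while len(keys) < n:
        chrom = _CHROMS[rng.integers(len(_CHROMS))]
        pos = int(rng.integers(1, _CHROM_LEN))
        ref, alt = rng.choice(bases, size=2, replace=False)
        keys.add((chrom, pos, str(ref), str(alt)))
    return sorted(keys)


def key_id(key: tuple) -> str:
    return f"{key[0]}:{key[1]}:{key[2]}:{key[3]}"


def simulate_caller_calls(
    config: CohortConfig,
) -> tuple[list[VariantObservation], GroundTruth]:
    """Three-caller somatic call sets with recurrent artifacts.

    True variants are detected per caller with ``caller_sensitivity`` and
    always labelled pass; artifacts are detected with
    ``artifact_detect_prob``, labelled reject with ``artifact_reject_prob``,
    and a ``artifact_panel_fraction`` of them receive >= 3 supporting reads
    in more than two panel normals.  True variants never receive panel
    support.
    """
    rng = _stream(config.seed, "calls")
    n_total = config.n_true_variants + config.n_artifact_variants
    keys = _random_variant_keys(rng, n_total)
    perm = rng.permutation(n_total)
    true_keys = [keys[i] for i in sorted(perm[: config.n_true_variants])]
    art_keys = [keys[i] for i in sorted(perm[config.n_true_variants:])]

    samples = config.tumour_sample_ids
    normals = config.normal_ids
    truth = GroundTruth(
        true_variant_ids={key_id(k) for k in true_keys},
        artifact_ids={key_id(k) for k in art_keys},
    )
    observations: list[VariantObservation] = []

    for key in true_keys:
        sample = samples[rng.integers(len(samples))]
        calls = {}
        for caller, sens in zip(DEFAULT_CALLERS, config.caller_sensitivity):
            detected = rng.random() < sens
            calls[caller] = CallStatus.PASS if detected else CallStatus.NOT_CALLED
        depth = max(1, int(rng.poisson(config.depth_mean)))
        alt_reads = int(rng.binomial(depth, 0.4))
        observations.append(
            VariantObservation(
                variant_key=key,
                sample_id=sample,
                caller_calls=calls,
                normal_support={},
                tumour_alt_reads=alt_reads,
                tumour_depth=depth,
            )
        )

    for key in art_keys:
        # artifacts recur across a random subset of tumour samples
        n_occ = int(rng.integers(1, max(2, len(samples) // 2) + 1))
        occ = rng.choice(len(samples), size=n_occ, replace=False)
        in_panel = rng.random() < config.artifact_panel_fraction
        support: dict[str, int] = {}
        if in_panel:
            n_hit = int(rng.integers(3, config.n_normals + 1))
            hit = rng.choice(config.n_normals, size=n_hit, replace=False)
            support = {
                normals[i]: int(rng.integers(3, 11)) for i in sorted(hit)
            }
            truth.panel_artifact_ids.add(key_id(key))
        else:
            # sub-threshold stray support in at most two normals
            n_hit = int(rng.integers(0, 3))
            hit = rng.choice(config.n_normals, size=n_hit, replace=False)
            support = {normals[i]: int(rng.integers(1, 3)) for i in sorted(hit)}
        for idx in sorted(occ):
            calls = {}
            for caller in DEFAULT_CALLERS:
                if rng.random() < config.artifact_detect_prob:
                    rejected = rng.random() < config.artifact_reject_prob
                    calls[caller] = (
                        CallStatus.REJECT if rejected else CallStatus.PASS
                    )
                else:
                    calls[caller] = CallStatus.NOT_CALLED
            depth = max(1, int(rng.poisson(config.depth_mean)))
            alt_reads = int(rng.binomial(depth, 0.1))
            observations.append(
                VariantObservation(
                    variant_key=key,
                    sample_id=samples[idx],
                    caller_calls=calls,
                    normal_support=support,
                    tumour_alt_reads=alt_reads,
                    tumour_depth=depth,
                )
            )
    return observations, truth


def simulate_cn_segments(config: CohortConfig) -> list[CNSegment]:
    """Allele-specific segments per tumour sample with known purity/ploidy.

    Whole chromosomes get a single segment; a subset are perturbed away from
    the baseline ploidy state so downstream PGA and VRP branches are
    exercised.
    """
    rng = _stream(config.seed, "segments")
    segments: list[CNSegment] = []
    for sample in config.tumour_sample_ids:
        purity = float(rng.uniform(*config.purity_range))
        ploidy = float(config.ploidy_choices[rng.integers(len(config.ploidy_choices))])
        base_total = int(round(ploidy))
        for chrom in _CHROMS:
            r = rng.random()
            if r < 0.6:  # baseline state
                major = base_total - base_total // 2
                minor = base_total // 2
            elif r < 0.7:  # diploid het
                major, minor = 1, 1
            elif r < 0.8:  # single copy loss
                major, minor = 1, 0
            elif r < 0.9:  # CN-LOH
                major, minor = 2, 0
            else:  # gain
                major, minor = base_total, 1
            segments.append(
                CNSegment(
                    sample_id=sample,
                    chrom=chrom,
                    start=1,
                    end=_CHROM_LEN,
                    n_markers=int(rng.integers(500, 5000)),
                    major_cn=float(major),
                    minor_cn=float(minor),
                    purity=purity,
                    sample_ploidy=ploidy,
                )
            )
    return segments


def _chain_clone_fractions(
    rng: np.random.Generator, depth: int, n_samples: int
) -> np.ndarray:
    """Chain tree of ``depth`` clones; child fraction <= parent per sample."""
    phi = np.empty((depth, n_samples))
    phi[0] = rng.uniform(0.7, 1.0, size=n_samples)
    for level in range(1, depth):
        phi[level] = phi[level - 1] * rng.uniform(0.2, 0.9, size=n_samples)
    return phi


def simulate_clonal_reads(
    config: CohortConfig,
    segments: Sequence[CNSegment],
    clone_fractions: np.ndarray | None = None,
    sample_ids: Sequence[str] | None = None,
) -> tuple[ClonalVariantMatrix, GroundTruth]:
    """Binomial read counts for one patient under a clone tree.

    ``alt ~ Binomial(depth, omega * phi)`` with omega the VRP implied by the
    covering segment (evaluated at the fully-clonal limit, VAF -> 1) and phi
    the assigned clone's fraction; ``depth ~ Poisson(depth_mean)`` truncated
    at 1.  Pass ``clone_fractions`` (clones x samples) to pin ground truth.
    """
    rng = _stream(config.seed, "reads")
    if sample_ids is None:
        sample_ids = [f"P000-T{s}" for s in range(config.samples_per_patient)]
    sample_ids = list(sample_ids)
    by_sample: dict[str, list[CNSegment]] = {}
    for seg in segments:
        by_sample.setdefault(seg.sample_id, []).append(seg)
    for sample in sample_ids:
        if sample not in by_sample:
            raise ValueError(f"no segments for sample {sample!r}")

    if clone_fractions is None:
        phi = _chain_clone_fractions(rng, config.clone_tree_depth, len(sample_ids))
    else:
        phi = np.asarray(clone_fractions, dtype=float)
        if phi.ndim != 2 or phi.shape[1] != len(sample_ids):
            raise ValueError("clone_fractions must be clones x samples")
    n_clones = phi.shape[0]

    keys = _random_variant_keys(rng, config.n_true_variants)
    assignment = {key_id(k): int(rng.integers(n_clones)) for k in keys}

    n_var, n_samp = len(keys), len(sample_ids)
    alt = np.zeros((n_var, n_samp), dtype=int)
    total = np.zeros((n_var, n_samp), dtype=int)
    omega = np.zeros((n_var, n_samp), dtype=float)
    purity = {}
    for j, sample in enumerate(sample_ids):
        segs = by_sample[sample]
        purity[sample] = segs[0].purity
        for i, key in enumerate(keys):
            chrom, pos = key[0], key[1]
            seg = next((s for s in segs if s.contains(chrom, pos)), None)
            if seg is None:
                raise ValueError(f"variant {key} outside all segments of {sample!r}")
            w = variant_read_probability(1.0, seg.purity, seg)
            depth = max(1, int(rng.poisson(config.depth_mean)))
            frac = phi[assignment[key_id(key)], j]
            alt[i, j] = rng.binomial(depth, min(w * frac, 1.0))
            total[i, j] = depth
            omega[i, j] = w
    matrix = ClonalVariantMatrix(
        variant_keys=keys,
        sample_ids=sample_ids,
        alt=alt,
        total=total,
        vrp=omega,
        purity=purity,
    )
    truth = GroundTruth(
        true_variant_ids={key_id(k) for k in keys},
        clone_fractions=phi,
        variant_clone_assignment=assignment,
    )
    return matrix, truth


def simulate_telomere_profiles(config: CohortConfig) -> list[TelomereProfile]:
    """Tumour/blood telomere count-table pairs for each configured scenario.

    ``normal`` draws tumour and blood intratelomeric counts at the same rate;
    ``enriched`` and ``alt_like`` scale the tumour rate by
    ``2 ** telomere_enriched_log2``; ``alt_like`` additionally depletes the
    canonical TTAGGG proportion by ``alt_canonical_depletion``.  Setting
    ``telomere_noise`` to 0 makes counts deterministic (expected values).
    """
    rng = _stream(config.seed, "telomere")
    gc_total = config.telomere_gc_total
    base = config.telomere_base_content * gc_total / 1e6
    profiles: list[TelomereProfile] = []
    idx = 0
    for scenario in sorted(config.telomere_scenarios):
        n_profiles = config.telomere_scenarios[scenario]
        for _ in range(n_profiles):
            sid = f"TEL{idx:04d}"
            idx += 1
            tumour_rate = base
            canonical_frac = 0.85
            ccircle = "negative"
            if scenario in ("enriched", "alt_like"):
                tumour_rate = base * 2.0 ** config.telomere_enriched_log2
            if scenario == "alt_like":
                canonical_frac *= config.alt_canonical_depletion
                ccircle = "positive"

            def draw(rate: float) -> int:
                if config.telomere_noise == 0:
                    return int(round(rate))
                return max(1, int(rng.poisson(rate * config.telomere_noise)
                                  / config.telomere_noise))

            for role, rate, cfrac in (
                ("tumour", tumour_rate, canonical_frac),
                ("blood", base, 0.85),
            ):
                intra = draw(rate)
                n_pat = len(config.tvr_patterns)
                rest = (1.0 - cfrac) / (n_pat - 1)
                weights = np.array(
                    [cfrac if p == CANONICAL_TVR else rest
                     for p in config.tvr_patterns]
                )
                if config.telomere_noise == 0:
                    tvr = np.floor(weights * intra).astype(int)
                else:
                    tvr = rng.multinomial(intra, weights / weights.sum())
                profiles.append(
                    TelomereProfile(
                        sample_id=sid,
                        role=role,
                        intratelomeric_reads=intra,
                        gc_matched_total_reads=gc_total,
                        total_reads=gc_total * 40,
                        tvr_counts=dict(zip(config.tvr_patterns,
                                            (int(x) for x in tvr))),
                        ccircle_status=ccircle if role == "tumour" else "unknown",
                    )
                )
    return profiles


def telomere_truth_labels(config: CohortConfig) -> dict[str, str]:
    """Scenario label per generated telomere sample id."""
    labels = {}
    idx = 0
    for scenario in sorted(config.telomere_scenarios):
        for _ in range(config.telomere_scenarios[scenario]):
            labels[f"TEL{idx:04d}"] = scenario
            idx += 1
    return labels


def toy_signature_matrix(
    scheme_classes: Sequence[str],
    n_signatures: int = 5,
    seed: int = 12345,
    concentration: float = 0.3,
) -> pd.DataFrame:
    """Random sparse probability-column signature matrix for tests/demo."""
    rng = np.random.default_rng([seed, 99])
    cols = {}
    for i in range(n_signatures):
        col = rng.dirichlet(np.full(len(scheme_classes), concentration))
        cols[f"SIG{i + 1}"] = col
    return pd.DataFrame(cols, index=list(scheme_classes))


def simulate_signature_catalog(
    signatures: pd.DataFrame,
    mix: Mapping[str, float],
    n: int,
    seed: int = 0,
) -> tuple[pd.Series, Mapping[str, float]]:
    """Multinomial mutation catalog from a signature mixture.

    Returns (catalog counts over classes, ground-truth exposures n * mix).
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if any(w < 0 for w in mix.values()):
        raise ValueError("mixture weights must be non-negative")
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("mixture weights must sum to 1")
    unknown = set(mix) - set(signatures.columns)
    if unknown:
        raise ValueError(f"unknown signatures in mix: {sorted(unknown)}")
    rng = np.random.default_rng([seed, _STREAMS["catalog"]])
    probs = np.zeros(len(signatures.index))
    for sig, w in mix.items():
        probs += w * signatures[sig].to_numpy(dtype=float)
    probs = probs / probs.sum() if probs.sum() > 0 else probs
    if n == 0:
        counts = np.zeros(len(probs), dtype=int)
    else:
        counts = rng.multinomial(n, probs)
    catalog = pd.Series(counts, index=signatures.index, name="catalog")
    truth = {sig: n * w for sig, w in mix.items()}
    return catalog, truth


def simulate_sv_calls(config: CohortConfig) -> list[SVCall]:
    """Structural-variant calls with a recurrent-artifact subset.

    One in five generated breakpoint pairs is planted across more than two
    patients (pass or reject) so the recurrence blacklist has targets; read
    support spans the pass/fail boundary of the support filter.
    """
    rng = _stream(config.seed, "sv")
    calls: list[SVCall] = []
    samples = config.tumour_sample_ids
    n_events = max(10, config.n_patients * 5)
    for i in range(n_events):
        c1 = _CHROMS[rng.integers(len(_CHROMS))]
        c2 = _CHROMS[rng.integers(len(_CHROMS))]
        bp1 = (c1, int(rng.integers(1, _CHROM_LEN)), "+" if rng.random() < 0.5 else "-")
        bp2 = (c2, int(rng.integers(1, _CHROM_LEN)), "+" if rng.random() < 0.5 else "-")
        recurrent = i % 5 == 0 and config.n_patients >= 3
        if recurrent:
            n_pat = int(rng.integers(3, config.n_patients + 1))
            pats = rng.choice(config.n_patients, size=n_pat, replace=False)
        else:
            pats = [int(rng.integers(config.n_patients))]
        for p in sorted(int(x) for x in pats):
            sample = f"P{p:03d}-T{int(rng.integers(config.samples_per_patient))}"
            assert sample in samples
            calls.append(
                SVCall(
                    sample_id=sample,
                    patient_id=f"P{p:03d}",
                    bp1=bp1,
                    bp2=bp2,
                    split_reads=int(rng.integers(0, 6)),
                    paired_reads=int(rng.integers(0, 6)),
                    caller_status="reject" if (recurrent and rng.random() < 0.5)
                    else "pass",
                )
            )
    return calls


def simulate_msi_inputs(config: CohortConfig) -> list[MsiInput]:
    """Microsatellite indel burdens drawn uniformly from msi_rate_range."""
    rng = _stream(config.seed, "msi")
    lo, hi = config.msi_rate_range
    if lo < 0 or hi < lo:
        raise ValueError("invalid msi_rate_range")
    out = []
    for sample in config.tumour_sample_ids:
        mb = 3000.0
        rate = float(rng.uniform(lo, hi))
        out.append(
            MsiInput(
                sample_id=sample,
                microsatellite_indel_count=int(round(rate * mb)),
                callable_megabases=mb,
            )
        )
    return out


def config_from_dict(d: Mapping) -> CohortConfig:
    """Build a config from a JSON-style mapping, tolerating list values."""
    kwargs = dict(d)
    for key in ("caller_sensitivity", "purity_range", "ploidy_choices",
                "msi_rate_range", "tvr_patterns"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    valid = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(kwargs) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return CohortConfig(**kwargs)
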