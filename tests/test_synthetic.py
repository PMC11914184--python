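"""Generator determinism, degenerate limits and ground-truth bookkeeping."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from pcpg_somatics.clonal import cluster_frequencies
from pcpg_somatics.snv_consensus import CallStatus, consensus_accept
from pcpg_somatics.signatures import SBS96_CLASSES, fit_exposures
from pcpg_somatics.synthetic import (
    CohortConfig,
    key_id,
    simulate_caller_calls,
    simulate_clonal_reads,
    simulate_cn_segments,
    simulate_msi_inputs,
    simulate_signature_catalog,
    simulate_sv_calls,
    simulate_telomere_profiles,
    telomere_truth_labels,
    toy_signature_matrix,
)
from pcpg_somatics.telomere import enrichment_ratio, telomere_content

from .conftest import diploid_segment


class TestConfigValidation:
    def test_defaults_valid(self):
        CohortConfig()

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_patients=0)

    def test_probability_bounds(self):
        with pytest.raises(ValueError):
            CohortConfig(artifact_reject_prob=1.5)

    def test_mix_must_sum_to_one(self):
        with pytest.raises(ValueError):
            CohortConfig(signature_mix={"A": 0.5, "B": 0.4})

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(signature_mix={"A": 1.5, "B": -0.5})

    def test_bad_scenario_label(self):
        with pytest.raises(ValueError):
            CohortConfig(telomere_scenarios={"weird": 1})


class TestSimulateCallerCalls:
    def test_degenerate_limits(self):
        cfg = CohortConfig(seed=1, n_artifact_variants=0,
                           caller_sensitivity=(1.0, 1.0, 1.0))
        obs, truth = simulate_caller_calls(cfg)
        assert truth.artifact_ids == set()
        for o in obs:
            assert all(s is CallStatus.PASS for s in o.caller_calls.values())
            assert len(o.caller_calls) == 3
            assert o.normal_support == {}
            assert consensus_accept(o)

    def test_determinism(self, small_config):
        a = simulate_caller_calls(small_config)
        b = simulate_caller_calls(small_config)
        assert a[0] == b[0]
        assert a[1].true_variant_ids == b[1].true_variant_ids

    def test_seed_changes_output(self, small_config):
        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        assert simulate_caller_calls(small_config)[0] != \
            simulate_caller_calls(other)[0]

    def test_artifact_fraction_within_binomial_ci(self):
        # n=1000 at f=0.5; detection of each variant by >=1 caller is
        # essentially certain, so emitted id proportions track the config.
        cfg = CohortConfig(seed=9, n_true_variants=500, n_artifact_variants=500)
        _, truth = simulate_caller_calls(cfg)
        n = len(truth.true_variant_ids) + len(truth.artifact_ids)
        assert n == 1000
        lo = stats.binom.ppf(0.005, 1000, 0.5) / 1000
        hi = stats.binom.ppf(0.995, 1000, 0.5) / 1000
        frac = len(truth.artifact_ids) / n
        assert lo <= frac <= hi

    def test_ground_truth_partition_complete(self, small_config):
        obs, truth = simulate_caller_calls(small_config)
        for o in obs:
            vid = key_id(o.variant_key)
            assert (vid in truth.true_variant_ids) ^ (vid in truth.artifact_ids)

    def test_true_variants_never_in_normals(self, small_config):
        obs, truth = simulate_caller_calls(small_config)
        for o in obs:
            if key_id(o.variant_key) in truth.true_variant_ids:
                assert o.normal_support == {}

    def test_panel_artifacts_meet_blacklist_rule(self, small_config):
        obs, truth = simulate_caller_calls(small_config)
        for o in obs:
            if key_id(o.variant_key) in truth.panel_artifact_ids:
                strong = [r for r in o.normal_support.values() if r >= 3]
                assert len(strong) > 2


class TestSimulateClonalReads:
    def _segments(self, samples=("P000-T0",)):
        return [diploid_segment(sample=s, chrom=str(c))
                for s in samples for c in range(1, 23)]

    def test_high_depth_vaf_concentration(self):
        cfg = CohortConfig(seed=2, n_true_variants=50, depth_mean=10_000.0,
                           samples_per_patient=1)
        phi = np.array([[1.0]])
        m, _ = simulate_clonal_reads(cfg, self._segments(), clone_fractions=phi,
                                     sample_ids=["P000-T0"])
        vaf = m.alt.sum() / m.total.sum()
        assert abs(vaf - 0.5) < 0.02

    def test_zero_fraction_clone_silent(self):
        cfg = CohortConfig(seed=3, n_true_variants=40, samples_per_patient=1)
        phi = np.array([[0.0]])
        m, truth = simulate_clonal_reads(cfg, self._segments(),
                                         clone_fractions=phi,
                                         sample_ids=["P000-T0"])
        assert (m.alt == 0).all()

    def test_determinism(self):
        cfg = CohortConfig(seed=4, n_true_variants=30, samples_per_patient=2)
        segs = self._segments(samples=("P000-T0", "P000-T1"))
        phi = np.array([[0.8, 0.6]])
        a, _ = simulate_clonal_reads(cfg, segs, clone_fractions=phi,
                                     sample_ids=["P000-T0", "P000-T1"])
        b, _ = simulate_clonal_reads(cfg, segs, clone_fractions=phi,
                                     sample_ids=["P000-T0", "P000-T1"])
        np.testing.assert_array_equal(a.alt, b.alt)
        np.testing.assert_array_equal(a.total, b.total)

    def test_counts_valid(self):
        cfg = CohortConfig(seed=5, n_true_variants=25)
        segs = self._segments(samples=("P000-T0", "P000-T1"))
        m, truth = simulate_clonal_reads(cfg, segs,
                                         sample_ids=["P000-T0", "P000-T1"])
        assert (m.total >= 1).all()
        assert (m.alt >= 0).all() and (m.alt <= m.total).all()
        assert truth.clone_fractions.shape[0] == cfg.clone_tree_depth
        # chain-tree ordering: child fraction <= parent in every sample
        diffs = np.diff(truth.clone_fractions, axis=0)
        assert (diffs <= 1e-12).all()

    def test_missing_segment_errors(self):
        cfg = CohortConfig(seed=6, n_true_variants=5)
        segs = [diploid_segment(sample="P000-T0", chrom="1")]
        with pytest.raises(ValueError, match="segment"):
            simulate_clonal_reads(cfg, segs, sample_ids=["P000-T0"])


class TestSimulateTelomereProfiles:
    def test_normal_scenario_centred_on_zero(self):
        cfg = CohortConfig(seed=7, telomere_scenarios={"normal": 200})
        profiles = simulate_telomere_profiles(cfg)
        by_sample = {}
        for p in profiles:
            by_sample.setdefault(p.sample_id, {})[p.role] = p
        ratios = [
            enrichment_ratio(d["tumour"], d["blood"])[0]
            for d in by_sample.values()
        ]
        assert abs(np.mean(ratios)) < 0.05

    def test_enriched_scenario_flagged_downstream(self):
        cfg = CohortConfig(seed=8, telomere_scenarios={"enriched": 100},
                           telomere_enriched_log2=1.0)
        profiles = simulate_telomere_profiles(cfg)
        by_sample = {}
        for p in profiles:
            by_sample.setdefault(p.sample_id, {})[p.role] = p
        flags = [
            enrichment_ratio(d["tumour"], d["blood"])[1]
            for d in by_sample.values()
        ]
        assert np.mean(flags) > 0.95

    def test_zero_noise_exact_ratio(self):
        cfg = CohortConfig(seed=9, telomere_scenarios={"enriched": 1},
                           telomere_noise=0.0, telomere_enriched_log2=1.0)
        profiles = simulate_telomere_profiles(cfg)
        tumour = next(p for p in profiles if p.role == "tumour")
        blood = next(p for p in profiles if p.role == "blood")
        ratio, _ = enrichment_ratio(tumour, blood)
        assert ratio == pytest.approx(1.0, abs=1e-12)

    def test_alt_like_depletes_canonical(self):
        cfg = CohortConfig(
            seed=10,
            telomere_scenarios={"normal": 20, "alt_like": 20},
            alt_canonical_depletion=0.5,
        )
        profiles = simulate_telomere_profiles(cfg)
        labels = telomere_truth_labels(cfg)
        from pcpg_somatics.telomere import canonical_tvr_proportion
        normal = [canonical_tvr_proportion(p) for p in profiles
                  if p.role == "tumour" and labels[p.sample_id] == "normal"]
        alt = [canonical_tvr_proportion(p) for p in profiles
               if p.role == "tumour" and labels[p.sample_id] == "alt_like"]
        assert np.mean(alt) < np.mean(normal) * 0.7

    def test_alt_like_marked_ccircle_positive(self):
        cfg = CohortConfig(seed=11, telomere_scenarios={"alt_like": 3})
        tumours = [p for p in simulate_telomere_profiles(cfg)
                   if p.role == "tumour"]
        assert all(p.ccircle_status == "positive" for p in tumours)

    def test_determinism(self, small_config):
        assert simulate_telomere_profiles(small_config) == \
            simulate_telomere_profiles(small_config)


class TestSimulateSignatureCatalog:
    def test_pure_mixture_sums(self):
        sigs = toy_signature_matrix(SBS96_CLASSES, n_signatures=2, seed=1)
        catalog, truth = simulate_signature_catalog(sigs, {"SIG1": 1.0}, 500,
                                                    seed=0)
        assert catalog.sum() == 500
        assert truth == {"SIG1": 500.0}
        # support restricted to signature A's support
        assert ((catalog > 0) <= (sigs["SIG1"] > 0)).all()

    def test_n_zero_gives_zero_vector(self):
        sigs = toy_signature_matrix(SBS96_CLASSES, n_signatures=2, seed=1)
        catalog, _ = simulate_signature_catalog(sigs, {"SIG1": 1.0}, 0, seed=0)
        assert (catalog == 0).all()

    def test_refit_recovers_mixture(self):
        sigs = toy_signature_matrix(SBS96_CLASSES, n_signatures=2, seed=2)
        mix = {"SIG1": 0.7, "SIG2": 0.3}
        catalog, truth = simulate_signature_catalog(sigs, mix, 10_000, seed=3)
        fit = fit_exposures(catalog.astype(float), sigs)
        for sig, exp in truth.items():
            assert abs(fit.exposures[sig] - exp) <= 200  # 2% of total

    def test_bad_weights(self):
        sigs = toy_signature_matrix(SBS96_CLASSES, n_signatures=2, seed=1)
        with pytest.raises(ValueError):
            simulate_signature_catalog(sigs, {"SIG1": 1.5, "SIG2": -0.5}, 10)

    def test_unknown_signature(self):
        sigs = toy_signature_matrix(SBS96_CLASSES, n_signatures=2, seed=1)
        with pytest.raises(ValueError, match="unknown"):
            simulate_signature_catalog(sigs, {"NOPE": 1.0}, 10)


class TestOtherGenerators:
    def test_cn_segments_cover_autosomes(self, small_config):
        segs = simulate_cn_segments(small_config)
        samples = {s.sample_id for s in segs}
        assert samples == set(small_config.tumour_sample_ids)
        for s in segs:
            assert s.major_cn >= s.minor_cn >= 0
            assert 0 <= s.purity <= 1

    def test_sv_calls_have_recurrent_targets(self, small_config):
        calls = simulate_sv_calls(small_config)
        from pcpg_somatics.sv_filter import build_sv_recurrence_blacklist
        assert len(build_sv_recurrence_blacklist(calls)) > 0

    def test_msi_rates_within_range(self, small_config):
        for inp in simulate_msi_inputs(small_config):
            rate = inp.microsatellite_indel_count / inp.callable_megabases
            lo, hi = small_config.msi_rate_range
            assert lo - 1e-3 <= rate <= hi + 1e-3

    def test_streams_independent(self, small_config):
        before = simulate_telomere_profiles(small_config)
        simulate_caller_calls(small_config)  # consuming calls stream
        after = simulate_telomere_profiles(small_config)
        assert before == after
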