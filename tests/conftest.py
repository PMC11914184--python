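import numpy as np
import pytest

from pcpg_somatics.cn_msi import CNSegment
from pcpg_somatics.snv_consensus import CallStatus, VariantObservation
from pcpg_somatics.synthetic import CohortConfig


@pytest.fixture
def small_config():
    return CohortConfig(
        seed=7,
        n_patients=3,
        samples_per_patient=2,
        n_true_variants=50,
        n_artifact_variants=20,
        n_normals=6,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_obs(
    key=("1", 100, "A", "T"),
    sample="S1",
    calls=None,
    support=None,
    alt_reads=10,
    depth=30,
):
    return VariantObservation(
        variant_key=key,
        sample_id=sample,
        caller_calls=calls or {},
        normal_support=support or {},
        tumour_alt_reads=alt_reads,
        tumour_depth=depth,
    )


def diploid_segment(sample="S1", chrom="1", purity=0.8, **kw):
    defaults = dict(
        sample_id=sample,
        chrom=chrom,
        start=1,
        end=50_000_000,
        n_markers=1000,
        major_cn=1.0,
        minor_cn=1.0,
        purity=purity,
        sample_ploidy=2.0,
    )
    defaults.update(kw)
    return CNSegment(**defaults)


PASS = CallStatus.PASS
REJECT = CallStatus.REJECT
NOT_CALLED = CallStatus.NOT_CALLED
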