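import math

import pytest
from hypothesis import HealthCheck, settings

from mrdtrack.synthetic_data import SimConfig, generate_cohort
from mrdtrack.variant_io import Consequence, GeneRole, SomaticVariant

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def make_variant(
    patient_id="P1",
    gene="APC",
    chrom="5",
    pos=112707498,
    ref="C",
    alt="T",
    consequence=Consequence.MISSENSE,
    ffpe_vaf=0.30,
    **kwargs,
):
    """Compact SomaticVariant factory for hand-built fixtures."""
    return SomaticVariant(
        patient_id=patient_id,
        gene=gene,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        consequence=consequence,
        ffpe_vaf=ffpe_vaf,
        **kwargs,
    )


def binomial_3se(p: float, n: int) -> float:
    return 3.0 * math.sqrt(p * (1 - p) / n)


@pytest.fixture(scope="session")
def default_config():
    return SimConfig(seed=20, n_patients=200)


@pytest.fixture(scope="session")
def cohort200(default_config):
    """One 200-patient synthetic cohort shared across recovery tests."""
    return generate_cohort(default_config)
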