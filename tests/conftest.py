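import numpy as np
import pytest

from bsakit import SimulationConfig, simulate_f2
from bsakit.variants import SampleCall, VariantRecord


def make_variant(
    chrom="chr1",
    pos=100,
    ref="A",
    alt="G",
    qual=500.0,
    qd=25.0,
    mq=60.0,
    fs=1.0,
    n_alt_alleles=1,
    parent_wt=((0, 0), 30, 0),
    parent_mut=((1, 1), 0, 30),
    bulk_low=((0, 1), 27, 3),
    bulk_high=((0, 1), 3, 27),
):
    """Handmade four-sample variant with sensible passing defaults."""

    def call(spec):
        if spec is None:
            return None
        gt, rd, ad = spec
        return SampleCall(genotype=gt, ref_depth=rd, alt_depth=ad)

    samples = {}
    for role, spec in (
        ("parent_wt", parent_wt),
        ("parent_mut", parent_mut),
        ("bulk_low", bulk_low),
        ("bulk_high", bulk_high),
    ):
        c = call(spec)
        if c is not None:
            samples[role] = c
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, qual=qual, qd=qd, mq=mq, fs=fs,
        n_alt_alleles=n_alt_alleles, samples=samples,
    )


@pytest.fixture(scope="session")
def small_config():
    """A small but linkage-realistic genome: 2 Mb carrying ~240 cM."""
    return SimulationConfig(
        chromosomes=(("chr1", 2_000_000),),
        qtls=(("chr1", 1_200_000, 3.0),),
        population_size=200,
        bulk_size=32,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_f2(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
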