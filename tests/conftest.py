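import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_trio():
    """A small simulated trio shared across tests (10 Mb, defaults)."""
    from fetoscope.simulate import SimConfig, simulate_family

    cfg = SimConfig(chrom_length_bp=10_000_000, seed=7)
    ds = simulate_family(cfg)
    return ds


@pytest.fixture(scope="session")
def small_trio_parts(small_trio):
    return (
        small_trio.to_locus_records(),
        small_trio.counts_map(),
        small_trio.truth_genotypes(),
    )
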