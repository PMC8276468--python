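import pytest
from hypothesis import settings

from hadalmeta.synthetic_data import SyntheticConfig, SyntheticBundle, generate_bundle

# property tests must be reproducible run-to-run
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_bundle() -> SyntheticBundle:
    """The benchmark community: 5 hosts x 50 kb, 2 prophages each,
    5 CRISPR arrays with 30 bp exact spacers, seed 42."""
    return generate_bundle(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A miniature config for fast structural tests."""
    return SyntheticConfig(
        seed=1,
        n_hosts=3,
        host_length=6_000,
        n_prophages_per_host=1,
        prophage_length_range=(1_500, 2_000),
        n_spacer_arrays=2,
        n_reads=2_000,
        n_decoys=1,
    )
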