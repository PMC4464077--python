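import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from varscape.annotation import annotate_variants
from varscape.filtering import filter_variants, passed_records
from varscape.synthetic import SimulationConfig, make_ssrg_fixture, simulate


@pytest.fixture(scope="session")
def ssrg():
    """The 18-gene starch-synthesis panel fixture."""
    return make_ssrg_fixture(seed=1)


@pytest.fixture(scope="session")
def ssrg_annotations(ssrg):
    genome, models, records, truth = ssrg
    passed = passed_records(filter_variants(records))
    return annotate_variants(passed, models, genome)


@pytest.fixture(scope="session")
def small_sim():
    """A 2 x 1 Mb genome with a 3-window desert and a 2-window hotspot."""
    config = SimulationConfig(
        seed=42,
        desert_spans=[("chr1", 300_001, 600_000)],
        hotspot_spans=[("chr2", 600_001, 800_000, 2.5)],
    )
    return config, simulate(config)
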