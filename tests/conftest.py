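import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from nrgfusion.junction_scan import build_anchor_index  # noqa: E402
from nrgfusion.synthetic_data import SimulationConfig, make_toy_genome  # noqa: E402


@pytest.fixture(scope="session")
def config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def toy(config, tmp_path_factory):
    """Session-wide toy genome + gene models (seeded, deterministic)."""
    return make_toy_genome(config, outdir=tmp_path_factory.mktemp("toy"))


@pytest.fixture(scope="session")
def anchor_index(toy):
    return build_anchor_index(list(toy.genes.values()), toy.genome, k=20)


@pytest.fixture()
def nrg1(toy):
    return toy.genes["NRG1"]
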