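import pytest
from hypothesis import settings

from swrseq.pipeline import run_chip_pipeline, run_invitro_pipeline
from swrseq.simulate import WorldParams, make_world

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def world():
    """Default synthetic world: 1,000 nucleosomes over 2 x 200 kb, 18% true
    SWR-dependent sites, 3% tract-planted preferred nucleosomes."""
    return make_world(WorldParams(), seed=11)


@pytest.fixture(scope="session")
def chip_result(world):
    return run_chip_pipeline(world, n_frags=100_000, seed=23)


@pytest.fixture(scope="session")
def invitro_result(world):
    return run_invitro_pipeline(world, n_frags=100_000, seed=23)
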