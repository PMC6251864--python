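import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from m5cpred.seqio import Transcript
from m5cpred.synthetic import SyntheticSpec, simulate

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_transcripts():
    return {
        "t1": Transcript(id="t1", sequence="AACGTACGTC", gene_id="g1"),
        "t2": Transcript(id="t2", sequence="CCCCGGGGTT", gene_id="g2"),
    }


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulation shared by unit tests: 15 transcripts, 3 tissues."""
    spec = SyntheticSpec(n_transcripts=15, length_range=(400, 600), seed=11)
    transcripts, tables = simulate(spec)
    return spec, transcripts, tables


@pytest.fixture(scope="session")
def small_sim_maps(small_sim):
    spec, transcripts, tables = small_sim
    return spec, {t.id: t for t in transcripts}, tables


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
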