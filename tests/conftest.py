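import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_peptide(rng):
    from idrscape.scales import AMINO_ACIDS

    def _make(length: int, generator=None) -> str:
        g = generator if generator is not None else rng
        return "".join(g.choice(list(AMINO_ACIDS), size=length))

    return _make
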