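import random

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from plantedmotif.seq_io import SequenceSet  # noqa: E402


@pytest.fixture
def rng():
    return random.Random(20150115)


@pytest.fixture
def make_seqs():
    """Factory for small random DNA sequence sets."""

    def _make(rng, n, m):
        return SequenceSet(
            [(f"s{i}", "".join(rng.choice("ACGT") for _ in range(m))) for i in range(n)]
        )

    return _make
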