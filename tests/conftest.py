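import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def with_substitutions(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    n_sub = int(round(rate * len(seq)))
    for p in rng.choice(len(seq), size=n_sub, replace=False):
        out[p] = "ACGT"[("ACGT".index(out[p]) + 1 + rng.integers(3)) % 4]
    return "".join(out)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_library(rng):
    from tepoly.library import TEConsensus

    return [
        TEConsensus("CR1-X", "CR1", random_seq(rng, 2000), is_autonomous=True),
        TEConsensus("L1-Y", "L1", random_seq(rng, 1500), is_autonomous=True),
        TEConsensus("SINE-Z", "SINE", random_seq(rng, 300)),
    ]
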