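import numpy as np
import pytest

import glacialis as gl


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic genome shared by read-only tests."""
    cfg = gl.SynthConfig(seed=11)
    return cfg, gl.simulate_genome(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
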