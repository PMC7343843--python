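import numpy as np
import pytest

from asmqc import synthetic


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def standard_mosaic():
    """The standard ancestry-mosaic scenario: 2e4 AIMs, switch 1e-3,
    stationary C fraction 0.78, source divergence 0.5, depth 50."""
    aims, truth = synthetic.gen_ancestry_mosaic(
        n_aims=20_000,
        switch_prob=1e-3,
        alpha_target=0.78,
        freq_divergence=0.5,
        depth=50.0,
        seed=11,
    )
    return aims, truth


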