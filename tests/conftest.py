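import numpy as np
import pytest


def random_spectrum_corpus(rng, n_spectra, min_len=2, max_len=500):
    """Random nonnegative spectra; half continuous, half quantized (ties)."""
    corpus = []
    for trial in range(n_spectra):
        q = int(rng.integers(min_len, max_len + 1))
        if trial % 2:
            vals = rng.integers(0, 8, q).astype(float)
        else:
            vals = rng.random(q)
        corpus.append(vals)
    return corpus


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_corpus(rng):
    """200 short random spectra for per-module property checks."""
    return random_spectrum_corpus(rng, 200, min_len=2, max_len=80)
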