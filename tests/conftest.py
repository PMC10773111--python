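import numpy as np
import pytest

from modmotif.motifs import Background, SYMBOL_INDEX, mouse_like_background


@pytest.fixture
def uniform_bg() -> Background:
    return Background.uniform()


@pytest.fixture
def realistic_bg() -> Background:
    """GC ~0.42 background with rare modified symbols, as in a mammalian
    modified genome."""
    return mouse_like_background()


@pytest.fixture
def acgt_bg() -> Background:
    """All mass on the four unmodified bases, 0.25 each."""
    f = np.zeros(len(SYMBOL_INDEX))
    for s in "ACGT":
        f[SYMBOL_INDEX[s]] = 0.25
    return Background(f)
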