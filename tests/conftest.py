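import numpy as np
import pytest

from kglupred.data_io import PeptideWindow
from kglupred.residues import ALPHABET22, STANDARD20


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_window(rng, length=33, alphabet=STANDARD20, center="K"):
    chars = [alphabet[i] for i in rng.integers(0, len(alphabet), size=length)]
    chars[length // 2] = center
    return "".join(chars)


@pytest.fixture
def windows33(rng):
    """A batch of random valid 33-mers over the full 22-letter alphabet."""
    return [random_window(rng, alphabet=ALPHABET22) for _ in range(25)]


def make_labeled_windows(n_pos, n_neg, seed=0):
    """Featureless windows (all-X flanks) carrying only labels, for split tests."""
    out = []
    for i in range(n_pos):
        out.append(PeptideWindow(f"pp{i}", 17, "X" * 16 + "K" + "X" * 16, 1))
    for i in range(n_neg):
        out.append(PeptideWindow(f"pn{i}", 17, "X" * 16 + "K" + "X" * 16, 0))
    return out
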