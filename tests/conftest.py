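import io
import random

import pytest

from fcodekit import Fcode, Layer, UNKNOWN, read_fdata
from fcodekit.core import CATEGORY

SIMPSON_FDATA = (
    "# Parents\n"
    "*\tHomer Simpson\n"
    "*C\tMarge Simpson\n"
    "# Offspring\n"
    "*o1\tBart Simpson\n"
    "*a2\tLisa Simpson\n"
    "*a3\tMaggie Simpson\n"
    "# Grandpas\n"
    "*P\tAbe Simpson\n"
    "*M\tMona Simpson\n"
)


@pytest.fixture
def simpson_text():
    return SIMPSON_FDATA


@pytest.fixture
def simpsons():
    fam, diags = read_fdata(io.StringIO(SIMPSON_FDATA))
    assert diags == []
    return fam


def random_raw_fcode(rng: random.Random, max_depth: int = 6) -> Fcode:
    """A grammatically valid code with arbitrary (possibly wrong-pattern)
    adjacencies — the input space the normalizer must handle."""
    layers = [Layer("*")]
    for _ in range(rng.randint(0, max_depth)):
        symbol = rng.choice("PMXCOAHoah")
        if CATEGORY[symbol] in ("brotherhood", "sonship"):
            order = rng.choice([UNKNOWN, rng.randint(1, 5)])
        else:
            order = rng.choice([None, None, UNKNOWN, rng.randint(1, 5)])
        layers.append(Layer(symbol, order))
    return Fcode(tuple(layers))
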