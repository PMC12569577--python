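"""Grammar and structural operations for kinship path codes.

A code is a left-to-right sequence of *layers* rooted at the origin of
coordinates (OC), written ``*``. Each layer is one relationship step —
a letter plus an optional birth-order number — read relative to the
position to its left:

==========  ===========  ====================================
category    symbols      meaning (relative to previous layer)
==========  ===========  ====================================
origin      ``*``        the reference person (layer 0)
parenthood  P, M, X      father, mother, parent of unknown sex
spousehood  C            spouse / partner
brotherhood O, A, H      brother, sister, sibling of unknown sex
sonship     o, a, h      son, daughter, child of unknown sex
==========  ===========  ====================================

Sibling and offspring layers always carry a birth-order number (``?``
when the order is not recorded). Parent and spouse layers carry one
only on the final layer; *strict* parsing enforces this, *lenient*
parsing (the default for files) tolerates deviations.

The number of non-origin layers is the code's **depth**; the prefix up
to layer *k* is **position** *k*; stripping numbers and sexes yields
the **lineage**, whose last symbol is the code's **type**.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Union

from .errors import (
    BadOrder,
    FcodeSyntaxError,
    IllegalSymbol,
    MissingOrder,
    MissingOrigin,
    PositionOutOfRange,
    StrictNumberViolation,
)

__all__ = [
    "UNKNOWN",
    "Layer",
    "Fcode",
    "parse_fcode",
    "render",
    "depth",
    "position",
    "to_lineage",
    "fcode_type",
    "CATEGORY",
    "SEX",
    "DESEXED",
    "ORIGIN",
    "PARENTHOOD",
    "SPOUSEHOOD",
    "BROTHERHOOD",
    "SONSHIP",
]

ORIGIN = "origin"
PARENTHOOD = "parenthood"
SPOUSEHOOD = "spousehood"
BROTHERHOOD = "brotherhood"
SONSHIP = "sonship"

#: symbol -> relationship category
CATEGORY: dict[str, str] = {
    "*": ORIGIN,
    "P": PARENTHOOD, "M": PARENTHOOD, "X": PARENTHOOD,
    "C": SPOUSEHOOD,
    "O": BROTHERHOOD, "A": BROTHERHOOD, "H": BROTHERHOOD,
    "o": SONSHIP, "a": SONSHIP, "h": SONSHIP,
}

#: symbol -> sex ("male", "female", "unknown", or None where the notion
#: does not apply: the origin marker and the spouse link carry no sex).
SEX: dict[str, str | None] = {
    "P": "male", "O": "male", "o": "male",
    "M": "female", "A": "female", "a": "female",
    "X": "unknown", "H": "unknown", "h": "unknown",
    "*": None, "C": None,
}

#: symbol -> its sex-free counterpart used in lineages
DESEXED: dict[str, str] = {
    "P": "X", "M": "X", "X": "X",
    "O": "H", "A": "H", "H": "H",
    "o": "h", "a": "h", "h": "h",
    "C": "C", "*": "*",
}

#: categories whose layers must always be numbered
_NUMBERED_CATEGORIES = frozenset({BROTHERHOOD, SONSHIP})
#: categories numbered only on the final layer (strict mode)
_TERMINAL_NUMBER_CATEGORIES = frozenset({PARENTHOOD, SPOUSEHOOD})


class _Unknown:
    """Singleton marker for a birth order that exists but is unrecorded."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "UNKNOWN"


UNKNOWN = _Unknown()

#: A birth order: a positive int, UNKNOWN (rendered "?"), or None (absent).
Order = Union[int, _Unknown, None]


@dataclass(frozen=True)
class Layer:
    """One relationship step: a legend symbol plus an optional birth order."""

    symbol: str
    order: Order = None

    def __post_init__(self) -> None:
        if self.symbol not in CATEGORY:
            raise IllegalSymbol(f"unknown relationship symbol {self.symbol!r}")
        if isinstance(self.order, int) and self.order < 1:
            raise BadOrder(f"birth order must be positive, got {self.order}")
        if self.symbol == "*" and self.order is not None:
            raise BadOrder("the origin layer never carries a birth order")
        if self.order is None and CATEGORY[self.symbol] in _NUMBERED_CATEGORIES:
            raise MissingOrder(
                f"sibling/offspring layer {self.symbol!r} must carry a birth "
                "order (use UNKNOWN when unrecorded)"
            )

    @property
    def category(self) -> str:
        return CATEGORY[self.symbol]

    @property
    def sex(self) -> str | None:
        return SEX[self.symbol]

    @property
    def desexed(self) -> str:
        return DESEXED[self.symbol]

    def with_order(self, order: Order) -> "Layer":
        return Layer(self.symbol, order)

    def render(self) -> str:
        if self.order is None:
            return self.symbol
        if self.order is UNKNOWN:
            return self.symbol + "?"
        return f"{self.symbol}{self.order}"

    def __str__(self) -> str:
        return self.render()


@dataclass(frozen=True)
class Fcode:
    """An ordered layer sequence; layer 0 is always the origin ``*``."""

    layers: tuple[Layer, ...]

    def __post_init__(self) -> None:
        if not self.layers or self.layers[0].symbol != "*":
            raise MissingOrigin("an Fcode must start with the origin layer '*'")
        if any(l.symbol == "*" for l in self.layers[1:]):
            raise IllegalSymbol("the origin marker may only appear at layer 0")

    # -- structure ---------------------------------------------------------

    @property
    def depth(self) -> int:
        """Number of non-origin layers: the kinship distance from the OC."""
        return len(self.layers) - 1

    def position(self, k: int) -> "Fcode":
        """The prefix of this code with ``k`` non-origin layers."""
        if not 0 <= k <= self.depth:
            raise PositionOutOfRange(
                f"position {k} outside 0..{self.depth} for {self}"
            )
        return Fcode(self.layers[: k + 1])

    def lineage(self) -> str:
        """The code with numbers removed and symbols desexed."""
        return "".join(l.desexed for l in self.layers)

    @property
    def type(self) -> str:
        """Last symbol of the lineage: the category of the encoded person."""
        return self.layers[-1].desexed

    # -- rendering ---------------------------------------------------------

    def render(self) -> str:
        return "".join(l.render() for l in self.layers)

    def canonical(self) -> "Fcode":
        """Drop birth orders from non-final parent/spouse layers.

        Interior parent/spouse numbers are informationally redundant (the
        path fixes the person); the canonical writer therefore omits them.
        Orders on the final layer, and on all sibling/offspring layers,
        are preserved — including unrecorded ones (``?``).
        """
        out = []
        last = len(self.layers) - 1
        for i, layer in enumerate(self.layers):
            if (
                i != last
                and layer.category in _TERMINAL_NUMBER_CATEGORIES
                and layer.order is not None
            ):
                layer = layer.with_order(None)
            out.append(layer)
        return Fcode(tuple(out))

    def __str__(self) -> str:
        return self.render()

    def __iter__(self):
        return iter(self.layers)

    def __len__(self) -> int:
        return len(self.layers)


def _make_fcode(layers: Iterable[Layer]) -> Fcode:
    return Fcode(tuple(layers))


Mode = Literal["strict", "lenient"]


def parse_fcode(text: str, mode: Mode = "lenient") -> Fcode:
    """Parse a code string into an :class:`Fcode`.

    In ``strict`` mode the terminal-only numbering rule for parent and
    spouse layers is enforced both ways: an interior number or a missing
    terminal number raises :class:`StrictNumberViolation`. In ``lenient``
    mode (default, used when reading files) interior numbers are accepted
    and preserved, and bare terminal parent/spouse layers are fine.
    Sibling and offspring layers must be numbered in both modes.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"mode must be 'strict' or 'lenient', got {mode!r}")
    if not text:
        raise MissingOrigin("empty string is not an Fcode")
    if text[0] != "*":
        raise MissingOrigin("an Fcode must start with '*'", text, 0)

    layers: list[Layer] = [Layer("*")]
    i = 1
    n = len(text)
    while i < n:
        ch = text[i]
        if ch == "*":
            raise IllegalSymbol("'*' may only appear at the start", text, i)
        if ch not in CATEGORY:
            if ch in "+-" or ch.isdigit():
                raise BadOrder(
                    f"unexpected {ch!r}: numbers must follow a relationship letter",
                    text, i,
                )
            raise IllegalSymbol(f"unknown relationship symbol {ch!r}", text, i)
        symbol = ch
        i += 1
        order: Order = None
        if i < n and text[i] == "?":
            order = UNKNOWN
            i += 1
        elif i < n and text[i] in "+-":
            raise BadOrder("signed birth orders are not allowed", text, i)
        elif i < n and text[i].isdigit():
            j = i
            while j < n and text[j].isdigit():
                j += 1
            value = int(text[i:j])
            if value == 0:
                raise BadOrder("birth order 0 is not allowed", text, i)
            order = value
            i = j
        if order is None and CATEGORY[symbol] in _NUMBERED_CATEGORIES:
            raise MissingOrder(
                f"sibling/offspring layer {symbol!r} must carry a birth "
                "order (use '?' when unrecorded)",
                text, i - 1,
            )
        layers.append(Layer(symbol, order))

    code = _make_fcode(layers)
    if mode == "strict":
        _check_strict(code, text)
    return code


def _check_strict(code: Fcode, text: str) -> None:
    last = len(code.layers) - 1
    for i, layer in enumerate(code.layers):
        if layer.category not in _TERMINAL_NUMBER_CATEGORIES:
            continue
        if i != last and layer.order is not None:
            raise StrictNumberViolation(
                f"layer {i} ({layer}) is not final and may not carry a "
                "birth order in strict mode",
                text,
            )
        if i == last and layer.order is None:
            raise StrictNumberViolation(
                f"final layer {layer.symbol!r} must carry a birth order "
                "or '?' in strict mode",
                text,
            )


# -- thin functional aliases (mirror the method surface) -------------------

def render(f: Fcode) -> str:
    """Render a code back to its string form (inverse of parsing)."""
    return f.render()


def depth(f: Fcode) -> int:
    return f.depth


def position(f: Fcode, k: int) -> Fcode:
    return f.position(k)


def to_lineage(f: Fcode) -> str:
    return f.lineage()


def fcode_type(f: Fcode) -> str:
    return f.type


def fcode(text: str, mode: Mode = "lenient") -> Fcode:
    """Convenience constructor accepting a string or an Fcode."""
    if isinstance(text, Fcode):
        return text
    return parse_fcode(text, mode)


# re-exported for callers that want to catch any parse failure
ParseError = FcodeSyntaxError
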