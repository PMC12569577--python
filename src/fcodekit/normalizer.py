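"""Shortest-path canonicalization of kinship codes.

A code must connect the origin to the encoded person by the most direct
route. Working on the lineage (sex- and number-free form), exactly eight
adjacent two-symbol patterns admit a shorter equivalent encoding; each
has a prescribed rewrite:

=========  =======  ==============================================
pattern    becomes  rewrite
=========  =======  ==============================================
``CC``     (loop)   spouse's spouse is the person itself: drop both
``hX``     ``C``    child's parent is one's partner
``HX``     ``X``    sibling's parent is one's own parent
``XC``     ``X``    parent's partner is the other parent (sex
                    switched; that parent's birth order is unknown)
``Ch``     ``h``    partner's child is one's own child
``hH``     ``h``    child's sibling is another child
``HH``     ``H``    sibling's sibling is a sibling
``Xh``     ``H``    parent's child is a sibling — *or the person
                    itself*, which the code alone cannot decide
=========  =======  ==============================================

The remaining eight adjacencies (grandparent ``XX``, aunt/uncle ``XH``,
in-laws ``CX``/``CH``/``HC``/``hC``, nephew ``Hh``, grandchild ``hh``)
are irreducible. :func:`normalize` applies rewrites to a fixpoint,
deletions before substitutions so that no unknown orders are introduced
when a pure deletion suffices; the ambiguous ``Xh`` rewrite is applied
only on request (``xh_mode="rewrite"``) and otherwise reported as a
warning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .core import UNKNOWN, Fcode, Layer, fcode
from .errors import StaleMatch

__all__ = [
    "PatternMatch",
    "find_wrong_patterns",
    "apply_fix",
    "normalize",
    "enumerate_wrong_pairs",
    "WRONG_PATTERNS",
    "ALLOWED_PAIRS",
]

#: pattern id -> shortest equivalent lineage fragment ("" = pure loop).
#: This is the relationship algebra of a monogamous nuclear family: the
#: composition of the two steps, re-expressed in at most one step.
_REDUCTION: dict[str, str] = {
    "CC": "",    # spouse of spouse = self
    "hX": "C",   # parent of child = partner
    "HX": "X",   # parent of sibling = parent
    "XC": "X",   # partner of parent = other parent
    "Ch": "h",   # child of partner = child
    "hH": "h",   # sibling of child = child
    "HH": "H",   # sibling of sibling = sibling
    "Xh": "H",   # child of parent = sibling (or self)
}

WRONG_PATTERNS = frozenset(_REDUCTION)

#: fixes that only delete layers, applied before substitutions
_DELETIONS = frozenset({"CC", "HX", "Ch", "HH"})

#: rewrites that neither create nor destroy a spousehood (C) layer; the
#: ancestor analysis restricts itself to these so that the
#: no-ancestor-through-marriage rule still sees every C layer
SPOUSE_PRESERVING = frozenset({"HX", "HH", "hH"})

_FIX_KIND = {
    "CC": "delete_pair",
    "HX": "delete_first",
    "Ch": "delete_first",
    "HH": "delete_first",
    "hX": "substitute",
    "XC": "substitute",
    "hH": "substitute",
    "Xh": "substitute",
}

_SEX_SWITCH = {"P": "M", "M": "P", "X": "X"}
_TO_SONSHIP = {"O": "o", "A": "a", "H": "h", "o": "o", "a": "a", "h": "h"}
_TO_BROTHERHOOD = {"o": "O", "a": "A", "h": "H", "O": "O", "A": "A", "H": "H"}

XH_NOTE = (
    "kept 'parent then child' step: rewriting it to a sibling is only valid "
    "if the encoded person is not the origin themselves — check whether the "
    "shortened code would denote the OC"
)
CH_NOTE = (
    "removed a spouse layer before a child: the partner's child is taken to "
    "be the person's own child (step-children are not distinguished)"
)


@dataclass(frozen=True)
class PatternMatch:
    """A wrong two-layer adjacency found in a code's lineage.

    ``start_layer`` indexes the first layer of the pair (>= 1; the origin
    layer never participates in a pattern).
    """

    pattern_id: str
    start_layer: int

    @property
    def fix_kind(self) -> str:
        return _FIX_KIND[self.pattern_id]


def find_wrong_patterns(f: Fcode | str) -> list[PatternMatch]:
    """All adjacent lineage pairs matching a wrong pattern, left to right."""
    f = fcode(f)
    lin = f.lineage()
    out = []
    for i in range(1, len(lin) - 1):
        pair = lin[i] + lin[i + 1]
        if pair in WRONG_PATTERNS:
            out.append(PatternMatch(pair, i))
    return out


def apply_fix(f: Fcode | str, m: PatternMatch) -> Fcode:
    """Rewrite one matched pattern; the result is strictly shorter.

    Raises :class:`StaleMatch` if ``m`` does not match ``f`` at its
    recorded position (e.g. after another fix shifted the layers).
    """
    f = fcode(f)
    layers = list(f.layers)
    i = m.start_layer
    if i < 1 or i + 1 >= len(layers):
        raise StaleMatch(f"{m.pattern_id} at layer {i} out of range for {f}")
    first, second = layers[i], layers[i + 1]
    if first.desexed + second.desexed != m.pattern_id:
        raise StaleMatch(
            f"{m.pattern_id} does not match {first}{second} at layer {i} of {f}"
        )

    pid = m.pattern_id
    if pid == "CC":
        repl: list[Layer] = []
    elif pid in ("HX", "Ch", "HH"):
        repl = [second]
    elif pid == "hX":
        # child's parent: one's partner, inheriting the parent's order
        repl = [Layer("C", second.order)]
    elif pid == "XC":
        # parent's partner: the other parent; its birth order is lost.
        sym = _SEX_SWITCH[first.symbol]
        terminal = i + 1 == len(layers) - 1
        repl = [Layer(sym, UNKNOWN if terminal else None)]
    elif pid == "hH":
        # child's sibling: another child, keeping that sibling's identity
        repl = [Layer(_TO_SONSHIP[second.symbol], second.order)]
    elif pid == "Xh":
        # parent's child: a sibling, keeping that child's identity
        repl = [Layer(_TO_BROTHERHOOD[second.symbol], second.order)]
    else:  # pragma: no cover - _FIX_KIND covers all ids
        raise StaleMatch(f"unknown pattern {pid}")

    return Fcode(tuple(layers[:i] + repl + layers[i + 2 :]))


XhMode = Literal["keep", "rewrite"]


def normalize(
    f: Fcode | str,
    xh_mode: XhMode = "keep",
    *,
    patterns: frozenset[str] | None = None,
) -> tuple[Fcode, list[str]]:
    """Rewrite ``f`` to a fixpoint of the pattern fixes.

    Fix selection: deletion fixes before substitution fixes, leftmost
    first within each class. Each applied fix removes at least one
    layer, so at most ``depth(f)`` fixes are ever applied. Returns the
    rewritten code and a list of human-readable warnings (kept ``Xh``
    occurrences, spouse-child merges).

    ``patterns`` restricts which pattern ids may be acted on (e.g.
    :data:`SPOUSE_PRESERVING` for comparisons that must keep every C
    layer visible); by default all eight are actionable.
    """
    if xh_mode not in ("keep", "rewrite"):
        raise ValueError(f"xh_mode must be 'keep' or 'rewrite', got {xh_mode!r}")
    cur = fcode(f)
    warnings: list[str] = []
    while True:
        matches = find_wrong_patterns(cur)
        actionable = [
            m for m in matches
            if (m.pattern_id != "Xh" or xh_mode == "rewrite")
            and (patterns is None or m.pattern_id in patterns)
        ]
        if not actionable:
            for m in matches:
                if m.pattern_id == "Xh" and (
                    patterns is None or "Xh" in patterns
                ):
                    warnings.append(f"layer {m.start_layer} of {cur}: {XH_NOTE}")
            return cur, warnings
        deletions = [m for m in actionable if m.pattern_id in _DELETIONS]
        chosen = deletions[0] if deletions else actionable[0]
        if chosen.pattern_id == "Ch":
            warnings.append(f"layer {chosen.start_layer} of {cur}: {CH_NOTE}")
        if chosen.pattern_id == "Xh" and chosen.start_layer == 1:
            warnings.append(
                f"layer 1 of {cur}: rewrote 'parent then child' to a sibling; "
                "verify the person is not the OC"
            )
        cur = apply_fix(cur, chosen)


def enumerate_wrong_pairs() -> set[str]:
    """Scan all 16 ordered lineage adjacencies for reducible ones.

    A pair is *wrong* when the relationship algebra re-expresses the two
    steps in fewer than two, i.e. the pair has an entry in the reduction
    table. Exactly eight of the sixteen qualify.
    """
    return {
        a + b
        for a in "XCHh"
        for b in "XCHh"
        if _REDUCTION.get(a + b) is not None
    }


#: the complement: adjacencies a valid code may contain
ALLOWED_PAIRS = frozenset(
    a + b for a in "XCHh" for b in "XCHh" if a + b not in WRONG_PATTERNS
)
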