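"""Common ancestors and the divergent-section inbreeding estimate.

Two codes sharing one origin trace two paths through the family. Their
*common ancestor* is the last position at which the layers still match;
the unmatched suffixes are the *divergent sections*. The construction
is only a genuine ancestor when neither divergent section contains a
spouse step (C) — a spouse step means the paths part through marriage,
not descent.

With DS1 and DS2 the depths (layer counts) of the two divergent
sections, the inbreeding coefficient of the pair is estimated as

    F = (1/2) ** (DS1 + DS2)

This is the single-path, single-common-ancestor form of Wright's path
coefficient: it does not add the classical ``+1`` exponent term, does
not weight by the ancestor's own inbreeding, and does not sum over
multiple common ancestors — the two codes alone expose exactly one
shared path. ``F`` is 1 for identical codes and halves with every extra
step of divergence; when no valid common ancestor exists the estimate
is reported as 0 with an explicit flag.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import UNKNOWN, Fcode, Layer, fcode
from .normalizer import SPOUSE_PRESERVING, normalize

__all__ = ["AncestorResult", "common_ancestor", "inbreeding_coefficient"]


@dataclass(frozen=True)
class AncestorResult:
    """Outcome of comparing two codes that share an origin."""

    has_common_ancestor: bool
    ancestor: Fcode | None
    divergent_a: tuple[Layer, ...]
    divergent_b: tuple[Layer, ...]

    @property
    def ds_a(self) -> int:
        return len(self.divergent_a)

    @property
    def ds_b(self) -> int:
        return len(self.divergent_b)

    @property
    def F(self) -> float | None:
        if not self.has_common_ancestor:
            return None
        return 0.5 ** (self.ds_a + self.ds_b)

    def divergent_strings(self) -> tuple[str, str]:
        return (
            "".join(l.render() for l in self.divergent_a),
            "".join(l.render() for l in self.divergent_b),
        )


def _layers_match(a: Layer, b: Layer) -> bool:
    """Layers match when symbols agree and orders agree or either order
    is absent/unrecorded (so ``*P`` matches ``*P3``)."""
    if a.symbol != b.symbol:
        return False
    if isinstance(a.order, int) and isinstance(b.order, int):
        return a.order == b.order
    return True


def _prefer_concrete(a: Layer, b: Layer) -> Layer:
    """For the ancestor spelling keep the more informative order."""
    if isinstance(a.order, int):
        return a
    if isinstance(b.order, int):
        return b
    if a.order is UNKNOWN:
        return a
    return b


def common_ancestor(a: Fcode | str, b: Fcode | str) -> AncestorResult:
    """Longest matching-layer prefix of two codes and their divergence.

    Spousehood-preserving rewrites (sibling's parent, sibling's
    sibling, child's sibling) are applied first so equivalent spellings
    of the same descent path agree; rewrites that would add or remove a
    C layer are deliberately *not* applied, because the marriage rule
    must see every spouse step as written. Birth orders are compared
    only when both sides record one, which makes the result invariant
    to the terminal-only numbering convention for parent/spouse layers.
    """
    fa, _ = normalize(fcode(a), "keep", patterns=SPOUSE_PRESERVING)
    fb, _ = normalize(fcode(b), "keep", patterns=SPOUSE_PRESERVING)
    la, lb = fa.layers, fb.layers
    prefix: list[Layer] = []
    i = 0
    while i < len(la) and i < len(lb) and _layers_match(la[i], lb[i]):
        prefix.append(_prefer_concrete(la[i], lb[i]))
        i += 1
    divergent_a = la[i:]
    divergent_b = lb[i:]
    valid = not any(
        layer.category == "spousehood" for layer in divergent_a + divergent_b
    )
    return AncestorResult(
        has_common_ancestor=valid,
        ancestor=Fcode(tuple(prefix)) if valid else None,
        divergent_a=tuple(divergent_a),
        divergent_b=tuple(divergent_b),
    )


def inbreeding_coefficient(a: Fcode | str, b: Fcode | str) -> float:
    """``0.5 ** (DS1 + DS2)`` when a common ancestor exists, else 0.0.

    Total on all valid code pairs, so pairwise matrices never raise;
    use :func:`common_ancestor` when the no-ancestor case must be
    distinguished from genuinely unrelated-but-linked persons.
    """
    result = common_ancestor(a, b)
    if not result.has_common_ancestor:
        return 0.0
    return result.F
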