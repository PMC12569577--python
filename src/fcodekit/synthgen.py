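"""Seeded random generation of valid codes and consistent families.

Generation walks the *allowed-pair automaton*: the complement of the
eight wrong lineage adjacencies. A new layer is only ever appended when
the resulting adjacency is irreducible, so every generated code is
shortest-path by construction — no rejection sampling and no post-hoc
normalization. Layers are then sexed and numbered: sibling/offspring
layers always get a birth order, and parent/spouse layers get one on
the final layer (the strict numbering convention), so all output parses
in strict mode.

All randomness flows from the single integer seed in
:class:`GenConfig`; the same config yields byte-identical output and no
global random state is touched. Names come from a small bundled list;
no real-person data is used.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .core import Fcode, Layer, parse_fcode
from .family import Family, PersonRecord
from .normalizer import ALLOWED_PAIRS

__all__ = ["GenConfig", "random_fcode", "random_family", "allowed_successors"]

#: lineage symbol -> lineage symbols that may follow it
_SUCCESSORS: dict[str, str] = {
    prev: "".join(s for s in "XCHh" if prev + s in ALLOWED_PAIRS)
    for prev in "XCHh"
}
_SUCCESSORS["*"] = "XCHh"  # patterns never involve the origin layer

_SEXED = {"X": "PM", "H": "OA", "h": "oa", "C": "C"}

_FIRST_NAMES = (
    "Ada", "Alan", "Alma", "Bruno", "Carla", "Dario", "Edith", "Felix",
    "Greta", "Hugo", "Ines", "Jonas", "Klara", "Leo", "Mara", "Nils",
    "Olga", "Pablo", "Quinn", "Rosa", "Sven", "Tessa", "Ulf", "Vera",
    "Wanda", "Xenia", "Yuri", "Zoe", "Iris", "Omar", "Lena", "Marc",
)
_SURNAMES = (
    "Almeida", "Baker", "Castro", "Dufour", "Eriksen", "Fischer",
    "Garcia", "Hansen", "Ivanov", "Jansen", "Keller", "Lindgren",
    "Moreau", "Novak", "Okafor", "Petrov", "Quintana", "Rossi",
    "Silva", "Tanaka",
)


@dataclass(frozen=True)
class GenConfig:
    """Knobs of the generator.

    ``max_depth`` bounds the kinship distance from the OC;
    ``max_children`` bounds birth orders (and hence sibship sizes);
    the two probabilities weight how often a spouse or a sibling is
    attached relative to parents and children.
    """

    seed: int
    max_depth: int = 4
    n_people: int = 10
    max_children: int = 4
    spouse_probability: float = 0.4
    sibling_probability: float = 0.4

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.n_people < 1:
            raise ValueError("n_people must be >= 1")
        if self.max_children < 1:
            raise ValueError("max_children must be >= 1")
        for p in (self.spouse_probability, self.sibling_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def allowed_successors(lineage_symbol: str) -> str:
    """Lineage symbols that may follow ``lineage_symbol`` in a valid code."""
    return _SUCCESSORS[lineage_symbol]


def _finish_layer(
    rng: random.Random, lin: str, terminal: bool, max_children: int
) -> Layer:
    symbol = rng.choice(_SEXED[lin])
    if lin in ("H", "h"):
        return Layer(symbol, rng.randint(1, max_children))
    if terminal:  # strict mode numbers the final parent/spouse layer
        return Layer(symbol, rng.randint(1, max_children))
    return Layer(symbol, None)


def random_fcode(cfg: GenConfig, rng: random.Random | None = None) -> Fcode:
    """A pattern-free strict-mode code of depth <= ``max_depth``."""
    rng = rng if rng is not None else random.Random(cfg.seed)
    target = rng.randint(0, cfg.max_depth)
    lineage = "*"
    layers = [Layer("*")]
    for step in range(target):
        lin = rng.choice(_SUCCESSORS[lineage[-1]])
        lineage += lin
        layers.append(
            _finish_layer(rng, lin, step == target - 1, cfg.max_children)
        )
    return Fcode(tuple(layers))


# ---------------------------------------------------------------------------
# Families
# ---------------------------------------------------------------------------

def _identity_key(code: Fcode) -> tuple:
    """Person identity: parent/spouse orders do not distinguish persons."""
    out = []
    for layer in code.layers[1:]:
        if layer.category in ("parenthood", "spousehood"):
            out.append((layer.symbol, None))
        else:
            out.append((layer.symbol, layer.order))
    return tuple(out)


def random_family(cfg: GenConfig, rng: random.Random | None = None) -> Family:
    """Grow a consistent family of ``n_people`` distinct codes.

    Persons are attached one at a time to a random existing person,
    through a step the automaton allows at that position: a parent not
    yet present, a spouse (at most one per person), a sibling or a child
    with a birth order unused in that sibship. If the constraints leave
    no room (e.g. a tiny ``max_depth`` with a large ``n_people``), the
    best-effort family is returned with a diagnostic rather than an
    error.
    """
    rng = rng if rng is not None else random.Random(cfg.seed)
    surname = rng.choice(_SURNAMES)

    oc = parse_fcode("*")
    codes: list[Fcode] = [oc]
    keys = {_identity_key(oc)}
    parents_used: dict[tuple, set[str]] = {}
    spouse_taken: set[tuple] = set()
    sibling_orders: dict[tuple, set[int]] = {}
    child_orders: dict[tuple, set[int]] = {}

    def own_order(code: Fcode) -> int | None:
        order = code.layers[-1].order
        return order if isinstance(order, int) else None

    attempts = 0
    budget = cfg.n_people * 60
    while len(codes) < cfg.n_people and attempts < budget:
        attempts += 1
        base = rng.choice(codes)
        if base.depth >= cfg.max_depth:
            continue
        key = _identity_key(base)
        last = base.layers[-1].desexed

        options: list[tuple[str, float]] = []
        if "X" in _SUCCESSORS[last] and len(parents_used.get(key, set())) < 2:
            options.append(("X", 1.0))
        if "C" in _SUCCESSORS[last] and key not in spouse_taken:
            options.append(("C", cfg.spouse_probability))
        if "H" in _SUCCESSORS[last]:
            used = sibling_orders.setdefault(key, set())
            if own_order(base) is not None:
                used = used | {own_order(base)}
            if len(used) < cfg.max_children:
                options.append(("H", cfg.sibling_probability))
        if "h" in _SUCCESSORS[last]:
            if len(child_orders.get(key, set())) < cfg.max_children:
                options.append(("h", 1.0))
        total = sum(w for _, w in options)
        if not options or total <= 0:
            continue
        pick = rng.random() * total
        acc = 0.0
        lin = options[-1][0]
        for sym, w in options:
            acc += w
            if pick <= acc:
                lin = sym
                break

        if lin == "X":
            used = parents_used.setdefault(key, set())
            sexes = [s for s in "PM" if s not in used]
            symbol = rng.choice(sexes)
            layer = Layer(symbol, rng.randint(1, cfg.max_children))
            used.add(symbol)
        elif lin == "C":
            layer = Layer("C", rng.randint(1, cfg.max_children))
            spouse_taken.add(key)
        elif lin == "H":
            used = sibling_orders.setdefault(key, set())
            taken = set(used)
            if own_order(base) is not None:
                taken.add(own_order(base))
            free = [k for k in range(1, cfg.max_children + 1) if k not in taken]
            order = rng.choice(free)
            layer = Layer(rng.choice("OA"), order)
            used.add(order)
        else:  # child
            used = child_orders.setdefault(key, set())
            free = [k for k in range(1, cfg.max_children + 1) if k not in used]
            order = rng.choice(free)
            layer = Layer(rng.choice("oa"), order)
            used.add(order)

        new_code = Fcode(base.layers + (layer,)).canonical()
        new_key = _identity_key(new_code)
        if new_key in keys:
            continue
        keys.add(new_key)
        codes.append(new_code)

    fam = Family()
    for code in codes:
        first = rng.choice(_FIRST_NAMES)
        fam.add(PersonRecord(code, f"{first} {surname}"))
    if len(codes) < cfg.n_people:
        fam.diagnostics.append(
            f"infeasible: only {len(codes)} of {cfg.n_people} requested "
            "persons fit under the depth/children constraints"
        )
    return fam
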