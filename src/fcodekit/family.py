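"""Families of kinship codes: file I/O, the person graph, queries, re-rooting.

A *family* is a set of named codes sharing one origin of coordinates
(OC). The on-disk form is the FDATA file: two tab-separated columns
(code, name), ``#`` comment lines and blank lines ignored. An extended
TSV adds optional ``nickname``, ``birthdate`` and ``biography`` columns.

Because every code is a path from the same OC, the records jointly
determine a person graph: one node per distinct position across all
records, with typed edges (parent/child, sibling, spouse). Node
identity follows the canonical code: parent and spouse steps are unique
per person regardless of birth order (``*P`` and ``*P3`` are the same
father), while sibling and offspring steps are distinguished by their
birth order, with ``?`` matching a concrete order only when exactly one
candidate exists.

Relationship closure assumes a monogamous nuclear-family model, the
same algebra that underlies the pattern rewrites: the two parents of a
person form a couple, full siblings share all known parents, children
of one person are children of that person's partner, and children of
the same parent are siblings of each other.
"""

from __future__ import annotations

import re
from collections import deque
from dataclasses import dataclass, field
from typing import IO, Iterable, Literal

import networkx as nx

from .core import UNKNOWN, Fcode, Layer, fcode, parse_fcode
from .errors import (
    BadRegex,
    DuplicateFcode,
    FcodeSyntaxError,
    ForeignOrigin,
    HeaderMismatch,
    InconsistentFamily,
    InvalidFcode,
    TabColumnError,
    UnknownPerson,
)
from .normalizer import normalize

__all__ = [
    "PersonRecord",
    "OCMeta",
    "Family",
    "KinshipGraph",
    "RelationshipSummary",
    "read_fdata",
    "write_fdata",
    "read_tsv",
    "write_tsv",
    "build_graph",
    "direct_relationships",
    "search",
    "rebase",
]

TSV_COLUMNS = ("fcode", "name", "nickname", "birthdate", "biography")


@dataclass
class PersonRecord:
    """One line of a family file: a code plus free-text person data."""

    fcode: Fcode
    name: str
    nickname: str = ""
    birthdate: str = ""
    biography: str = ""

    def normalized(self) -> str:
        """Canonical shortest-path spelling used for indexing/identity."""
        norm, _ = normalize(self.fcode, "keep")
        return norm.canonical().render()


@dataclass
class OCMeta:
    """Sex and birth order of the OC person — metadata the code itself
    cannot carry (the origin layer is just ``*``)."""

    sex: str | None = None        # "male" / "female" / None
    birth_order: int | None = None


class Family:
    """An ordered collection of records sharing one OC."""

    def __init__(
        self,
        records: Iterable[PersonRecord] = (),
        oc_meta: OCMeta | None = None,
    ):
        self.records: list[PersonRecord] = []
        self.index: dict[str, PersonRecord] = {}
        self.oc_meta = oc_meta
        self.diagnostics: list[str] = []
        self._graph: KinshipGraph | None = None
        for rec in records:
            self.add(rec)

    def add(self, rec: PersonRecord, *, line: int | None = None) -> None:
        key = rec.normalized()
        if key in self.index:
            raise DuplicateFcode(
                f"code {rec.fcode} duplicates {key!r} "
                f"({self.index[key].name!r})",
                line,
            )
        self.records.append(rec)
        self.index[key] = rec
        self._graph = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def graph(self) -> "KinshipGraph":
        """The person graph, built on first use and cached."""
        if self._graph is None:
            self._graph = build_graph(self)
        return self._graph


# ---------------------------------------------------------------------------
# FDATA / TSV input and output
# ---------------------------------------------------------------------------

_OC_DIRECTIVE = re.compile(
    r"^#!\s*oc\b[:\s]*(?P<body>.*)$", re.IGNORECASE
)
_SEXES = {"male", "female"}


def _parse_oc_directive(body: str, line_no: int, diags: list[str]) -> OCMeta:
    meta = OCMeta()
    for token in body.replace(",", " ").split():
        if "=" not in token:
            diags.append(f"line {line_no}: ignored OC metadata token {token!r}")
            continue
        key, _, value = token.partition("=")
        key = key.strip().lower()
        value = value.strip().lower()
        if key == "sex" and value in _SEXES:
            meta.sex = value
        elif key in ("order", "birth_order") and value.isdigit() and int(value) > 0:
            meta.birth_order = int(value)
        else:
            diags.append(f"line {line_no}: ignored OC metadata token {token!r}")
    return meta


def read_fdata(
    stream: IO[str] | Iterable[str],
    *,
    allow_duplicates: bool = False,
) -> tuple[Family, list[str]]:
    """Read an FDATA stream into a :class:`Family`.

    Blank lines and ``#`` comments are skipped; a ``#! oc sex=... order=...``
    comment, if present, supplies OC metadata (an optional extension —
    plain readers see it as a comment). Each data line must have exactly
    two tab-separated columns. Duplicate canonical codes raise
    :class:`DuplicateFcode` unless ``allow_duplicates`` downgrades them
    to a warning keeping the first occurrence.
    """
    fam = Family()
    diags: list[str] = []
    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            m = _OC_DIRECTIVE.match(line)
            if m:
                fam.oc_meta = _parse_oc_directive(m.group("body"), line_no, diags)
            continue
        cols = line.split("\t")
        if len(cols) != 2:
            raise TabColumnError(
                f"expected 2 tab-separated columns, found {len(cols)}", line_no
            )
        code_text, name = cols[0].strip(), cols[1].strip()
        if not code_text.startswith("*"):
            raise ForeignOrigin(
                f"code {code_text!r} does not start with the shared origin '*'",
                line_no,
            )
        try:
            code = parse_fcode(code_text, "lenient")
        except FcodeSyntaxError as exc:
            raise InvalidFcode(str(exc), line_no) from exc
        if not name:
            diags.append(f"line {line_no}: record {code_text!r} has an empty name")
        rec = PersonRecord(code, name)
        try:
            fam.add(rec, line=line_no)
        except DuplicateFcode as exc:
            if allow_duplicates:
                diags.append(f"{exc} — keeping first occurrence")
            else:
                raise
    fam.diagnostics = list(diags)
    return fam, diags


def write_fdata(fam: Family, stream: IO[str]) -> None:
    """Write a family as FDATA, codes in canonical spelling."""
    if fam.oc_meta and (fam.oc_meta.sex or fam.oc_meta.birth_order):
        parts = []
        if fam.oc_meta.sex:
            parts.append(f"sex={fam.oc_meta.sex}")
        if fam.oc_meta.birth_order:
            parts.append(f"order={fam.oc_meta.birth_order}")
        stream.write(f"#! oc {' '.join(parts)}\n")
    for rec in fam.records:
        stream.write(f"{rec.fcode.canonical().render()}\t{rec.name}\n")


def read_tsv(
    stream: IO[str] | Iterable[str],
    *,
    allow_duplicates: bool = False,
) -> tuple[Family, list[str]]:
    """Read the extended TSV form (header ``fcode name nickname birthdate
    biography``; trailing columns optional)."""
    fam = Family()
    diags: list[str] = []
    lines = iter(enumerate(stream, start=1))
    header: list[str] | None = None
    for line_no, raw in lines:
        line = raw.rstrip("\r\n")
        if not line.strip() or line.startswith("#"):
            continue
        header = [c.strip().lower() for c in line.split("\t")]
        break
    if header is None:
        fam.diagnostics = diags
        return fam, diags
    if len(header) < 2 or tuple(header) != TSV_COLUMNS[: len(header)]:
        raise HeaderMismatch(
            f"expected a prefix of {list(TSV_COLUMNS)}, found {header}"
        )
    width = len(header)
    for line_no, raw in lines:
        line = raw.rstrip("\r\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) > width:
            raise TabColumnError(
                f"expected at most {width} columns, found {len(cols)}", line_no
            )
        cols += [""] * (width - len(cols))
        values = dict(zip(header, (c.strip() for c in cols)))
        code_text = values["fcode"]
        if not code_text.startswith("*"):
            raise ForeignOrigin(
                f"code {code_text!r} does not start with the shared origin '*'",
                line_no,
            )
        try:
            code = parse_fcode(code_text, "lenient")
        except FcodeSyntaxError as exc:
            raise InvalidFcode(str(exc), line_no) from exc
        rec = PersonRecord(
            code,
            values.get("name", ""),
            values.get("nickname", ""),
            values.get("birthdate", ""),
            values.get("biography", ""),
        )
        try:
            fam.add(rec, line=line_no)
        except DuplicateFcode as exc:
            if allow_duplicates:
                diags.append(f"{exc} — keeping first occurrence")
            else:
                raise
    fam.diagnostics = list(diags)
    return fam, diags


def write_tsv(fam: Family, stream: IO[str]) -> None:
    stream.write("\t".join(TSV_COLUMNS) + "\n")
    for rec in fam.records:
        stream.write(
            "\t".join(
                (
                    rec.fcode.canonical().render(),
                    rec.name,
                    rec.nickname,
                    rec.birthdate,
                    rec.biography,
                )
            )
            + "\n"
        )


# ---------------------------------------------------------------------------
# Person graph
# ---------------------------------------------------------------------------

_PARENTHOOD_SYMBOLS = {"P": "male", "M": "female", "X": "unknown"}
_SIBLING_SYMBOL = {"male": "O", "female": "A", "unknown": "H"}
_CHILD_SYMBOL = {"male": "o", "female": "a", "unknown": "h"}
_PARENT_SYMBOL = {"male": "P", "female": "M", "unknown": "X"}


class KinshipGraph:
    """Person nodes unified across codes, with typed relationship edges.

    ``parents`` / ``children`` are mutual inverses; ``siblings`` and
    ``spouses`` are symmetric. Node attributes: ``code`` (canonical
    display code of the path that created the node), ``sex``,
    ``birth_order`` (order within the sibship, when recorded), and
    ``record_ids`` (indices into the source family's record list).
    """

    def __init__(self, oc_meta: OCMeta | None = None):
        self.code: dict[int, str] = {}
        self.sex: dict[int, str] = {}
        self.birth_order: dict[int, int | None] = {}
        self.record_ids: dict[int, list[int]] = {}
        self.parents: dict[int, set[int]] = {}
        self.children: dict[int, set[int]] = {}
        self.siblings: dict[int, set[int]] = {}
        self.spouses: dict[int, set[int]] = {}
        self.diagnostics: list[str] = []
        # walking slots used for node resolution along code paths
        self._parent_slot: dict[int, dict[str, int]] = {}
        self._spouse_slot: dict[int, int | None] = {}
        self._sib_slot: dict[int, dict[tuple, int]] = {}
        self._child_slot: dict[int, dict[tuple, int]] = {}
        self._next = 0
        meta = oc_meta or OCMeta()
        self.oc = self._new_node("*", meta.sex or "unknown", meta.birth_order)

    # -- construction ------------------------------------------------------

    def _new_node(self, code: str, sex: str, order: int | None) -> int:
        nid = self._next
        self._next += 1
        self.code[nid] = code
        self.sex[nid] = sex
        self.birth_order[nid] = order
        self.record_ids[nid] = []
        for d in (self.parents, self.children, self.siblings, self.spouses):
            d[nid] = set()
        self._parent_slot[nid] = {}
        self._spouse_slot[nid] = None
        self._sib_slot[nid] = {}
        self._child_slot[nid] = {}
        return nid

    def add_parent(self, child: int, parent: int) -> bool:
        if parent in self.parents[child]:
            return False
        self.parents[child].add(parent)
        self.children[parent].add(child)
        return True

    def add_sibling(self, a: int, b: int) -> bool:
        if a == b or b in self.siblings[a]:
            return False
        self.siblings[a].add(b)
        self.siblings[b].add(a)
        return True

    def add_spouse(self, a: int, b: int) -> bool:
        if a == b or b in self.spouses[a]:
            return False
        self.spouses[a].add(b)
        self.spouses[b].add(a)
        return True

    def _resolve_ordered_slot(
        self, slots: dict[tuple, int], layer: Layer
    ) -> int | None:
        """Find an existing sibling/child node for a layer, honouring the
        unknown-order wildcard (``?`` matches a concrete order only when
        exactly one concrete candidate with the same symbol exists)."""
        order = layer.order
        if isinstance(order, int):
            return slots.get((layer.symbol, order))
        # unknown order
        concrete = [
            nid for (sym, o), nid in slots.items()
            if sym == layer.symbol and isinstance(o, int)
        ]
        if len(concrete) == 1:
            return concrete[0]
        if len(concrete) > 1:
            self.diagnostics.append(
                f"ambiguous '?' order on {layer.symbol!r}: "
                f"{len(concrete)} concrete candidates — kept distinct"
            )
        return slots.get((layer.symbol, "?"))

    def step(self, cur: int, layer: Layer, *, create: bool) -> int | None:
        """Follow (or create) the node one layer above ``cur``."""
        cat = layer.category
        if cat == "parenthood":
            nid = self._parent_slot[cur].get(layer.symbol)
            if nid is None and create:
                nid = self._new_node(
                    self.code[cur] + layer.symbol,
                    _PARENTHOOD_SYMBOLS[layer.symbol],
                    layer.order if isinstance(layer.order, int) else None,
                )
                self._parent_slot[cur][layer.symbol] = nid
                self.add_parent(cur, nid)
            elif nid is not None and isinstance(layer.order, int):
                if self.birth_order[nid] is None:
                    self.birth_order[nid] = layer.order
            return nid
        if cat == "spousehood":
            nid = self._spouse_slot[cur]
            if nid is None and create:
                nid = self._new_node(
                    self.code[cur] + layer.symbol,
                    "unknown",
                    layer.order if isinstance(layer.order, int) else None,
                )
                self._spouse_slot[cur] = nid
                self._spouse_slot[nid] = cur
                self.add_spouse(cur, nid)
            elif nid is not None and isinstance(layer.order, int):
                if self.birth_order[nid] is None:
                    self.birth_order[nid] = layer.order
            return nid
        if cat == "brotherhood":
            slots = self._sib_slot[cur]
        elif cat == "sonship":
            slots = self._child_slot[cur]
        else:
            raise ValueError(f"cannot step through layer {layer!r}")
        nid = self._resolve_ordered_slot(slots, layer)
        if nid is None and create:
            order = layer.order if isinstance(layer.order, int) else None
            nid = self._new_node(
                self.code[cur] + layer.render(),
                {"male": "male", "female": "female"}.get(layer.sex, "unknown"),
                order,
            )
            slots[(layer.symbol, order if order is not None else "?")] = nid
            if cat == "brotherhood":
                self.add_sibling(cur, nid)
            else:
                self.add_parent(nid, cur)
        return nid

    def resolve(self, code: Fcode | str) -> int:
        """Node for a code, or raise :class:`UnknownPerson`."""
        norm, _ = normalize(fcode(code), "keep")
        cur = self.oc
        for layer in norm.canonical().layers[1:]:
            nxt = self.step(cur, layer, create=False)
            if nxt is None:
                raise UnknownPerson(f"{code} does not resolve to a person")
            cur = nxt
        return cur

    # -- closure and consistency -------------------------------------------

    def close(self) -> None:
        """Propagate the nuclear-family implications to a fixpoint."""
        changed = True
        while changed:
            changed = False
            nodes = list(self.code)
            for n in nodes:
                ps = sorted(self.parents[n])
                # the two parents of one person form a couple
                if len(ps) == 2 and self.add_spouse(ps[0], ps[1]):
                    changed = True
                # children of one parent are siblings of each other
                kids = sorted(self.children[n])
                for i, a in enumerate(kids):
                    for b in kids[i + 1 :]:
                        if self.add_sibling(a, b):
                            changed = True
            for n in nodes:
                # full siblings share all known parents
                for s in sorted(self.siblings[n]):
                    for p in sorted(self.parents[n]):
                        if self.add_parent(s, p):
                            changed = True
                # a partner's child is one's own child
                for sp in sorted(self.spouses[n]):
                    for c in sorted(self.children[n]):
                        if self.add_parent(c, sp):
                            changed = True

    def check_consistency(self) -> None:
        for n in self.code:
            males = [p for p in self.parents[n] if self.sex[p] == "male"]
            females = [p for p in self.parents[n] if self.sex[p] == "female"]
            if len(males) > 1:
                raise InconsistentFamily(
                    f"{self.code[n]} has {len(males)} distinct fathers: "
                    f"{sorted(self.code[p] for p in males)}"
                )
            if len(females) > 1:
                raise InconsistentFamily(
                    f"{self.code[n]} has {len(females)} distinct mothers: "
                    f"{sorted(self.code[p] for p in females)}"
                )
            if len(self.parents[n]) > 2:
                raise InconsistentFamily(
                    f"{self.code[n]} has more than two parents: "
                    f"{sorted(self.code[p] for p in self.parents[n])}"
                )

    # -- interop ------------------------------------------------------------

    def to_networkx(self) -> "nx.DiGraph":
        """Typed-edge view for downstream graph analysis."""
        g = nx.DiGraph()
        for n, code in self.code.items():
            g.add_node(
                n, code=code, sex=self.sex[n], birth_order=self.birth_order[n]
            )
        for n in self.code:
            for p in self.parents[n]:
                g.add_edge(p, n, kind="parent_of")
                g.add_edge(n, p, kind="child_of")
            for s in self.siblings[n]:
                g.add_edge(n, s, kind="sibling_of")
            for s in self.spouses[n]:
                g.add_edge(n, s, kind="spouse_of")
        return g


def build_graph(fam: Family) -> KinshipGraph:
    """Build and close the person graph of a family.

    Raises :class:`InconsistentFamily` when the records force two
    distinct fathers/mothers (or more than two parents) onto one person.
    """
    g = KinshipGraph(fam.oc_meta)
    for idx, rec in enumerate(fam.records):
        norm, _ = normalize(rec.fcode, "keep")
        cur = g.oc
        for layer in norm.canonical().layers[1:]:
            cur = g.step(cur, layer, create=True)
        if g.record_ids[cur]:
            g.diagnostics.append(
                f"records {g.record_ids[cur][0]} and {idx} denote the same "
                f"person {g.code[cur]}"
            )
        g.record_ids[cur].append(idx)
    g.close()
    g.check_consistency()
    return g


# ---------------------------------------------------------------------------
# Queries
# ---------------------------------------------------------------------------

@dataclass
class RelationshipSummary:
    """Direct relatives of one person, each as ``(code, name)``."""

    person: tuple[str, str]
    father: tuple[str, str] | None = None
    mother: tuple[str, str] | None = None
    parents_unsexed: list[tuple[str, str]] = field(default_factory=list)
    siblings: list[tuple[str, str]] = field(default_factory=list)
    spouses: list[tuple[str, str]] = field(default_factory=list)
    children: list[tuple[str, str]] = field(default_factory=list)


def _entry(fam: Family, g: KinshipGraph, nid: int) -> tuple[str, str]:
    name = ""
    if g.record_ids[nid]:
        name = fam.records[g.record_ids[nid][0]].name
    return (g.code[nid], name)


def _by_order(g: KinshipGraph):
    def key(nid: int):
        order = g.birth_order[nid]
        return (order is None, order if order is not None else 0, g.code[nid])
    return key


def direct_relationships(fam: Family, code: Fcode | str) -> RelationshipSummary:
    """Father, mother, siblings, spouses and children of one person."""
    g = fam.graph()
    nid = g.resolve(code)
    summary = RelationshipSummary(person=_entry(fam, g, nid))
    for p in sorted(g.parents[nid], key=_by_order(g)):
        if g.sex[p] == "male" and summary.father is None:
            summary.father = _entry(fam, g, p)
        elif g.sex[p] == "female" and summary.mother is None:
            summary.mother = _entry(fam, g, p)
        else:
            summary.parents_unsexed.append(_entry(fam, g, p))
    summary.siblings = [
        _entry(fam, g, s) for s in sorted(g.siblings[nid], key=_by_order(g))
    ]
    summary.spouses = [
        _entry(fam, g, s) for s in sorted(g.spouses[nid], key=_by_order(g))
    ]
    summary.children = [
        _entry(fam, g, c) for c in sorted(g.children[nid], key=_by_order(g))
    ]
    return summary


SearchField = Literal["fcode", "name", "any"]


def search(
    fam: Family,
    query: str,
    field: SearchField = "any",
    *,
    regex: bool = False,
) -> list[PersonRecord]:
    """Case-insensitive substring (or regex) search over codes and names,
    results in file order."""
    if field not in ("fcode", "name", "any"):
        raise ValueError(f"field must be fcode/name/any, got {field!r}")
    if regex:
        try:
            pattern = re.compile(query, re.IGNORECASE)
        except re.error as exc:
            raise BadRegex(f"invalid regular expression {query!r}: {exc}") from exc
        match = lambda hay: pattern.search(hay) is not None
    else:
        needle = query.lower()
        match = lambda hay: needle in hay.lower()
    out = []
    for rec in fam.records:
        hays = []
        if field in ("fcode", "any"):
            hays.append(rec.fcode.canonical().render())
        if field in ("name", "any"):
            hays.append(rec.name)
        if any(match(h) for h in hays):
            out.append(rec)
    return out


# ---------------------------------------------------------------------------
# Re-rooting
# ---------------------------------------------------------------------------

_EDGE_PRIORITY = {"parent": 0, "spouse": 1, "sibling": 2, "child": 3}


def _edge_layer(g: KinshipGraph, target: int, kind: str) -> Layer:
    sex = g.sex[target]
    order = g.birth_order[target]
    if kind == "parent":
        return Layer(_PARENT_SYMBOL[sex], order)
    if kind == "spouse":
        return Layer("C", order)
    if kind == "sibling":
        return Layer(_SIBLING_SYMBOL[sex], order if order else UNKNOWN)
    return Layer(_CHILD_SYMBOL[sex], order if order else UNKNOWN)


def rebase(fam: Family, new_oc: Fcode | str) -> Family:
    """Re-express every record relative to a new origin person.

    Codes are rebuilt along breadth-first shortest paths in the person
    graph (ties broken by edge kind — parent, spouse, sibling, child —
    then by code), then normalized. Unsexed symbols (X/H/h) appear
    wherever a sex is underivable, notably for the old OC unless the
    file carried OC metadata. Unreachable persons are dropped with a
    diagnostic on the returned family.
    """
    g = fam.graph()
    root = g.resolve(new_oc)
    paths: dict[int, tuple[Layer, ...]] = {root: ()}
    queue = deque([root])
    while queue:
        cur = queue.popleft()
        steps: list[tuple[int, str, int]] = []
        for p in g.parents[cur]:
            steps.append((_EDGE_PRIORITY["parent"], "parent", p))
        for s in g.spouses[cur]:
            steps.append((_EDGE_PRIORITY["spouse"], "spouse", s))
        for s in g.siblings[cur]:
            steps.append((_EDGE_PRIORITY["sibling"], "sibling", s))
        for c in g.children[cur]:
            steps.append((_EDGE_PRIORITY["child"], "child", c))
        steps.sort(key=lambda t: (t[0], g.code[t[2]]))
        for _, kind, target in steps:
            if target in paths:
                continue
            paths[target] = paths[cur] + (_edge_layer(g, target, kind),)
            queue.append(target)

    out = Family()
    diags: list[str] = []
    for idx, rec in enumerate(fam.records):
        nid = next(
            (n for n, ids in g.record_ids.items() if idx in ids), None
        )
        if nid is None or nid not in paths:
            diags.append(
                f"record {rec.fcode} ({rec.name!r}) is unreachable from the "
                "new origin — dropped"
            )
            continue
        layers = (Layer("*"),) + paths[nid]
        code, _ = normalize(Fcode(layers), "keep")
        new_rec = PersonRecord(
            code.canonical(),
            rec.name,
            rec.nickname,
            rec.birthdate,
            rec.biography,
        )
        try:
            out.add(new_rec)
        except DuplicateFcode:
            diags.append(
                f"record {rec.fcode} ({rec.name!r}) collides with an earlier "
                f"record at {new_rec.fcode} — dropped"
            )
    sex = g.sex[root]
    order = g.birth_order[root]
    if sex != "unknown" or order is not None:
        out.oc_meta = OCMeta(None if sex == "unknown" else sex, order)
    out.diagnostics = diags
    return out
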