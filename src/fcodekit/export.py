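"""Exporters: Graphviz DOT tree, dictionary-style HTML report, PED file.

All three are pure text emitters over a built family graph and are
deterministic for a given family (nodes sorted by canonical code).
DOT is emitted as text only; rendering to PDF/PNG is left to an
external ``dot`` invocation.
"""

from __future__ import annotations

import html

from .family import Family, KinshipGraph

__all__ = ["to_dot", "to_html_report", "to_ped"]

_SEX_CODE = {"male": "1", "female": "2", "unknown": "0"}


def _dot_escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def _sorted_nodes(g: KinshipGraph) -> list[int]:
    return sorted(g.code, key=lambda n: g.code[n])


def _node_name(fam: Family, g: KinshipGraph, nid: int) -> str:
    if g.record_ids[nid]:
        return fam.records[g.record_ids[nid][0]].name
    return ""


def to_dot(fam: Family, graph_name: str = "family") -> str:
    """Family tree as Graphviz DOT text.

    One box per person labeled ``name\\ncode``; each couple is joined
    through a point-shaped junction node, and children hang off the
    junction of their parents (or directly off a single parent).
    """
    g = fam.graph()
    nodes = _sorted_nodes(g)
    ids = {nid: f"p{i}" for i, nid in enumerate(nodes)}

    lines = [f"digraph {graph_name} {{"]
    lines.append('    node [shape=box, fontname="Helvetica"];')
    for nid in nodes:
        name = _node_name(fam, g, nid)
        label = f"{name}\\n{g.code[nid]}" if name else g.code[nid]
        lines.append(f'    {ids[nid]} [label="{_dot_escape(label)}"];')

    couples = sorted(
        {
            tuple(sorted((a, b), key=lambda n: g.code[n]))
            for a in nodes
            for b in g.spouses[a]
        },
        key=lambda ab: (g.code[ab[0]], g.code[ab[1]]),
    )
    union_of: dict[frozenset, str] = {}
    for j, (a, b) in enumerate(couples):
        uid = f"u{j}"
        union_of[frozenset((a, b))] = uid
        lines.append(f"    {uid} [shape=point, label=\"\"];")
        lines.append(f"    {ids[a]} -> {uid} [dir=none];")
        lines.append(f"    {ids[b]} -> {uid} [dir=none];")

    for nid in nodes:
        parents = frozenset(g.parents[nid])
        if not parents:
            continue
        uid = union_of.get(parents)
        if uid is not None:
            lines.append(f"    {uid} -> {ids[nid]};")
        else:
            for p in sorted(parents, key=lambda n: g.code[n]):
                lines.append(f"    {ids[p]} -> {ids[nid]};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def to_html_report(fam: Family, title: str = "Family report") -> str:
    """Dictionary-style HTML report: one anchored entry per recorded
    person, every direct relative linked to its own entry."""
    g = fam.graph()
    record_nodes = sorted(
        (nid for nid in g.code if g.record_ids[nid]),
        key=lambda n: g.code[n],
    )
    anchor = {nid: f"person-{i}" for i, nid in enumerate(record_nodes)}

    def ref(nid: int) -> str:
        name = _node_name(fam, g, nid) or g.code[nid]
        text = html.escape(f"{name} ({g.code[nid]})")
        if nid in anchor:
            return f'<a href="#{anchor[nid]}">{text}</a>'
        return text

    def li(label: str, nids: list[int]) -> str:
        if not nids:
            return ""
        items = ", ".join(ref(n) for n in nids)
        return f"        <li><b>{label}:</b> {items}</li>\n"

    parts = [
        "<!DOCTYPE html>",
        '<html lang="en">',
        "<head>",
        '<meta charset="utf-8">',
        f"<title>{html.escape(title)}</title>",
        "</head>",
        "<body>",
        f"<h1>{html.escape(title)}</h1>",
    ]
    for nid in record_nodes:
        name = _node_name(fam, g, nid) or g.code[nid]
        parts.append(f'<section id="{anchor[nid]}">')
        parts.append(
            f"    <h2>{html.escape(name)} "
            f"<code>{html.escape(g.code[nid])}</code></h2>"
        )
        body = ""
        fathers = [p for p in sorted(g.parents[nid]) if g.sex[p] == "male"]
        mothers = [p for p in sorted(g.parents[nid]) if g.sex[p] == "female"]
        others = [
            p for p in sorted(g.parents[nid]) if g.sex[p] not in ("male", "female")
        ]
        key = lambda n: (g.birth_order[n] is None, g.birth_order[n] or 0, g.code[n])
        body += li("Father", fathers)
        body += li("Mother", mothers)
        body += li("Parent", sorted(others, key=key))
        body += li("Siblings", sorted(g.siblings[nid], key=key))
        body += li("Spouses", sorted(g.spouses[nid], key=key))
        body += li("Children", sorted(g.children[nid], key=key))
        if body:
            parts.append("    <ul>\n" + body + "    </ul>")
        else:
            parts.append("    <p>No recorded direct relationships.</p>")
        parts.append("</section>")
    parts.append("</body>")
    parts.append("</html>")
    return "\n".join(parts) + "\n"


def to_ped(fam: Family, family_id: str = "FAM1") -> str:
    """Six-column pedigree text (family, individual, father, mother,
    sex, phenotype), one line per recorded person.

    Individual ids are canonical codes. A parent is referenced only
    when that parent is itself a recorded person, keeping the file
    closed under parent references; unknown parents are ``0``. Sex is
    1/2/0 for male/female/unknown; when a couple's sexes are both
    unknown the father/mother slots are assigned deterministically by
    code order. Phenotype is always ``0`` (unobserved).
    """
    g = fam.graph()
    node_id: dict[int, str] = {}
    for nid in g.code:
        if g.record_ids[nid]:
            node_id[nid] = fam.records[g.record_ids[nid][0]].normalized()

    lines = []
    for rec_idx, rec in enumerate(fam.records):
        nid = next(n for n, ids in g.record_ids.items() if rec_idx in ids)
        parents = [p for p in sorted(g.parents[nid]) if p in node_id]
        father = mother = "0"
        males = [p for p in parents if g.sex[p] == "male"]
        females = [p for p in parents if g.sex[p] == "female"]
        unknowns = [p for p in parents if g.sex[p] not in ("male", "female")]
        if males:
            father = node_id[males[0]]
        if females:
            mother = node_id[females[0]]
        unknowns.sort(key=lambda n: node_id[n])
        for p in unknowns:
            if father == "0":
                father = node_id[p]
            elif mother == "0":
                mother = node_id[p]
        lines.append(
            "\t".join(
                (
                    family_id,
                    node_id[nid],
                    father,
                    mother,
                    _SEX_CODE.get(g.sex[nid], "0"),
                    "0",
                )
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")
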