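# fcodekit

A toolkit for **kinship path codes** — a human-writable encoding of family
relationships designed for settings where genealogical data arrives
unstructured and out of order (clinical interviews, social-science field
notes, historical records), yet must remain machine-processable alongside
formats like PED/LINKAGE.

A code is a path from a reference person, the *origin of coordinates*
(OC, written `*`), to the encoded person. Each step (*layer*) is a letter
for the relationship — father `P`, mother `M`, brother `O`, sister `A`,
son `o`, daughter `a`, spouse `C`, with unsexed forms `X`/`H`/`h` — plus a
birth-order number where one applies. So `*MM4` is the OC's maternal
grandmother (fourth-born among her siblings), and `*PMA2O1` is the paternal
grandmother's second-born sister's first-born brother. Unlike Ahnentafel or
Register-style numbering, each person's code is independent of the rest of
the dataset: records can be added in any order without renumbering.

What the library covers:

- **Grammar** (`fcodekit.core`): parsing/rendering, depth, positions,
  lineages (desexed, number-free form) and types; strict vs lenient
  numbering conventions.
- **Canonicalization** (`fcodekit.normalizer`): codes must use the
  shortest path from the OC. Exactly 8 of the 16 possible two-step
  lineage adjacencies are reducible (e.g. `hX` — "my child's parent" —
  is just `C`, "my partner"); each has a prescribed rewrite, applied to a
  fixpoint.
- **Families** (`fcodekit.family`): FDATA files (two tab-separated
  columns: code, name; `#` comments), an extended TSV, the derived person
  graph with typed edges and nuclear-family closure, substring/regex
  search, direct-relationship summaries, and re-rooting (`rebase`) at any
  family member.
- **Kinship** (`fcodekit.kinship`): common-ancestor analysis of a code
  pair and the inbreeding estimate `F = (1/2)^(DS1 + DS2)`, where DS1 and
  DS2 are the depths of the two *divergent sections* (the unmatched layer
  suffixes); no common ancestor exists when a spouse layer occurs in a
  divergent section.
- **Synthetic data** (`fcodekit.synthgen`): seeded, reproducible random
  codes and consistent families, valid by construction.
- **Export** (`fcodekit.export`): Graphviz DOT trees, dictionary-style
  HTML reports with cross-linked entries, and 6-column PED.

## Worked example

Quote code arguments — `*` is a shell glob character.

```text
$ fcodekit inbreeding "*P3" "*PMO1a1"
common ancestor: *P3
divergent sections: ('', 'MO1a1')
divergent depths: (0, 3)
F = 0.5^(0+3) = 0.125
```

`*P3` (the father) is itself the last matching position; the second code
diverges by three layers (`MO1a1`: the father's mother's first-born
sister's first-born daughter), so F = (1/2)^(0+3) = 0.125, the
first-cousin-level coefficient.

```text
$ fcodekit normalize "*a1M3"
*C3
```

"My first daughter's mother" is not a shortest path — she is simply "my
partner" (`*C3`; the birth order carries over).

Re-rooting a family file at another member re-encodes everyone:

```text
$ fcodekit rebase simpsons.fdata "*C"
*C	Homer Simpson
*	Marge Simpson
*o1	Bart Simpson
*a2	Lisa Simpson
*a3	Maggie Simpson
*CP	Abe Simpson
*CM	Mona Simpson
```

Other subcommands: `search`, `tree` (DOT), `report` (HTML),
`convert --to {tsv,ped,fdata}`, `random fcode` / `random fdata`. Run
`fcodekit --help` for the full list.

## Notes

See `docs/methods.md` for the model assumptions (monogamous
nuclear-family closure, what information C layers can and cannot carry),
numerical conventions, and known limitations.
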