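# Methods

## The encoding model

A kinship code is a path of relationship steps from a fixed reference
person (the origin of coordinates, OC). Four step categories exist —
parenthood (`P`/`M`/`X`), spousehood (`C`), brotherhood (`O`/`A`/`H`) and
sonship (`o`/`a`/`h`) — with unsexed forms (`X`, `H`, `h`) provided for
computational use. Two numbering conventions govern birth orders:
sibling and offspring steps always carry one (`?` when unrecorded,
since omitting it would be ambiguous within a sibship), while parent and
spouse steps are unique per person, so their order is informative only
as an annotation and the convention attaches it to the final layer only.

The parser is two-moded. *Strict* mode enforces the terminal-only rule
in both directions (interior parent/spouse numbers are rejected, a bare
terminal parent/spouse layer is rejected). *Lenient* mode — the default
for files — accepts and preserves interior numbers and bare terminal
layers: real files (including the canonical seven-person example family
shipped in the tests) routinely write `*P` for "father". The canonical
writer strips interior parent/spouse numbers but never invents a `?`
for a bare terminal layer; this keeps file round-trips byte-exact.

## Shortest-path canonicalization

A code must take the most direct path from OC to person. On the lineage
(desexed, number-free form), exactly eight of the sixteen ordered
two-step adjacencies are reducible under a monogamous nuclear-family
algebra (spouse's spouse = self, child's parent = partner, sibling's
parent = parent, parent's partner = other parent, partner's child =
child, child's sibling = child, sibling's sibling = sibling, parent's
child = sibling). The other eight (grandparent, aunt/uncle, the
in-law compositions, nephew, grandchild) are irreducible.

`normalize` applies the prescribed rewrites to a fixpoint. Two ordering
rules matter and are deliberate:

- **Deletions before substitutions, leftmost first.** Pure deletions
  never lose a birth order; applying a substitution first can. The
  spouse-shortcut example `*PC1o2` must become `*Po2` (delete the
  spouse step), not `*M?o2` (substitute the parent–spouse pair), and
  the chosen priority produces exactly that.
- **The `Xh` rewrite ("parent's child is my sibling") is opt-in**
  (`xh_mode="rewrite"`). It is the one rewrite that can be wrong: the
  parent's child may be the OC themselves, which the code alone cannot
  decide. In the default `keep` mode the pattern is left in place and
  reported as a warning; `rewrite` mode applies it (with the same
  caveat surfaced) for table-faithful canonicalization.

Termination is structural: every fix removes at least one layer, so at
most `depth(f)` fixes are applied. Idempotence and pattern-freeness of
the output are exercised over tens of thousands of seeded random codes.

The parent–spouse substitution (`XC`) loses the surviving parent's
birth order; it emits `?` when the new layer is terminal (where a
number is conventionally expected) and nothing when interior.

## The person graph

All codes in a family share one OC, so their positions jointly define a
graph. Node identity: parent and spouse steps are unique per person
irrespective of birth order (`*P` and `*P3` are the same father — the
weakest rule that unifies spellings, and the model is monogamous);
sibling and offspring steps are distinguished by birth order, with `?`
matching a concrete order only when exactly one candidate with the same
symbol exists (otherwise kept distinct and flagged). Sexed and unsexed
symbols are never unified (`*X` may be either parent; guessing would be
worse than duplication).

Closure rules, iterated to a fixpoint, mirror the rewrite algebra: the
two parents of a person form a couple; full siblings share all known
parents; a partner's child is one's own child; children of the same
parent are siblings. Half- and step-relations are therefore *not*
representable — this is the model's central simplification, inherited
from the shortest-path rules themselves. A family whose records force a
person two distinct fathers, two distinct mothers, or more than two
parents is rejected as inconsistent.

Re-rooting (`rebase`) walks breadth-first shortest paths from the new
origin (ties broken by edge kind — parent, spouse, sibling, child —
then code order, for determinism) and re-encodes each person, then
normalizes. Two kinds of information loss are inherent and documented
rather than papered over: a spouse (`C`) step carries no sex, and the
old OC's sex/birth order are not recorded in any code, so re-encoded
paths may need unsexed symbols and `?` orders. In rare families two
distinct persons (e.g. two orderless, unsexed parents) become textually
identical from the new root; the collision is reported and the later
record dropped — the alphabet cannot express the distinction. An
optional OC-metadata directive (`#! oc sex=... order=...`, read as a
plain comment by other tools) upgrades the old OC's re-encoding.

## Ancestor analysis and the inbreeding estimate

The common ancestor of two codes is the last position at which their
layers match (symbols equal; orders compared only when both sides
record one, making the analysis invariant to the terminal-only
numbering convention). The unmatched suffixes are the divergent
sections; a spouse layer in either voids the ancestor — divergence
through marriage is not descent. The estimate is

    F = (1/2) ** (DS1 + DS2)

with DS1/DS2 the divergent depths: 1 for identical codes, halving per
divergent step, 0 (with an explicit flag on the result object) when no
valid ancestor exists. This is the single-path form of Wright's path
counting: no `+1` exponent, no ancestor-inbreeding factor, no summation
over multiple common ancestors — a code pair exposes exactly one shared
path, and reconciling the estimate with the full multi-loop definition
is out of scope.

Before comparison, codes are normalized using only the
spousehood-preserving rewrites (`HX`, `HH`, `hH`). Full normalization
would delete or create `C` layers (e.g. rewrite "partner's child" into
"child") and silently disarm the marriage rule; the restricted set
unifies equivalent descent spellings while keeping every spouse step
visible to it.

## Synthetic data

The generator emulates small interview-style pedigrees, not demography:
no age structure, mortality, or remarriage, and names come from a
bundled synthetic word list. Codes are grown by walking the
allowed-adjacency automaton (the complement of the eight wrong
patterns), so outputs are shortest-path valid by construction; families
additionally respect per-sibship distinct birth orders, at most one
spouse and two parents per person. Generated records number terminal
parent/spouse layers (complete records, strict-parsable); lenient
parsing of sparser real files is tested separately. Defaults —
`max_depth=4`, `n_people=10`, `max_children=4`, spouse/sibling
probability 0.4 — are chosen once as typical of a recalled close-kin
network; no published distributional target exists for them. All
randomness flows from the single config seed; equal seeds give
byte-identical FDATA.

Passing the randomized suites therefore shows internal consistency of
grammar, rewriting, graph construction and I/O under the generator's
assumptions; it does not validate the nuclear-family model against real
pedigrees containing half-siblings, step-parents or multiple unions.

## Numerical and formatting conventions

- Birth orders are positive integers (multi-digit supported, greedy);
  `0`, signs and a numberless sibling/offspring layer are parse errors.
- Files are UTF-8, LF or CRLF; fields never contain tabs; `#` lines and
  blank lines are skipped; duplicate canonical codes are an error by
  default (downgradable to keep-first with a warning).
- PED export: individual ids are canonical codes; a parent is
  referenced only when that parent is itself a record (keeping the file
  closed under references), otherwise `0`; sex is 1/2/0; when both
  partners' sexes are unknown the father/mother columns are filled
  deterministically by code order; phenotype is always `0`.
- Exporters are pure and deterministic (nodes sorted by canonical
  code); DOT is emitted as text, rendering is delegated to Graphviz.
- Test problem sizes: the large randomized suite uses 10,000 random
  codes and 1,000 eight-person families, sizes at which every property
  has comfortably stabilized while the whole suite stays interactive.

## Known limitations

- Monogamous nuclear-family semantics throughout (no step/half
  relations, at most two parents, one spouse per person).
- `F` follows the printed single-path formula; it understates classical
  multi-loop inbreeding where several common ancestors exist.
- Rebase can lose sex/order information (see above) and, in degenerate
  cases, must drop a textually colliding record with a diagnostic.
- Whether a `C` layer may carry a sex, and how the OC's own birth order
  interacts with sibling numbering, are left outside the code string;
  the OC-metadata directive covers the common need.
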