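# Methods

## Pathway model and GPML

A pathway is a flat object model: data nodes (gene products, proteins,
RNAs, metabolites, sub-pathways), interactions (ordered waypoint polylines
with arrowhead types and optional anchors), labels, shapes and groups, on a
board with origin top-left and y pointing down. Annotations are `(identifier
system, identifier)` pairs compared by exact, case-sensitive string
equality; a missing annotation is `None`, never a pair of empty strings.

GPML I/O targets the 2013a namespace; 2010a documents (where interactions
are `Line` elements) are normalized into the same model and always written
back as 2013a. Fidelity choices:

* **Nothing is dropped.** Unknown attributes are kept per element and
  re-emitted; unrecognized child elements (InfoBox, Legend, Biopax
  payloads, dynamic `Attribute` properties) are stored as canonicalized,
  whitespace-stripped XML fragments and appended on write. `Comment`
  `Source` attributes ride along in a hidden key space of the element's
  extra-attribute store.
* **Determinism.** Elements are written in class order (data nodes,
  interactions, labels, shapes, groups), input order within a class;
  floats use the shortest representation that parses back to the same
  value; indentation is fixed. Two writes of one model are byte-identical,
  which makes regression tests exact.
* **Groups.** GPML expresses membership as `GroupRef` attributes on member
  elements; the model stores a member-id list on the group. Member order is
  therefore document order, an element can be written as a member of at
  most one group (validation flags multi-membership), and a `GroupRef` to a
  non-existent group is kept verbatim rather than invented into a group.
* **Validation** returns issues (severity, graph id, message) instead of
  raising: duplicate graph ids, unknown node/shape types, non-positive
  dimensions, fewer than two waypoints, dangling references, unresolved
  group members are errors; a board smaller than its content is a warning.

## Identifier mapping

The mapper is an undirected graph of symmetric Xref pairs loaded from a
four-column TSV. Matching uses the full transitive closure (memoized
connected components, recomputed when a pair is added): two Xrefs name the
same entity when they are equal or lie in one component. Full closure was
chosen over a designated "backbone" system because with table-driven input
there is no privileged system; chains such as symbol → Entrez → Ensembl
then resolve automatically. Every Xref matches itself even when absent from
the table, so mapping is identity-preserving. No notion of primary vs.
secondary identifiers is modeled — the input table carries no such
distinction.

## Datasets and the criterion language

Column kinds are inferred: numeric iff every non-missing cell parses as a
real with a decimal point and optional scientific notation. The empty cell
is the only missing marker; tokens like `n/a` are data (and make the column
text), and locale decimal commas are deliberately not numbers, keeping
imports identical across machines.

The criterion grammar has precedence comparison > `NOT` > `AND` > `OR`,
left-associative, parentheses override; `ABS` is the only function;
`=`/`<>` are the only operators defined on text, and mixing text with
numbers in a comparison is an evaluation error naming the offending column.
Evaluation is Kleene three-valued: a comparison touching a missing value is
*undefined*; `AND`/`OR`/`NOT` propagate undefined except where the other
operand decides (`false AND undefined = false`, `true OR undefined =
true`). A row "meets" a criterion only on a definite true — undefined never
counts, never matches a color rule, and never makes a gene positive. This
conservative reading was chosen because it is standard (SQL's treatment of
NULL), testable against a truth-table oracle, and never promotes absent
evidence into a result.

The parser is a hand-written recursive-descent parser over a regex lexer;
error positions are character offsets. The pretty-printer emits canonical
text (uppercase keywords, minimal parentheses) that reparses to an
identical tree — fuzzed round-trips enforce this.

## Over-representation analysis

Counting is gene-level. Data rows are bucketed by identifier-equivalence
class (the mapper's component representative); a pathway's annotated Xrefs
are looked up by class, so probe-level multiplicity cannot inflate `n` or
`r`, and any true row makes its gene positive. `total` counts distinct
annotated Xrefs of the selected node types only (default: gene products,
proteins, RNA; metabolite analysis selectable) — unannotated boxes and
graphics can never be measured, so they are not part of the universe.
`N` and `R` are counted over the union of equivalence classes across the
collection, so a gene shared by five pathways contributes once, and genes
absent from every pathway are ignored.

The Z-score is computed in double precision exactly as written above; the
variance factor is evaluated as `1 − (n−1)/(N−1)`, algebraically equal to
`(N−n)/(N−1)` (a test asserts both to 1e−12). When `r` equals the
expectation the numerator `r − nR/N` is exactly zero in IEEE arithmetic
(the division `nR/N` is exact when `N` divides `nR`), so `Z == 0.0` holds
exactly, not approximately. Degenerate variance yields `None`/`NA`, sorted
after all defined scores; ties break by pathway name, then source file.
No permutation p-value is computed — the ranking is by Z-score alone.

## Visualization

Gradients have 2 or 3 strictly increasing anchors. Interpolation is
channel-wise linear in integer RGB with round-half-up and no gamma
correction — naive, but exactly specified, so expected colors in tests are
single integers (blue@−2 / white@0 / red@2 at v = 1 gives (255, 128, 128)).
Values outside the anchor range clamp to the end colors. Color rules are
first-match-wins in declared order; rule criteria share the dataset
criterion language. A node's box is tiled column-major by scheme order and
row-major by data-row (file) order; no data gives one row of the
not-measured color, and a missing value in a gradient column blanks only
its own cell.

SVG is emitted directly as text: one `<g>` per element carrying its graph
id (`class="data-node"` on gene boxes), cells as sub-rectangles splitting
the box width/height evenly, interactions as polylines with arrow/T-bar
markers (other arrowhead types render as plain ends but survive in the
model), labels centered and clipped to their box without font-metric
scaling. Identical inputs give byte-identical SVG. PNG export rasterizes
through `cairosvg` when installed and otherwise raises a capability error;
the SVG path never depends on it.

## Synthetic data

The generator states one world: 20 pathways × 10 genes sampled without
replacement from a 200-gene universe; pathway nodes annotated in system
"SysA", the expression table keyed in "SysB", linked 1:1 by the generated
mapping table so identifier mapping is always exercised. Pathway 0 is
planted by default: its genes meet the criterion with probability 0.9
versus 0.1 for background genes. Positive genes draw |log2FC| ~ U(1.5, 3)
with random sign and p ~ U(10⁻⁴, 0.01); background genes draw
log2FC ~ U(−0.5, 0.5), p ~ U(0.2, 0.9) — comfortably inside/outside the
|log2FC| > 1, p < 0.05 criterion, as in a clean differential-expression
experiment. Each artifact uses one `random.Random` derived from the spec
seed; outputs are byte-reproducible.

What the generator does *not* emulate: correlated expression within
pathways, probe-level noise or many-to-many identifier mappings, missing
values, text columns, or pathway overlap structure beyond independent
sampling. A green planted-recovery test therefore establishes that the
pipeline ranks a strong, clean enrichment first — not performance under
realistic noise.

One subtlety found while validating the null case (no planted pathway):
with small integer counts, several pathways often tie at the top Z-score,
and the deterministic name tie-break then always credits the
lexicographically first pathway. Measured with fair (seeded random) tie
breaking, pathway 0 tops the ranking in 1/20 of replicates as symmetry
requires; measured through the reporting tie-break it appears first more
often. The reporting order is a presentation convention, not a statistical
claim.

## Limitations

* GPML states (gene-variant boxes), nested groups' semantics and the
  visual attributes of elements (colors, fonts, line styles) are carried
  opaquely, not modeled.
* `total` counts annotated data nodes only; collections whose diagrams are
  sparsely annotated will under-count pathway size.
* The criterion language has no arithmetic beyond `ABS` and no `IN`/range
  syntax.
* Rendering is schematic (rectangles, polylines, unscaled centered text),
  aimed at faithful data display rather than publication graphics.
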