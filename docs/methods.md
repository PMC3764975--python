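# Methods

## The representation

A CML CompChem document is ordinary namespaced XML in which meaning is
carried by three things: the element vocabulary of the CML namespace
(`http://www.xml-cml.org/schema`), dictionary references (`dictRef`
attributes whose QName values point into the CompChem dictionary
namespace, `http://www.xml-cml.org/dictionary/compchem/`), and explicit
units references on every numeric quantity. The package treats everything
else — namespace prefix spellings, attribute order, indentation — as
presentation. This split is what `semantically_equal` implements: two
documents are equal iff their trees match under resolved (URI, local-name)
element and attribute identity, with element order and element text
compared exactly. QName-valued attributes (`dictRef`, `units`, `name`,
`convention`, `dataType`) are compared by resolved URI when their prefix
is bound, falling back to literal comparison otherwise (the `xsd:` prefix
is conventionally used without being declared).

Mixed content (non-whitespace text interleaved with child elements) is not
part of any format here; the parser concatenates such text into the node's
text field rather than dropping it, and whitespace-only text between
children is treated as indentation and discarded. Leaf-element text is
preserved byte-exactly — that is the load-bearing rule for the input-deck
format. Character data is escaped (`&amp;`, `&lt;`, `&gt;`) rather than
wrapped in CDATA so canonicalizers cannot change the content model.

## Writer strictness

The writer is a state machine (open session → open/close modules → finish)
whose operations validate before they mutate, so the document under
construction is convention-conformant at every step:

- atoms require a known element symbol and three finite coordinates;
  generated ids are `a1…aN` in input order, caller-supplied ids win and
  must be unique;
- numeric scalars require a units QName — dimensionless quantities use
  `units:none` rather than omitting the attribute, so "has units" is a
  checkable syntactic property;
- string scalars may not carry dimensioned units;
- `finish()` fails while modules remain open, and a finished session
  refuses further writes.

Coordinates are written with 10 significant digits (`%.10g`), which
round-trips Å-scale geometry well below chemical significance (1e-6 Å).
Orbital energies and coefficients use Python shortest-repr doubles (up to
17 significant digits), so read-after-write recovers the exact binary
value. The units dictionary prefix `units:` is bound to
`http://www.xml-cml.org/units/` with `units:hartree`, `units:angstrom` and
`units:none` as the references this package emits; energies are stored in
Hartree only, with no conversion layer.

The intended invariant, exercised by the test suite, is writer-strictness
≡ validator-soundness: no sequence of writer calls can produce a document
the validator flags with an error.

## Molecular orbitals

One set is a `cml:list` with dictRef `compchem:molecularOrbitals`
containing an `xsd:string` array of basis descriptions and one
`compchem:molecularOrbital` list per orbital (energy, symmetry, spin,
occupancy scalars and the `compchem:aoVector` coefficient array, whose
length must equal the basis count). Constraints enforced on both write and
validate: occupancy in [0, 2], at most 1 when the spin channel is alpha or
beta; spin in {alpha, beta, none}; shell labels drawn from either the
cartesian (s, px, py, pz, dxx, dxy, …) or the spherical (s, px, py, pz,
d-2 … d2, …) vocabulary, generated here up to g shells and extensible, and
not mixed within one set. When an electron count is supplied, occupancies
must sum to it within 1e-8 (an absolute tolerance; occupancies are O(1)
numbers, so no relative scaling is needed).

Basis descriptions are serialized as `1:H,s` with no internal spaces:
CML arrays are whitespace-tokenized, so a space inside a token would break
the array into fragments. A single space after the comma is tolerated on
input.

## Input-deck embedding

Each file becomes a module (dictRef `compchem:inputFile`, grouped under
`compchem:inputFileList`) holding a metadataList (file name under
`compchem:inputFileName`; absent for nameless sources such as standard
input) and one `xsd:string` scalar per line, line endings stripped, in
document order. `xml:space="preserve"` is set on line scalars as a defence
against generic XML tooling; the package's own parser preserves leaf text
regardless. Only ASCII is accepted — a non-ASCII byte is a hard error with
its offset reported — and CR/LF may not appear inside a line.

Stripping line endings loses one bit of information: whether the file
ended with a newline. Reconstruction always appends a final line ending
(default `\n`, `\r\n` selectable); when a dumped file lacked one, the
writer records an extension metadata entry (`compchem:x-noFinalNewline`)
that this package's extractors surface as a flag and plain readers simply
ignore. Per-line ending style is deliberately not recorded.

The streaming extractor is an expat state machine that reacts only to
`cml:module`/`cml:scalar`/`cml:metadata` events at the relevant depths,
maintaining its own prefix-binding stack to resolve dictRef values; memory
is bounded by the largest single embedded file, which the tests check
coarsely (allocation peak under a quarter of a ~10 MB document; in
practice it is a few hundred kB). A truncated or malformed stream raises
and discards partial results. An empty deck (zero files) is written with a
warning and read back as empty: permissive write, strict validate.

## Tolerant reading

`read_calculation` aggregates geometry, dictRef-tagged scalar properties
(excluding those inside input-file modules and orbital containers),
the orbital set and the input deck. Unknown elements — any element outside
the known CML vocabulary, in any namespace — are counted in
`unrecognized_count` and otherwise ignored, so adding future vocabulary to
a document never changes what this reader recovers. Numeric properties
that fail to parse are kept as strings with a warning: the reader is
lenient exactly where the writer is strict.

Multi-step documents (several geometries or orbital sets) are read by
taking the *last* occurrence in document order — the converged or final
result by convention — with counts of all occurrences reported
(`geometry_count`, `mo_set_count`). `extract_geometry` and
`read_molecular_orbitals` default to the first occurrence and take a
`which` argument; the last-occurrence rule is a provisional choice pending
a real multi-step convention.

## Validation severities

"Must"-level structural rules are errors (missing units on numeric
scalars, unresolvable dictRef prefixes, incomplete atoms, orbital
constraint violations, non-ASCII deck text); "should"-level stylistic ones
are warnings (foreign elements inside input-file modules, missing file
name metadata). `--strict` on the CLI promotes warnings to errors. Issue
locations are positional paths (`/cml:cml/cml:module[2]/cml:scalar[3]`)
that resolve to a unique node in the document.

## Synthetic data

The generators exist so that every property above is testable with no
external inputs. A single integer seed feeds one named PRNG stream per
generator (string-seeded `random.Random`, which is stable across processes
and platforms); the same seed yields byte-identical documents. Default
fixture sizes — 2 files of up to 12 lines, 3 atoms, 6 basis functions,
6 orbitals — keep a full corpus of documents cheap while covering every
structural feature; the deliberately bulky document for streaming tests is
~10 MB. Input-file lines are drawn to cover the whitespace cases the
format must preserve (empty lines, tabs, leading/trailing spaces, runs of
spaces, arbitrary printable ASCII). Orbital sets are closed-shell by
default (lowest half of the orbitals doubly occupied, so occupancies sum
to an even electron count; the two-orbital case gives [2.0, 0.0] — the
minimal H2-like picture) or spin-resolved with occupancies ≤ 1; a
violation-injection mode flips exactly one constraint for mutation
testing.

What the generator does *not* emulate: physically meaningful
wavefunctions (coefficients are Gaussian noise, energies are sorted
uniform draws), real program input syntax beyond superficial resemblance,
basis-set contraction data, or non-ASCII/binary payloads. Passing tests
therefore demonstrate format fidelity — round trips, invariances,
constraint enforcement — not chemical correctness of any calculation.

## Known limitations

- Comments and processing instructions do not survive parsing; they are
  outside semantic equality by design.
- Mixed content is tolerated on parse but has no serialization guarantee.
- The `convention` attribute value on the root is emitted as
  `convention:compchem` but is configurable; no claim of parity with any
  external CML validation service is made, and full CML XSD validation is
  out of scope.
- Nested input-file modules inside other input-file modules are not part
  of the format; the DOM and streaming extractors may treat such documents
  differently.
- f-shell and higher labels follow the generated cartesian/spherical
  patterns; codes using other conventions need the vocabulary extended.
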