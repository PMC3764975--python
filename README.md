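# cmlcompchem

Semantically rich storage of computational-chemistry results in Chemical
Markup Language (CML), for people who write simulation outputs that other
software — validators, visualizers, search indexes — must still understand
years later.

Quantum-chemistry codes traditionally emit free-form text logs that every
downstream tool re-parses with its own heuristics. Storing results as
namespaced XML with dictionary references (`dictRef` attributes pointing
into a controlled CompChem vocabulary) removes that ambiguity, but only if
producers are *strict* and consumers are *tolerant*. This package
implements both sides:

- **`cmlcompchem.writer`** — a session-based writer through which it is
  impossible to emit convention-violating CML: an atom cannot be added
  without an element symbol *and* a full x3/y3/z3 position (Å), a numeric
  `cml:scalar` cannot be written without a units reference, and the
  `cml` / `convention` / `compchem` namespaces are always declared.
- **`cmlcompchem.mo`** — the molecular-orbital format: a `cml:list`
  container holding an array of atomic-basis-function descriptions
  (`1:H,s` = atom 1, hydrogen, s shell) and, per orbital φᵢ = Σμ cμᵢ χμ,
  scalars for the energy εᵢ (Hartree), point-group symmetry label, spin
  channel and occupancy nᵢ ∈ [0, 2] (nᵢ ≤ 1 for a spin-resolved channel),
  plus the coefficient vector (cμᵢ) as a `cml:array`.
- **`cmlcompchem.deck`** — byte-faithful embedding of the ASCII input
  file(s) that drove a calculation: one `cml:scalar` per line, empty lines
  as empty scalars, all whitespace (tabs, runs of spaces, leading/trailing
  blanks) preserved so the exact input deck can be reconstructed — even
  after the document has been canonicalized — by a DOM extractor or a
  constant-memory streaming extractor. Both a whole-file interface and a
  five-call streaming write interface (list/file/line/…) are provided.
- **`cmlcompchem.reader`** — a tolerant reader that scans a document for
  the structures it understands (geometry, scalar properties, orbitals,
  input deck) and ignores — but counts — everything else, so documents
  from future producers still read correctly.
- **`cmlcompchem.validation`** — convention-level checks (units on numeric
  scalars, resolvable dictRefs, complete atoms, orbital constraints,
  input-deck structure) with error/warning severities.
- **`cmlcompchem.core`** — the underlying document model with *semantic*
  equality (prefix spellings, attribute order and indentation are
  presentation; element order and text are data) and a lossless CML↔JSON
  bridge.
- **`cmlcompchem.fixtures`** — seeded synthetic input decks, orbital sets
  and whole calculation documents, so every property above is testable
  without any external data.

## Worked example

Pack two input files into a CML document, validate it, and get the files
back byte-for-byte:

```sh
$ printf 'geometry\n  H 0 0 0\n\tH 0 0 0.74\n\nend\n' > h2.nw
$ cmlcc pack-inputs h2.nw -o deck.cml
$ cmlcc validate deck.cml
valid: no issues
$ cmlcc extract-inputs deck.cml -o out
wrote out/h2.nw (5 lines)
$ cmp h2.nw out/h2.nw && echo byte-identical
byte-identical
```

Generate a synthetic calculation and inspect its orbitals and geometry:

```sh
$ cmlcc make-fixture --seed 3 --kind calc -o fx
$ cmlcc mo-summary fx/calc_3.cml
6 basis functions, 6 orbitals
   #      energy/Eh   spin   occ  symmetry
   1      -1.600721   none  2.00  a1
   2      -1.517183   none  2.00  b2
   ...
$ cmlcc to-xyz fx/calc_3.cml | head -3
3
extracted from fx/calc_3.cml
N      -2.54085000     -2.14400200     -0.65795300
```

The first mo-summary column is the orbital index, the second the orbital
energy εᵢ in Hartree, then spin channel, occupancy and symmetry label; the
XYZ output is the standard count/comment/`symbol x y z` layout in Å. The
same operations are available as library calls (`read_calculation`,
`extract_input_deck`, `write_molecular_orbitals`, …); the CLI also offers
`to-json` / `from-json` for the lossless JSON mapping.

## Documentation

`docs/methods.md` describes the formats, the numerical and design choices,
what the synthetic generator does and does not emulate, and known
limitations.
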