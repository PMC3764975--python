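"""Seeded synthetic data: input decks, molecular-orbital sets and whole
calculation documents.

Everything here is generated from a single integer seed through one
private PRNG stream (no global random state), so every fixture is exactly
reproducible.  The input-file generator deliberately covers the whitespace
edge cases the embedding format must preserve: empty lines, tab
indentation, runs of internal spaces, leading and trailing spaces.  The
orbital generator produces structurally valid (not physically meaningful)
wavefunction coefficients, closed-shell by default, and can inject exactly
one named constraint violation for mutation testing.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace

from .core import CmlDocument, DIMENSIONLESS, HARTREE, CmlNode
from .deck import InputDeck, InputFile, write_input_deck
from .mo import (
    AtomicBasisDescription,
    MolecularOrbital,
    MolecularOrbitalSet,
    write_molecular_orbitals,
)
from .writer import Atom, Molecule, begin_document

__all__ = [
    "FixtureSpec",
    "generate_input_file",
    "generate_input_deck",
    "generate_mo_set",
    "generate_calculation_document",
    "inject_unknown_elements",
    "INVALID_CODES",
]

INVALID_CODES = (
    "occupancy_range",
    "spin_occupancy",
    "bad_spin",
    "vector_length",
    "bad_basis",
)

_ELEMENT_POOL = ["H", "C", "N", "O"]
# Minimal-basis shells per element (H: 1s; first row: 1s 2s 2p).
_SHELLS = {"H": ["s"], "C": ["s", "s", "px", "py", "pz"]}
_SHELLS["N"] = _SHELLS["O"] = _SHELLS["C"]

_WORDS = [
    "geometry", "basis", "task", "scf", "dft", "end", "charge", "title",
    "units", "angstrom", "print", "memory", "maxiter", "vectors", "xc",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic fixture; the seed fully determines it."""

    seed: int = 0
    n_files: int = 2
    n_lines_max: int = 12
    line_len_max: int = 40
    n_atoms: int = 3
    n_basis: int = 6
    n_orbitals: int = 6
    spin_resolved: bool = False
    inject_invalid: str | None = None

    def __post_init__(self):
        for name in ("n_files", "n_lines_max", "line_len_max", "n_atoms",
                     "n_basis", "n_orbitals"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.inject_invalid is not None and self.inject_invalid not in INVALID_CODES:
            raise ValueError(f"unknown violation code {self.inject_invalid!r}")


def _random_line(rng: random.Random, max_len: int) -> str:
    kind = rng.random()
    if kind < 0.12:
        return ""
    if kind < 0.30:
        # Coordinate-like line: leading spaces and internal runs of spaces.
        el = rng.choice(_ELEMENT_POOL)
        pad = " " * rng.randint(1, 4)
        sep = " " * rng.randint(1, 3)
        return pad + el + sep.join(
            "" if i == 0 else f"{rng.uniform(-9, 9):.6f}" for i in range(4)
        )
    if kind < 0.42:
        return "\t" + rng.choice(_WORDS) + "\t" + rng.choice(_WORDS)
    if kind < 0.54:
        return rng.choice(_WORDS) + " " * rng.randint(1, 3)  # trailing spaces
    n = rng.randint(1, max(1, max_len))
    return "".join(chr(rng.randint(32, 126)) for _ in range(n))


def generate_input_file(spec: FixtureSpec) -> InputFile:
    """One deterministic ASCII input file with whitespace edge cases."""
    rng = random.Random(f"file-{spec.seed}")
    n_lines = rng.randint(0, spec.n_lines_max) if spec.n_lines_max else 0
    lines = [_random_line(rng, spec.line_len_max) for _ in range(n_lines)]
    return InputFile(file_name=f"job{spec.seed}.nw", lines=lines)


def generate_input_deck(spec: FixtureSpec) -> InputDeck:
    files = [
        generate_input_file(replace(spec, seed=spec.seed * 1000 + i))
        for i in range(spec.n_files)
    ]
    for i, f in enumerate(files):
        f.file_name = f"job{spec.seed}_{i}.nw"
    return InputDeck(files=files, title=f"input deck (seed {spec.seed})")


def generate_mo_set(spec: FixtureSpec) -> tuple[Molecule, MolecularOrbitalSet]:
    """A molecule plus a structurally valid orbital set.

    Closed-shell sets occupy the lowest half of the orbitals with 2
    electrons each (so occupancies sum to an even electron count);
    spin-resolved sets alternate alpha/beta channels with occupancies of
    at most 1.  ``inject_invalid`` flips exactly one constraint.
    """
    rng = random.Random(f"mo-{spec.seed}")
    atoms = [
        Atom(
            element=rng.choice(_ELEMENT_POOL) if spec.n_atoms > 2 or i == 0 else "H",
            x3=round(rng.uniform(-3, 3), 6),
            y3=round(rng.uniform(-3, 3), 6),
            z3=round(rng.uniform(-3, 3), 6),
        )
        for i in range(max(1, spec.n_atoms))
    ]
    molecule = Molecule(atoms=atoms)

    descriptions = []
    i_atom = 0
    while len(descriptions) < max(1, spec.n_basis):
        atom = atoms[i_atom % len(atoms)]
        for shell in _SHELLS.get(atom.element, ["s"]):
            if len(descriptions) >= max(1, spec.n_basis):
                break
            descriptions.append(
                AtomicBasisDescription(
                    atom_number=(i_atom % len(atoms)) + 1,
                    atom_name=atom.element,
                    shell_type=shell,
                )
            )
        i_atom += 1

    n_orb = max(1, spec.n_orbitals)
    energies = sorted(rng.uniform(-2.0, 1.5) for _ in range(n_orb))
    orbitals = []
    n_occ = n_orb // 2
    for i, energy in enumerate(energies):
        if spec.spin_resolved:
            spin = "alpha" if i % 2 == 0 else "beta"
            occ = 1.0 if i < n_occ else 0.0
        else:
            spin = "none"
            occ = 2.0 if i < n_occ else 0.0
        orbitals.append(
            MolecularOrbital(
                energy=round(energy, 6),
                symmetry=rng.choice(["a1", "b1", "b2", "a2", "sg", "su"]),
                spin=spin,
                occupancy=occ,
                coefficients=[
                    round(rng.gauss(0.0, 0.5), 6) for _ in range(len(descriptions))
                ],
            )
        )
    mos = MolecularOrbitalSet(descriptions=descriptions, orbitals=orbitals)

    code = spec.inject_invalid
    if code == "occupancy_range":
        mos.orbitals[0].spin = "none"
        mos.orbitals[0].occupancy = 2.5
    elif code == "spin_occupancy":
        mos.orbitals[0].spin = "alpha"
        mos.orbitals[0].occupancy = 1.5
    elif code == "bad_spin":
        mos.orbitals[0].spin = "gamma"
    elif code == "vector_length":
        mos.orbitals[0].coefficients.append(0.1)
    elif code == "bad_basis":
        mos.descriptions[0] = replace(mos.descriptions[0], shell_type="q7")
    return molecule, mos


def electron_count(mos: MolecularOrbitalSet) -> float:
    return sum(o.occupancy for o in mos.orbitals)


def generate_calculation_document(spec: FixtureSpec) -> CmlDocument:
    """A complete synthetic calculation document, built through the strict
    writer: metadata, embedded input deck, geometry, scalar properties and
    the molecular-orbital set."""
    rng = random.Random(f"calc-{spec.seed}")
    session = begin_document(title=f"synthetic calculation (seed {spec.seed})")
    session.add_metadata("compchem:program", "cmlcompchem synthetic generator")
    session.add_metadata("compchem:jobName", f"job{spec.seed}")

    deck = generate_input_deck(spec)
    write_input_deck(session, deck)

    molecule, mos = generate_mo_set(spec)
    session.open_module("compchem:calculation", title="synthetic single point")
    session.add_molecule(molecule)
    session.add_scalar(
        "compchem:totalEnergy", round(rng.uniform(-200.0, -1.0), 8), HARTREE
    )
    session.add_scalar(
        "compchem:numberOfElectrons", int(electron_count(mos)), DIMENSIONLESS,
        data_type="xsd:integer",
    )
    session.add_scalar("compchem:pointGroup", "C1")
    write_molecular_orbitals(session, mos)
    session.close_module()
    return session.finish()


def generate_large_document(seed: int = 0, target_bytes: int = 10_000_000) -> CmlDocument:
    """A bulky document (default ~10 MB serialized) holding one small input
    deck amid a large volume of unrelated scalar data — the shape that
    makes constant-memory streaming extraction worthwhile."""
    import string

    rng = random.Random(f"large-{seed}")
    session = begin_document(title="bulk synthetic document")
    write_input_deck(session, generate_input_deck(FixtureSpec(seed=seed, n_files=1)))
    session.open_module("compchem:trajectory", title="bulk filler")
    alphabet = string.ascii_letters + string.digits + " "
    pool = "".join(rng.choices(alphabet, k=4096))
    per_scalar = 1000
    n = max(1, target_bytes // (per_scalar + 80))
    for i in range(n):
        node = CmlNode(qname="cml:scalar")
        node.attributes["dataType"] = "xsd:string"
        off = (i * 37) % (len(pool) - per_scalar)
        node.text = pool[off : off + per_scalar]
        session._add_leaf(node)
    session.close_module()
    return session.finish()


def inject_unknown_elements(
    doc: CmlDocument, n: int, seed: int
) -> CmlDocument:
    """Insert *n* unknown, namespace-qualified elements into the tree.

    Insertion points are elements that already have element children, so
    the content model of text leaves is untouched.  Used to demonstrate
    reader forward-compatibility.  The document is modified in place and
    returned.
    """
    rng = random.Random(f"inject-{seed}")
    for i in range(n):
        hosts = [node for node in doc.iter() if node.children]
        host = rng.choice(hosts)
        unknown = CmlNode(qname=f"x:future{i}")
        unknown.ns_decls["x"] = "http://example.org/future-vocabulary"
        unknown.attributes["x:kind"] = "novel"
        if rng.random() < 0.5:
            child = CmlNode(qname="x:payload")
            child.text = f"opaque-{i}"
            unknown.append(child)
        host.children.insert(rng.randint(0, len(host.children)), unknown)
    return doc
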