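"""Molecular-orbital CML format.

A set of molecular orbitals is stored as a ``cml:list`` container
(dictRef ``compchem:molecularOrbitals``) holding

* one ``cml:array`` of atomic-basis-function descriptions
  (``compchem:atomicBasisDescriptions``, dataType xsd:string), each token
  of the form ``<atom number>:<element>,<shell>`` — e.g. ``1:H,s``; and
* one ``cml:list`` per orbital (``compchem:molecularOrbital``) carrying
  scalars for the orbital energy (Hartree), point-group symmetry label,
  spin channel and occupancy, plus the coefficient vector as a
  ``cml:array`` of doubles (``compchem:aoVector``).

Occupancies range from 0 to 2 electrons; a spin-resolved (alpha or beta)
orbital holds at most 1.  Shell labels follow either the cartesian
(s, px, py, pz, dxx, dxy, …) or the spherical (s, px, py, pz, d-2, …, d2)
naming, and a single set must not mix the two.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .core import (
    CmlDocument,
    CmlNode,
    CmlStructureError,
    DIMENSIONLESS,
    HARTREE,
    find_by_dictref,
)
from .writer import _ELEMENTS, WriterError, WriterSession

__all__ = [
    "AtomicBasisDescription",
    "MolecularOrbital",
    "MolecularOrbitalSet",
    "format_basis_description",
    "parse_basis_description",
    "write_molecular_orbitals",
    "read_molecular_orbitals",
    "validate_mo_set",
    "CARTESIAN_SHELLS",
    "SPHERICAL_SHELLS",
]


def _cartesian_labels(max_l: int = 4) -> set[str]:
    labels = {"s", "px", "py", "pz"}
    letters = {2: "d", 3: "f", 4: "g"}
    for l in range(2, max_l + 1):
        for combo in itertools.combinations_with_replacement("xyz", l):
            labels.add(letters[l] + "".join(combo))
    return labels


def _spherical_labels(max_l: int = 4) -> set[str]:
    labels = {"s", "px", "py", "pz"}
    letters = {2: "d", 3: "f", 4: "g"}
    for l in range(2, max_l + 1):
        for m in range(-l, l + 1):
            labels.add(f"{letters[l]}{m}")
    return labels


#: The two shell-label vocabularies; extensible by mutation if higher
#: angular momenta are ever needed.
CARTESIAN_SHELLS = _cartesian_labels()
SPHERICAL_SHELLS = _spherical_labels()

_SPINS = ("alpha", "beta", "none")


@dataclass(frozen=True)
class AtomicBasisDescription:
    """One atomic basis function: which atom it sits on (1-based), the
    element symbol of that atom, and the shell (angular-momentum) label."""

    atom_number: int
    atom_name: str
    shell_type: str


@dataclass
class MolecularOrbital:
    energy: float  # Hartree
    symmetry: str = ""
    spin: str = "none"
    occupancy: float = 0.0
    coefficients: list[float] = field(default_factory=list)


@dataclass
class MolecularOrbitalSet:
    descriptions: list[AtomicBasisDescription]
    orbitals: list[MolecularOrbital]


# ---------------------------------------------------------------------------
# Basis-description microsyntax


def format_basis_description(d: AtomicBasisDescription) -> str:
    """Render as ``1:H,s`` — no internal spaces, so tokens survive storage
    in a whitespace-delimited CML array."""
    return f"{d.atom_number}:{d.atom_name},{d.shell_type}"


def parse_basis_description(s: str) -> AtomicBasisDescription:
    """Inverse of :func:`format_basis_description`; a single space after the
    comma is tolerated on input."""
    head, comma, shell = s.partition(",")
    num, colon, name = head.partition(":")
    shell = shell.lstrip(" ")
    if not (comma and colon) or not num.isdigit() or not name or not shell:
        raise CmlStructureError(f"unparseable basis description: {s!r}")
    atom_number = int(num)
    if atom_number < 1:
        raise CmlStructureError(f"atom number must be >= 1 in {s!r}")
    if shell not in CARTESIAN_SHELLS and shell not in SPHERICAL_SHELLS:
        raise CmlStructureError(f"unknown shell label {shell!r} in {s!r}")
    return AtomicBasisDescription(atom_number, name, shell)


# ---------------------------------------------------------------------------
# Validation (shared predicate: the writer rejects exactly what the
# validator flags)


def validate_mo_set(mos: MolecularOrbitalSet, electron_count: float | None = None):
    """Check a set against the dictionary constraints; returns a list of
    :class:`~cmlcompchem.validation.ValidationIssue` (empty when valid)."""
    from .validation import ValidationIssue

    issues: list[ValidationIssue] = []

    def err(code: str, where: str, msg: str) -> None:
        issues.append(ValidationIssue("error", code, where, msg))

    if not mos.descriptions:
        err("mo-empty-basis", "descriptions", "basis description list is empty")
    seen_vocab: set[str] = set()
    for i, d in enumerate(mos.descriptions):
        where = f"descriptions[{i}]"
        if d.atom_number < 1:
            err("mo-bad-atom-number", where, f"atom number {d.atom_number} < 1")
        if d.atom_name not in _ELEMENTS:
            err("mo-bad-element", where, f"unknown element symbol {d.atom_name!r}")
        in_cart = d.shell_type in CARTESIAN_SHELLS
        in_sph = d.shell_type in SPHERICAL_SHELLS
        if not (in_cart or in_sph):
            err("mo-bad-shell", where, f"unknown shell label {d.shell_type!r}")
        else:
            if in_cart and not in_sph:
                seen_vocab.add("cartesian")
            elif in_sph and not in_cart:
                seen_vocab.add("spherical")
    if len(seen_vocab) > 1:
        err(
            "mo-mixed-vocabulary",
            "descriptions",
            "cartesian and spherical shell labels mixed in one set",
        )
    n_basis = len(mos.descriptions)
    occ_sum = 0.0
    for i, orb in enumerate(mos.orbitals):
        where = f"orbitals[{i}]"
        if orb.spin not in _SPINS:
            err(
                "mo-bad-spin",
                where,
                f"spin must be one of alpha, beta or none; got {orb.spin!r}",
            )
        max_occ = 1.0 if orb.spin in ("alpha", "beta") else 2.0
        if not (0.0 <= orb.occupancy <= max_occ):
            err(
                "mo-occupancy-range",
                where,
                f"occupancy {orb.occupancy} outside [0, {max_occ}]"
                + (f" for spin {orb.spin}" if max_occ == 1.0 else ""),
            )
        if len(orb.coefficients) != n_basis:
            err(
                "mo-vector-length",
                where,
                f"aoVector has {len(orb.coefficients)} coefficients, "
                f"expected {n_basis}",
            )
        occ_sum += orb.occupancy
    if electron_count is not None and abs(occ_sum - electron_count) > 1e-8:
        err(
            "mo-electron-count",
            "orbitals",
            f"occupancies sum to {occ_sum}, expected {electron_count}",
        )
    return issues


# ---------------------------------------------------------------------------
# Writing


def _array_node(dictref: str, data_type: str, tokens: list[str]) -> CmlNode:
    node = CmlNode(qname="cml:array")
    node.attributes["dictRef"] = dictref
    node.attributes["dataType"] = data_type
    node.attributes["size"] = str(len(tokens))
    node.text = " ".join(tokens)
    return node


def write_molecular_orbitals(session: WriterSession, mos: MolecularOrbitalSet) -> None:
    """Emit a molecular-orbital set at the session's current position.

    The set is validated first; nothing is written for an invalid set.
    """
    issues = validate_mo_set(mos)
    if issues:
        raise WriterError(
            "invalid molecular-orbital set: "
            + "; ".join(f"{i.code} at {i.location}" for i in issues)
        )
    container = CmlNode(qname="cml:list")
    container.attributes["dictRef"] = "compchem:molecularOrbitals"
    container.append(
        _array_node(
            "compchem:atomicBasisDescriptions",
            "xsd:string",
            [format_basis_description(d) for d in mos.descriptions],
        )
    )
    for orb in mos.orbitals:
        onode = CmlNode(qname="cml:list")
        onode.attributes["dictRef"] = "compchem:molecularOrbital"

        def scalar(dictref, data_type, text, units=None):
            s = CmlNode(qname="cml:scalar")
            s.attributes["dictRef"] = dictref
            s.attributes["dataType"] = data_type
            if units is not None:
                s.attributes["units"] = units.units_ref
            s.text = text
            return s

        onode.append(
            scalar("compchem:orbitalEnergy", "xsd:double", repr(float(orb.energy)), HARTREE)
        )
        onode.append(scalar("compchem:orbitalSymmetry", "xsd:string", orb.symmetry))
        onode.append(scalar("compchem:orbitalSpin", "xsd:string", orb.spin))
        onode.append(
            scalar(
                "compchem:orbitalOccupancy",
                "xsd:double",
                repr(float(orb.occupancy)),
                DIMENSIONLESS,
            )
        )
        onode.append(
            _array_node(
                "compchem:aoVector",
                "xsd:double",
                [repr(float(c)) for c in orb.coefficients],
            )
        )
        container.append(onode)
    session._add_leaf(container)


# ---------------------------------------------------------------------------
# Reading (tolerant: unknown siblings/children are ignored)


def _subtree_ids(node: CmlNode) -> set[int]:
    return {id(n) for n in node.iter()}


def _first_text(doc, container_ids, within_ids, dictref, default=None):
    for node in find_by_dictref(doc, dictref):
        if id(node) in within_ids:
            return node.text
    return default


def read_molecular_orbitals(
    doc: CmlDocument, which: str = "first"
) -> MolecularOrbitalSet | None:
    """Recover a molecular-orbital set from a document, or None when absent.

    ``which`` selects the first or last container in document order when a
    multi-step document carries several.
    """
    containers = find_by_dictref(doc, "compchem:molecularOrbitals")
    if not containers:
        return None
    container = containers[0] if which == "first" else containers[-1]
    inside = _subtree_ids(container)

    desc_arrays = [
        n
        for n in find_by_dictref(doc, "compchem:atomicBasisDescriptions")
        if id(n) in inside
    ]
    if not desc_arrays:
        raise CmlStructureError(
            "molecularOrbitals container lacks an atomicBasisDescriptions array"
        )
    descriptions = [
        parse_basis_description(tok) for tok in desc_arrays[0].text.split()
    ]

    orbitals: list[MolecularOrbital] = []
    for idx, onode in enumerate(
        n for n in find_by_dictref(doc, "compchem:molecularOrbital") if id(n) in inside
    ):
        oids = _subtree_ids(onode)
        energy = _first_text(doc, inside, oids, "compchem:orbitalEnergy", "0")
        symmetry = _first_text(doc, inside, oids, "compchem:orbitalSymmetry", "")
        spin = _first_text(doc, inside, oids, "compchem:orbitalSpin", "none")
        occupancy = _first_text(doc, inside, oids, "compchem:orbitalOccupancy", "0")
        vec_arrays = [
            n for n in find_by_dictref(doc, "compchem:aoVector") if id(n) in oids
        ]
        coefficients = (
            [float(t) for t in vec_arrays[0].text.split()] if vec_arrays else []
        )
        if len(coefficients) != len(descriptions):
            raise CmlStructureError(
                f"orbital {idx}: aoVector length {len(coefficients)} does not "
                f"match basis description count {len(descriptions)}"
            )
        orbitals.append(
            MolecularOrbital(
                energy=float(energy),
                symmetry=symmetry,
                spin=spin,
                occupancy=float(occupancy),
                coefficients=coefficients,
            )
        )
    return MolecularOrbitalSet(descriptions=descriptions, orbitals=orbitals)
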