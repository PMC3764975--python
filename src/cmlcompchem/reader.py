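"""Tolerant calculation reader.

The reader scans a document for the structures it understands — geometry,
dictRef-tagged scalar properties, the molecular-orbital set, the embedded
input deck — and ignores everything else.  Unknown elements are counted
but never fatal, so documents written by future producers with richer
vocabularies still read correctly (forward compatibility by design).

A single document may hold a multi-step experiment with several
geometries and orbital sets; the reader reports the *last* of each in
document order (the converged/final result) and lists all occurrences in
an auxiliary index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .core import (
    CML_NS,
    CANONICAL_PREFIXES,
    CmlDocument,
    CmlNode,
    CmlStructureError,
    XSD_NS,
    find_by_dictref,
    resolve_qname_value,
)
from .deck import InputDeck, extract_input_deck
from .mo import MolecularOrbitalSet, read_molecular_orbitals
from .writer import Atom, Molecule

__all__ = ["CalculationResult", "read_calculation", "extract_geometry", "to_xyz"]

logger = logging.getLogger(__name__)

_KNOWN_CML_LOCALS = {
    "cml",
    "module",
    "molecule",
    "atomArray",
    "atom",
    "scalar",
    "array",
    "list",
    "metadataList",
    "metadata",
    "parameter",
    "parameterList",
    "propertyList",
    "property",
}

_URI_TO_CANONICAL = {uri: prefix for prefix, uri in CANONICAL_PREFIXES.items()}


@dataclass
class CalculationResult:
    """Everything the reader recovered from one document."""

    molecule: Molecule | None = None
    mo_set: MolecularOrbitalSet | None = None
    properties: dict[str, tuple] = field(default_factory=dict)
    input_deck: InputDeck = field(default_factory=InputDeck)
    unrecognized_count: int = 0
    geometry_count: int = 0
    mo_set_count: int = 0


def _molecule_from_node(node: CmlNode) -> Molecule:
    atoms: list[Atom] = []
    for sub in node.iter():
        if sub.local_name != "atom":
            continue
        element = sub.get("elementType")
        coords = {}
        for axis in ("x3", "y3", "z3"):
            raw = sub.get(axis)
            if raw is None:
                raise CmlStructureError(
                    f"atom {sub.get('id', '?')!r} is missing coordinate {axis}"
                )
            coords[axis] = float(raw)
        if not element:
            raise CmlStructureError(
                f"atom {sub.get('id', '?')!r} is missing an element symbol"
            )
        atoms.append(Atom(element=element, id=sub.get("id"), **coords))
    charge = node.get("formalCharge")
    mult = node.get("spinMultiplicity")
    return Molecule(
        atoms=atoms,
        formal_charge=int(charge) if charge is not None else None,
        spin_multiplicity=int(mult) if mult is not None else None,
    )


def extract_geometry(doc: CmlDocument, which: str = "first") -> Molecule | None:
    """Atoms of the first (or last) ``cml:molecule`` element, coordinates
    read from x3/y3/z3 in Angstrom; None when the document has none."""
    molecules = [n for n in doc.iter() if n.local_name == "molecule"]
    if not molecules:
        return None
    return _molecule_from_node(molecules[0] if which == "first" else molecules[-1])


def _canonical_ref(value: str, scope: dict[str, str]) -> str:
    uri, local = resolve_qname_value(value, scope)
    if uri in _URI_TO_CANONICAL:
        return f"{_URI_TO_CANONICAL[uri]}:{local}"
    return value


def read_calculation(doc: CmlDocument) -> CalculationResult:
    """Aggregate geometry, properties, orbitals and input deck from a
    document, counting (but never failing on) unrecognized elements."""
    result = CalculationResult()

    molecules = [n for n in doc.iter() if n.local_name == "molecule"]
    result.geometry_count = len(molecules)
    if molecules:
        result.molecule = _molecule_from_node(molecules[-1])

    result.mo_set = read_molecular_orbitals(doc, which="last")
    result.mo_set_count = len(find_by_dictref(doc, "compchem:molecularOrbitals"))
    result.input_deck = extract_input_deck(doc)

    # Scalars inside input-file modules are file lines; scalars inside MO
    # containers belong to the orbitals — neither is a document property.
    excluded: set[int] = set()
    for module in find_by_dictref(doc, "compchem:inputFile", local_element="module"):
        excluded.update(id(n) for n in module.iter())
    for container in find_by_dictref(doc, "compchem:molecularOrbitals"):
        excluded.update(id(n) for n in container.iter())

    def walk(node: CmlNode, scope: dict[str, str]) -> None:
        scope = {**scope, **node.ns_decls}
        prefix, local = (node.prefix, node.local_name)
        uri = scope.get(prefix) if prefix is not None else scope.get("")
        if not (uri == CML_NS and local in _KNOWN_CML_LOCALS):
            result.unrecognized_count += 1
        elif local == "scalar" and id(node) not in excluded:
            ref = node.get("dictRef")
            if ref is not None:
                dt = node.get("dataType", "xsd:string")
                dt_resolved = resolve_qname_value(dt, scope)
                value: object = node.text
                if dt_resolved in ((XSD_NS, "double"), (XSD_NS, "integer")):
                    try:
                        value = (
                            int(node.text)
                            if dt_resolved == (XSD_NS, "integer")
                            else float(node.text)
                        )
                    except ValueError:
                        logger.warning(
                            "scalar %s: cannot parse %r as %s; keeping string",
                            ref,
                            node.text,
                            dt,
                        )
                result.properties[_canonical_ref(ref, scope)] = (
                    value,
                    node.get("units"),
                    dt,
                )
        for child in node.children:
            walk(child, scope)

    walk(doc.root, {})
    return result


def to_xyz(molecule: Molecule, comment: str = "") -> str:
    """Render a molecule in the standard XYZ format (count line, comment
    line, then one ``symbol x y z`` line per atom, Angstrom)."""
    if "\n" in comment or "\r" in comment:
        raise CmlStructureError("XYZ comment must be a single line")
    lines = [str(len(molecule.atoms)), comment]
    for atom in molecule.atoms:
        lines.append(
            f"{atom.element:<2s} {atom.x3:15.8f} {atom.y3:15.8f} {atom.z3:15.8f}"
        )
    return "\n".join(lines) + "\n"
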