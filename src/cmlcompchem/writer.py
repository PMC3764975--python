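"""Strict CML CompChem writer.

The writer is deliberately restrictive: it is a session-based, append-only
builder through which it is *impossible* to produce a document the
convention validator would flag.  Concretely, an atom cannot be added
without both an element symbol and a full 3-D position, a numeric quantity
cannot be written without a units reference, and the cml / convention /
compchem namespaces are always declared at the root.  Looser needs (free
XML) are out of scope by design; the molecular-orbital and input-deck
modules use the small internal element API here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import (
    ANGSTROM,
    CANONICAL_PREFIXES,
    CmlDocument,
    CmlNode,
    CmlStructureError,
    Units,
    is_qname,
)

__all__ = ["Atom", "Molecule", "WriterSession", "WriterError", "begin_document"]

# Element symbols accepted for atoms (H–Og).
_ELEMENTS = set(
    """H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe
    Co Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn
    Sb Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W
    Re Os Ir Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf
    Es Fm Md No Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og""".split()
)

_COORD_FORMAT = "{:.10g}"  # 10 significant digits: chemical precision for Angstrom


class WriterError(CmlStructureError):
    """The requested write would violate the convention contract."""


def _finite(x) -> bool:
    try:
        return x == x and abs(float(x)) != float("inf")
    except (TypeError, ValueError):
        return False


@dataclass(frozen=True)
class Atom:
    """An atom with element symbol and Cartesian position in Angstrom.

    Both the symbol and all three coordinates are mandatory — there is no
    way to place a nameless or position-less atom.
    """

    element: str
    x3: float
    y3: float
    z3: float
    id: str | None = None

    def validate(self) -> None:
        if not self.element or self.element not in _ELEMENTS:
            raise WriterError(
                f"atom requires a known element symbol, got {self.element!r}"
            )
        for name in ("x3", "y3", "z3"):
            v = getattr(self, name)
            if v is None or not _finite(v):
                raise WriterError(
                    f"atom {self.element!r} requires finite coordinate {name}"
                )


@dataclass
class Molecule:
    """An ordered list of atoms with optional charge and spin multiplicity."""

    atoms: list[Atom] = field(default_factory=list)
    formal_charge: int | None = None
    spin_multiplicity: int | None = None

    def validate(self) -> None:
        if not self.atoms:
            raise WriterError("molecule requires at least one atom")
        for atom in self.atoms:
            atom.validate()
        if self.spin_multiplicity is not None and self.spin_multiplicity < 1:
            raise WriterError("spin multiplicity must be a positive integer")
        ids = [a.id for a in self.atoms if a.id is not None]
        if len(ids) != len(set(ids)):
            raise WriterError("caller-supplied atom ids must be unique")


def _require_qname(value: str, what: str) -> str:
    if not is_qname(value):
        raise WriterError(f"{what} must be a prefixed QName, got {value!r}")
    return value


class WriterSession:
    """Append-only construction of one CML CompChem document.

    Usage mirrors a streaming writer: open modules, add content, close
    modules, :meth:`finish`.  A finished session refuses further writes.
    """

    def __init__(self, title: str | None = None, convention: str = "convention:compchem"):
        root = CmlNode(qname="cml:cml")
        root.ns_decls = dict(CANONICAL_PREFIXES)
        root.attributes["convention"] = _require_qname(convention, "convention")
        if title:
            root.attributes["title"] = title
        self._doc = CmlDocument(root=root)
        self._stack: list[CmlNode] = [root]
        self._finished = False
        self._atom_counter = 0

    # -- internal element API (used by the MO and input-deck modules) ------

    def _check_open(self) -> None:
        if self._finished:
            raise WriterError("session is finished; no further writes allowed")

    @property
    def _cursor(self) -> CmlNode:
        return self._stack[-1]

    def _push(self, node: CmlNode) -> CmlNode:
        self._check_open()
        self._cursor.append(node)
        self._stack.append(node)
        return node

    def _pop(self) -> None:
        self._check_open()
        if len(self._stack) == 1:
            raise WriterError("no open module to close")
        self._stack.pop()

    def _add_leaf(self, node: CmlNode) -> CmlNode:
        self._check_open()
        self._cursor.append(node)
        return node

    # -- public interface ---------------------------------------------------

    def open_module(self, dictref: str, title: str | None = None) -> None:
        node = CmlNode(qname="cml:module")
        node.attributes["dictRef"] = _require_qname(dictref, "module dictRef")
        if title is not None:
            node.attributes["title"] = title
        self._push(node)

    def close_module(self) -> None:
        if self._cursor.local_name != "module":
            raise WriterError(
                f"close_module: innermost open element is cml:{self._cursor.local_name}"
            )
        self._pop()

    def add_molecule(self, molecule: Molecule) -> None:
        self._check_open()
        molecule.validate()
        mol = CmlNode(qname="cml:molecule")
        if molecule.formal_charge is not None:
            mol.attributes["formalCharge"] = str(molecule.formal_charge)
        if molecule.spin_multiplicity is not None:
            mol.attributes["spinMultiplicity"] = str(molecule.spin_multiplicity)
        array = CmlNode(qname="cml:atomArray")
        mol.append(array)
        for atom in molecule.atoms:
            self._atom_counter += 1
            node = CmlNode(qname="cml:atom")
            node.attributes["id"] = atom.id or f"a{self._atom_counter}"
            node.attributes["elementType"] = atom.element
            node.attributes["x3"] = _COORD_FORMAT.format(float(atom.x3))
            node.attributes["y3"] = _COORD_FORMAT.format(float(atom.y3))
            node.attributes["z3"] = _COORD_FORMAT.format(float(atom.z3))
            array.append(node)
        self._cursor.append(mol)

    def add_scalar(
        self,
        dictref: str,
        value,
        units: Units | None = None,
        data_type: str | None = None,
    ) -> None:
        """Add a ``cml:scalar``.

        Numeric values *must* carry a units reference (use ``units:none``
        for dimensionless quantities); string values must not carry units
        of any type other than *none*.
        """
        self._check_open()
        _require_qname(dictref, "scalar dictRef")
        if data_type is None:
            if isinstance(value, bool):
                raise WriterError("boolean scalars are not part of the convention")
            data_type = (
                "xsd:integer"
                if isinstance(value, int)
                else "xsd:double"
                if isinstance(value, float)
                else "xsd:string"
            )
        if data_type not in ("xsd:double", "xsd:integer", "xsd:string"):
            raise WriterError(f"unsupported dataType {data_type!r}")
        numeric = data_type in ("xsd:double", "xsd:integer")
        if numeric:
            if units is None:
                raise WriterError(
                    f"numeric scalar {dictref!r} requires units "
                    "(use units:none for dimensionless values)"
                )
            if not _finite(value):
                raise WriterError(f"numeric scalar {dictref!r} must be finite")
        elif units is not None and units.unit_type != "none":
            raise WriterError(
                f"string scalar {dictref!r} cannot carry {units.unit_type} units"
            )
        node = CmlNode(qname="cml:scalar")
        node.attributes["dictRef"] = dictref
        node.attributes["dataType"] = data_type
        if units is not None:
            node.attributes["units"] = units.units_ref
        if data_type == "xsd:double" and not isinstance(value, str):
            node.text = repr(float(value))  # shortest lexical form round-tripping the double
        else:
            node.text = str(value)
        self._add_leaf(node)

    def add_metadata(self, name: str, content: str) -> None:
        """Add a ``cml:metadata`` entry, creating or reusing a metadataList
        under the current element."""
        self._check_open()
        _require_qname(name, "metadata name")
        mlist = None
        for child in self._cursor.children:
            if child.local_name == "metadataList":
                mlist = child
                break
        if mlist is None:
            mlist = CmlNode(qname="cml:metadataList")
            self._cursor.append(mlist)
        entry = CmlNode(qname="cml:metadata")
        entry.attributes["name"] = name
        entry.attributes["content"] = content
        mlist.append(entry)

    def finish(self) -> CmlDocument:
        """Close the session and return the (now immutable) document."""
        self._check_open()
        if len(self._stack) > 1:
            open_refs = [n.get("dictRef", n.qname) for n in self._stack[1:]]
            raise WriterError(f"unclosed modules at finish: {open_refs}")
        self._finished = True
        return self._doc


def begin_document(title: str | None = None) -> WriterSession:
    """Start a new writer session whose root declares the cml, convention,
    compchem (and units, xsd) namespaces."""
    return WriterSession(title=title)


def geometry_units() -> Units:
    """Units reference used for Cartesian coordinates."""
    return ANGSTROM
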