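"""Generic CML document model.

CML (Chemical Markup Language) documents are ordinary namespaced XML, but
the CompChem convention layers two requirements on top of plain XML
processing that general-purpose tools do not give us for free:

* the text of ``cml:scalar`` elements carries data (e.g. one verbatim line
  of a simulation input file) and must survive parse/serialize byte-exactly,
  while inter-element indentation elsewhere is meaningless;
* documents are compared *semantically* — namespace prefixes, attribute
  order and indentation are presentation, element order and text are data —
  so that canonicalization or pretty-printing never changes meaning.

This module provides the tree (:class:`CmlNode` / :class:`CmlDocument`),
parse and serialize, semantic equality, dictRef-based lookup, and a
lossless JSON mapping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from lxml import etree

__all__ = [
    "CML_NS",
    "CONVENTION_NS",
    "COMPCHEM_NS",
    "UNITS_NS",
    "XSD_NS",
    "CANONICAL_PREFIXES",
    "CmlError",
    "CmlParseError",
    "CmlNamespaceError",
    "CmlStructureError",
    "CmlNode",
    "CmlDocument",
    "Units",
    "parse_document",
    "serialize_document",
    "semantically_equal",
    "find_modules_by_dictref",
    "find_by_dictref",
    "cml_to_json",
    "json_to_cml",
]

CML_NS = "http://www.xml-cml.org/schema"
CONVENTION_NS = "http://www.xml-cml.org/convention/"
COMPCHEM_NS = "http://www.xml-cml.org/dictionary/compchem/"
UNITS_NS = "http://www.xml-cml.org/units/"
XSD_NS = "http://www.w3.org/2001/XMLSchema"

#: Prefixes bound on output; arbitrary prefixes are accepted on input.
CANONICAL_PREFIXES = {
    "cml": CML_NS,
    "convention": CONVENTION_NS,
    "compchem": COMPCHEM_NS,
    "units": UNITS_NS,
    "xsd": XSD_NS,
}

# Attributes whose values are QNames and therefore compared by resolved
# namespace URI rather than by prefix spelling.
_QNAME_VALUED_ATTRS = {"dictRef", "units", "name", "convention", "dataType"}


class CmlError(Exception):
    """Base class for errors raised by this package."""


class CmlParseError(CmlError):
    """Malformed XML, with line/column where available."""


class CmlNamespaceError(CmlError):
    """A prefix is used but not bound to a namespace URI."""


class CmlStructureError(CmlError):
    """Input does not follow the expected document structure."""


def split_qname(qname: str) -> tuple[str | None, str]:
    """Split ``prefix:local`` into (prefix, local); prefix is None if absent."""
    if ":" in qname:
        prefix, _, local = qname.partition(":")
        if not prefix or not local or ":" in local:
            raise CmlStructureError(f"malformed QName: {qname!r}")
        return prefix, local
    return None, qname


def is_qname(s: str) -> bool:
    """True when *s* is a prefixed QName: exactly one colon, both parts nonempty."""
    parts = s.split(":")
    return len(parts) == 2 and all(p and not p.isspace() for p in parts)


@dataclass
class CmlNode:
    """One element: qualified name, ordered attributes, text, ordered children.

    ``ns_decls`` holds the prefix → URI bindings *declared on this node*
    (the empty-string prefix is the default namespace).  Bindings inherit
    downward, so resolution walks the ancestor chain; :meth:`CmlDocument.
    scope_of` or a carried-down scope map is used where a parent chain is
    not available.
    """

    qname: str
    attributes: dict[str, str] = field(default_factory=dict)
    text: str = ""
    children: list["CmlNode"] = field(default_factory=list)
    ns_decls: dict[str, str] = field(default_factory=dict)

    @property
    def prefix(self) -> str | None:
        return split_qname(self.qname)[0]

    @property
    def local_name(self) -> str:
        return split_qname(self.qname)[1]

    def get(self, attr: str, default: str | None = None) -> str | None:
        return self.attributes.get(attr, default)

    def append(self, child: "CmlNode") -> "CmlNode":
        self.children.append(child)
        return child

    def iter(self):
        """Depth-first pre-order iteration over this node and descendants."""
        yield self
        for child in self.children:
            yield from child.iter()


@dataclass
class CmlDocument:
    """A parsed or constructed document: a root node plus root declarations."""

    root: CmlNode

    @property
    def declared_namespaces(self) -> dict[str, str]:
        return dict(self.root.ns_decls)

    def iter(self):
        return self.root.iter()


@dataclass(frozen=True)
class Units:
    """A units-dictionary reference plus the coarse unit type it belongs to.

    ``units_ref`` must be a QName (e.g. ``units:hartree``); ``unit_type``
    is one of energy / length / none / other.  A *none* unit type is how
    dimensionless numeric quantities (occupancies, counts) still satisfy
    the everything-numeric-has-units rule.
    """

    units_ref: str
    unit_type: str = "other"

    _ALLOWED_TYPES = ("energy", "length", "none", "other")

    def __post_init__(self):
        if not is_qname(self.units_ref):
            raise CmlStructureError(
                f"units reference is not a QName: {self.units_ref!r}"
            )
        if self.unit_type not in self._ALLOWED_TYPES:
            raise CmlStructureError(f"unknown unit type: {self.unit_type!r}")


HARTREE = Units("units:hartree", "energy")
ANGSTROM = Units("units:angstrom", "length")
DIMENSIONLESS = Units("units:none", "none")


# ---------------------------------------------------------------------------
# Parsing


def _from_lxml(elem, parent_scope: dict[str, str]) -> CmlNode:
    nsmap = {("" if k is None else k): v for k, v in elem.nsmap.items()}
    decls = {p: u for p, u in nsmap.items() if parent_scope.get(p) != u}

    # lxml uses Clark notation; recover a prefixed qname from the scope.
    def to_qname(clark: str, for_attr: bool) -> str:
        if clark.startswith("{"):
            uri, _, local = clark[1:].partition("}")
            if uri == "http://www.w3.org/XML/1998/namespace":
                return f"xml:{local}"
            for p, u in nsmap.items():
                if u == uri and (p or not for_attr):
                    return f"{p}:{local}" if p else local
            raise CmlNamespaceError(f"no prefix in scope for namespace {uri}")
        return clark

    node = CmlNode(qname=to_qname(elem.tag, False), ns_decls=decls)
    for k, v in elem.attrib.items():
        node.attributes[to_qname(k, True)] = v

    n_children = len(elem)
    texts = []
    if elem.text:
        texts.append(elem.text)
    for child in elem:
        node.children.append(_from_lxml(child, nsmap))
        if child.tail:
            texts.append(child.tail)
    if n_children == 0:
        node.text = elem.text or ""
    else:
        # Inter-element whitespace is indentation, not data; anything else
        # is mixed content, which the CompChem formats do not use — keep it
        # concatenated so no data is silently dropped.
        node.text = "".join(t for t in texts if t.strip())
    return node


def parse_document(raw: bytes | str) -> CmlDocument:
    """Parse XML bytes (or text) into a :class:`CmlDocument`.

    Leaf-element text is preserved byte-exactly; whitespace-only text
    between child elements is treated as indentation and dropped.
    """
    if isinstance(raw, str):
        raw = raw.encode("utf-8")
    try:
        tree = etree.fromstring(raw)
    except etree.XMLSyntaxError as exc:
        raise CmlParseError(str(exc)) from exc
    return CmlDocument(root=_from_lxml(tree, {}))


# ---------------------------------------------------------------------------
# Serialization


def _escape_text(s: str) -> str:
    return s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")


def _escape_attr(s: str) -> str:
    return (
        _escape_text(s)
        .replace('"', "&quot;")
        .replace("\t", "&#9;")
        .replace("\n", "&#10;")
        .replace("\r", "&#13;")
    )


def _check_resolvable(node: CmlNode, scope: dict[str, str]) -> None:
    for q in (node.qname, *node.attributes):
        prefix, _ = split_qname(q)
        if prefix is not None and prefix != "xml" and prefix not in scope:
            raise CmlNamespaceError(
                f"prefix {prefix!r} on {q!r} is not bound to a namespace"
            )


def _serialize_node(
    node: CmlNode, scope: dict[str, str], indent: int, pretty: bool, out: list[str]
) -> None:
    scope = {**scope, **node.ns_decls}
    _check_resolvable(node, scope)
    attrs = []
    for prefix, uri in node.ns_decls.items():
        name = f"xmlns:{prefix}" if prefix else "xmlns"
        attrs.append(f' {name}="{_escape_attr(uri)}"')
    for k, v in node.attributes.items():
        attrs.append(f' {k}="{_escape_attr(v)}"')
    open_tag = f"<{node.qname}{''.join(attrs)}"
    pad = "  " * indent if pretty else ""
    if not node.children and not node.text:
        out.append(f"{pad}{open_tag}/>")
        return
    if not node.children:
        # Text-carrying element: never insert whitespace around the text.
        out.append(f"{pad}{open_tag}>{_escape_text(node.text)}</{node.qname}>")
        return
    out.append(f"{pad}{open_tag}>")
    if node.text:
        out.append(_escape_text(node.text))
    for child in node.children:
        _serialize_node(child, scope, indent + 1, pretty, out)
    out.append(f"{pad}</{node.qname}>")


def serialize_document(doc: CmlDocument, pretty: bool = True) -> bytes:
    """Serialize to UTF-8 XML.

    With ``pretty`` on, indentation is inserted only between child elements
    of text-free elements, so element text — in particular ``cml:scalar``
    content — is emitted byte-exactly either way.
    """
    out: list[str] = []
    _serialize_node(doc.root, {}, 0, pretty, out)
    joiner = "\n" if pretty else ""
    body = joiner.join(out)
    return f'<?xml version="1.0" encoding="UTF-8"?>\n{body}\n'.encode("utf-8")


# ---------------------------------------------------------------------------
# Semantic comparison and dictRef lookup


def resolve_qname_value(
    value: str, scope: dict[str, str]
) -> tuple[str | None, str]:
    """Resolve a QName-valued string to (namespace URI, local); URI is None
    when the value has no prefix or the prefix is unbound (literal compare)."""
    prefix, local = split_qname(value) if ":" in value else (None, value)
    if prefix is None:
        return None, value
    uri = CANONICAL_PREFIXES.get(prefix) if prefix not in scope else scope[prefix]
    if uri is None:
        return None, value
    return uri, local


def _resolved_name(qname: str, scope: dict[str, str], default_applies: bool):
    prefix, local = split_qname(qname)
    if prefix is None:
        uri = scope.get("") if default_applies else None
        return (uri, local)
    if prefix == "xml":
        return ("http://www.w3.org/XML/1998/namespace", local)
    uri = scope.get(prefix)
    if uri is None:
        raise CmlNamespaceError(f"unbound prefix in {qname!r}")
    return (uri, local)


def _semantic_key(node: CmlNode, scope: dict[str, str]):
    scope = {**scope, **node.ns_decls}
    name = _resolved_name(node.qname, scope, default_applies=True)
    attrs = {}
    for k, v in node.attributes.items():
        rk = _resolved_name(k, scope, default_applies=False)
        if rk[0] is None and rk[1] in _QNAME_VALUED_ATTRS and is_qname(v):
            v = resolve_qname_value(v, scope)
        attrs[rk] = v
    children = tuple(_semantic_key(c, scope) for c in node.children)
    return (name, tuple(sorted(attrs.items(), key=repr)), node.text, children)


def semantically_equal(a: CmlDocument, b: CmlDocument) -> bool:
    """Equality up to presentation: prefix spellings and attribute order are
    ignored (URIs compared); element order and element text are exact."""
    return _semantic_key(a.root, {}) == _semantic_key(b.root, {})


def find_by_dictref(
    doc: CmlDocument,
    dictref: str,
    local_element: str | None = None,
) -> list[CmlNode]:
    """All elements whose ``dictRef`` resolves to *dictref*, in document order.

    ``local_element`` restricts matches to a given CML local element name
    (e.g. ``module``, ``list``).  dictRef values are compared by resolved
    namespace URI + local name; an unbound prefix falls back to literal
    comparison.
    """
    want = resolve_qname_value(dictref, CANONICAL_PREFIXES)
    found: list[CmlNode] = []

    def walk(node: CmlNode, scope: dict[str, str]) -> None:
        scope = {**scope, **node.ns_decls}
        if local_element is None or node.local_name == local_element:
            ref = node.get("dictRef")
            if ref is not None and resolve_qname_value(ref, scope) == want:
                found.append(node)
        for child in node.children:
            walk(child, scope)

    walk(doc.root, {})
    return found


def find_modules_by_dictref(doc: CmlDocument, dictref: str) -> list[CmlNode]:
    """All ``cml:module`` elements whose dictRef matches, in document order."""
    return find_by_dictref(doc, dictref, local_element="module")


# ---------------------------------------------------------------------------
# JSON bridge
#
# The mapping keeps everything semantic equality looks at: element name,
# declared bindings, ordered attributes, text, ordered children.  Attributes
# are a list of [name, value] pairs so order survives any JSON library.


def _node_to_obj(node: CmlNode) -> dict:
    obj: dict = {"name": node.qname}
    if node.ns_decls:
        obj["xmlns"] = dict(node.ns_decls)
    if node.attributes:
        obj["attributes"] = [[k, v] for k, v in node.attributes.items()]
    if node.text:
        obj["text"] = node.text
    if node.children:
        obj["children"] = [_node_to_obj(c) for c in node.children]
    return obj


_JSON_KEYS = {"name", "xmlns", "attributes", "text", "children"}


def _obj_to_node(obj) -> CmlNode:
    if not isinstance(obj, dict) or "name" not in obj:
        raise CmlStructureError("JSON element must be an object with a 'name' key")
    extra = set(obj) - _JSON_KEYS
    if extra:
        raise CmlStructureError(f"unexpected JSON keys: {sorted(extra)}")
    node = CmlNode(qname=obj["name"])
    node.ns_decls = dict(obj.get("xmlns", {}))
    attrs = obj.get("attributes", [])
    if not isinstance(attrs, list):
        raise CmlStructureError("'attributes' must be a list of [name, value] pairs")
    for pair in attrs:
        if not (isinstance(pair, list) and len(pair) == 2):
            raise CmlStructureError("attribute entries must be [name, value] pairs")
        node.attributes[pair[0]] = pair[1]
    node.text = obj.get("text", "")
    node.children = [_obj_to_node(c) for c in obj.get("children", [])]
    return node


def cml_to_json(doc: CmlDocument, indent: int | None = 2) -> str:
    """Lossless JSON rendering of a document (see :func:`json_to_cml`)."""
    return json.dumps(_node_to_obj(doc.root), indent=indent)


def json_to_cml(text: str) -> CmlDocument:
    """Inverse of :func:`cml_to_json`; raises :class:`CmlStructureError`
    for JSON not produced by that mapping."""
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise CmlStructureError(f"invalid JSON: {exc}") from exc
    return CmlDocument(root=_obj_to_node(obj))
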