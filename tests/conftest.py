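"""Shared fixtures and document-perturbation helpers.

The perturbations model what third-party XML tooling legitimately does to
a document without changing its meaning: reindentation, canonicalization
(which also reorders attributes), and rebinding namespace prefixes.
"""

from __future__ import annotations

import copy

import pytest
from lxml import etree

from cmlcompchem.core import CmlDocument, parse_document, serialize_document
from cmlcompchem.fixtures import FixtureSpec, generate_calculation_document

CORPUS_SEEDS = tuple(range(12))

_QNAME_ATTRS = {"dictRef", "units", "name", "convention", "dataType"}


@pytest.fixture(scope="session")
def calc_docs() -> dict[int, CmlDocument]:
    """Read-only corpus of synthetic calculation documents; tests that
    mutate must deepcopy."""
    return {
        seed: generate_calculation_document(FixtureSpec(seed=seed))
        for seed in CORPUS_SEEDS
    }


def reindent(xml: bytes, space: str = "    ") -> bytes:
    """Pretty-print with a different indentation style."""
    tree = etree.fromstring(xml)
    etree.indent(tree, space=space)
    return etree.tostring(tree, xml_declaration=True, encoding="UTF-8")


def canonicalize(xml: bytes) -> bytes:
    """Exclusive-prefix-free C14N: reorders attributes, strips the
    declaration, normalizes self-closing tags."""
    return etree.tostring(etree.fromstring(xml), method="c14n")


def rename_prefixes(doc: CmlDocument, mapping: dict[str, str]) -> CmlDocument:
    """A deep copy of *doc* with namespace prefixes rebound per *mapping*
    (QName-valued attribute values follow)."""
    doc = copy.deepcopy(doc)

    def fix(qname: str) -> str:
        if ":" in qname:
            prefix, _, local = qname.partition(":")
            return f"{mapping.get(prefix, prefix)}:{local}"
        return qname

    def walk(node):
        node.qname = fix(node.qname)
        node.ns_decls = {mapping.get(p, p): u for p, u in node.ns_decls.items()}
        new_attrs = {}
        for key, value in node.attributes.items():
            if key.rpartition(":")[2] in _QNAME_ATTRS and ":" in value:
                value = fix(value)
            new_attrs[fix(key)] = value
        node.attributes = new_attrs
        for child in node.children:
            walk(child)

    walk(doc.root)
    return doc


PREFIX_SWAP = {"cml": "c", "compchem": "cc", "units": "u", "convention": "conv"}


def perturbations(doc: CmlDocument):
    """Yield (label, document) pairs for every meaning-preserving
    transformation of *doc*."""
    xml = serialize_document(doc)
    yield "reindent", parse_document(reindent(xml))
    yield "c14n", parse_document(canonicalize(xml))
    yield "compact", parse_document(serialize_document(doc, pretty=False))
    renamed = rename_prefixes(doc, PREFIX_SWAP)
    yield "prefix-rename", parse_document(serialize_document(renamed))
    yield "rename+c14n", parse_document(canonicalize(serialize_document(renamed)))
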