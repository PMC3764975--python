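"""Byte-faithful embedding of ASCII input files in CML documents.

Simulation codes conventionally echo their input back into the output for
provenance.  Here each input file becomes a ``cml:module`` with dictRef
``compchem:inputFile`` (grouped under a ``compchem:inputFileList`` module),
a metadataList carrying the file name, and one ``cml:scalar`` of dataType
xsd:string per line, in document order.  Line-ending characters are
stripped; every other byte — tabs, runs of spaces, leading and trailing
whitespace, empty lines (empty scalar elements) — is preserved exactly, so
the original file can be reconstructed even after the XML has been
canonicalized or pretty-printed.  Only ASCII text is in scope.

Two writing interfaces are provided: a whole-file one
(:func:`dump_input_deck`) and a five-call streaming one
(:func:`start_input_deck_list` … :func:`end_input_deck_list`) for
applications that never hold a complete file, e.g. data read from
standard input.  Extraction likewise comes in a DOM flavour
(:func:`extract_input_deck`) and a constant-memory streaming flavour
(:func:`extract_input_deck_streaming`).
"""

from __future__ import annotations

import io
import logging
import xml.parsers.expat
from dataclasses import dataclass, field
from pathlib import Path

from .core import (
    CML_NS,
    COMPCHEM_NS,
    CmlDocument,
    CmlNode,
    CmlParseError,
    CmlStructureError,
    XSD_NS,
    find_by_dictref,
    resolve_qname_value,
)
from .writer import WriterError, WriterSession

__all__ = [
    "InputFile",
    "InputDeck",
    "dump_input_deck",
    "start_input_deck_list",
    "start_input_deck_file",
    "add_input_deck_line",
    "end_input_deck_file",
    "end_input_deck_list",
    "extract_input_deck",
    "extract_input_deck_streaming",
    "reconstruct_file",
]

logger = logging.getLogger(__name__)

#: Extension metadata name recording that the original file lacked a final
#: newline (the line-stripping representation cannot express this itself).
NO_FINAL_NEWLINE_META = "compchem:x-noFinalNewline"


def _check_line(line: str) -> str:
    if "\r" in line or "\n" in line:
        raise CmlStructureError("input-deck line must not contain CR or LF")
    for pos, ch in enumerate(line):
        if ord(ch) > 127:
            raise CmlStructureError(
                f"non-ASCII character {ch!r} at column {pos} in input-deck line"
            )
    return line


@dataclass
class InputFile:
    """One embedded input file: a name (optional — stdin has none) and its
    lines with line endings stripped."""

    file_name: str | None = None
    lines: list[str] = field(default_factory=list)
    title: str | None = None
    had_final_newline: bool = True

    def validate(self) -> None:
        for line in self.lines:
            _check_line(line)


@dataclass
class InputDeck:
    """An ordered collection of input files."""

    files: list[InputFile] = field(default_factory=list)
    title: str | None = None


# ---------------------------------------------------------------------------
# Writing


def _scalar_line(line: str) -> CmlNode:
    node = CmlNode(qname="cml:scalar")
    node.attributes["dataType"] = "xsd:string"
    # Defends embedded whitespace against generic XML tooling.
    node.attributes["xml:space"] = "preserve"
    node.text = line
    return node


def start_input_deck_list(session: WriterSession, title: str | None = None) -> None:
    state = getattr(session, "_deck_state", None)
    if state is not None:
        raise WriterError("input-deck list already open")
    session.open_module("compchem:inputFileList", title=title)
    session._deck_state = "list"


def start_input_deck_file(
    session: WriterSession, name: str | None = None, title: str | None = None
) -> None:
    if getattr(session, "_deck_state", None) != "list":
        raise WriterError("start_input_deck_file outside an open input-deck list")
    session.open_module("compchem:inputFile", title=title)
    if name is not None:
        session.add_metadata("compchem:inputFileName", name)
    session._deck_state = "file"


def add_input_deck_line(session: WriterSession, line: str) -> None:
    if getattr(session, "_deck_state", None) != "file":
        raise WriterError("add_input_deck_line outside an open input-deck file")
    session._add_leaf(_scalar_line(_check_line(line)))


def end_input_deck_file(session: WriterSession) -> None:
    if getattr(session, "_deck_state", None) != "file":
        raise WriterError("end_input_deck_file without an open file")
    session.close_module()
    session._deck_state = "list"


def end_input_deck_list(session: WriterSession) -> None:
    if getattr(session, "_deck_state", None) != "list":
        raise WriterError("end_input_deck_list without an open list (or file still open)")
    session.close_module()
    session._deck_state = None


def _split_ascii(data: bytes, where: str) -> tuple[list[str], bool]:
    for pos, byte in enumerate(data):
        if byte > 127:
            raise CmlStructureError(
                f"non-ASCII byte 0x{byte:02x} at offset {pos} in {where}"
            )
    text = data.decode("ascii")
    had_final_newline = text.endswith(("\n", "\r")) or not text
    lines = text.splitlines()
    return lines, had_final_newline


def dump_input_deck(session: WriterSession, paths: list[str | Path]) -> None:
    """Embed the named files wholesale (open, write, close per file)."""
    if not paths:
        logger.warning("dumping an input deck with zero files")
    start_input_deck_list(session)
    for path in paths:
        path = Path(path)
        try:
            data = path.read_bytes()
        except OSError as exc:
            raise CmlStructureError(f"cannot read input file {path}: {exc}") from exc
        lines, had_final_newline = _split_ascii(data, str(path))
        start_input_deck_file(session, name=path.name)
        if not had_final_newline:
            session.add_metadata(NO_FINAL_NEWLINE_META, "true")
        for line in lines:
            add_input_deck_line(session, line)
        end_input_deck_file(session)
    end_input_deck_list(session)


def write_input_deck(session: WriterSession, deck: InputDeck) -> None:
    """Embed an in-memory deck via the streaming interface."""
    start_input_deck_list(session, title=deck.title)
    for f in deck.files:
        f.validate()
        start_input_deck_file(session, name=f.file_name, title=f.title)
        if not f.had_final_newline:
            session.add_metadata(NO_FINAL_NEWLINE_META, "true")
        for line in f.lines:
            add_input_deck_line(session, line)
        end_input_deck_file(session)
    end_input_deck_list(session)


# ---------------------------------------------------------------------------
# DOM extraction


def _scope_map(doc: CmlDocument, target: CmlNode) -> dict[str, str]:
    # In-scope bindings at *target*, found by a walk from the root.
    def walk(node: CmlNode, scope: dict[str, str]):
        scope = {**scope, **node.ns_decls}
        if node is target:
            return scope
        for child in node.children:
            got = walk(child, scope)
            if got is not None:
                return got
        return None

    return walk(doc.root, {}) or {}


def extract_input_deck(doc: CmlDocument) -> InputDeck:
    """Recover every embedded input file, in document order.

    Robust to reindentation and canonicalization: line text comes from the
    scalar elements byte-exactly; non-scalar intruders are ignored (a
    scalar with a non-string dataType draws a warning but its text is
    still taken).
    """
    deck = InputDeck()
    lists = find_by_dictref(doc, "compchem:inputFileList", local_element="module")
    if lists:
        deck.title = lists[0].get("title")
    for module in find_by_dictref(doc, "compchem:inputFile", local_element="module"):
        f = InputFile(title=module.get("title"))
        scope = _scope_map(doc, module)
        for child in module.children:
            if child.local_name == "scalar":
                dt = child.get("dataType")
                if dt is not None and resolve_qname_value(dt, scope) not in (
                    (XSD_NS, "string"),
                    (None, dt),
                ):
                    logger.warning(
                        "input-deck scalar with dataType %r; taking text anyway", dt
                    )
                f.lines.append(child.text)
            elif child.local_name == "metadataList":
                for meta in child.children:
                    if meta.local_name != "metadata":
                        continue
                    name = meta.get("name", "")
                    resolved = resolve_qname_value(name, scope)
                    if resolved == (COMPCHEM_NS, "inputFileName"):
                        f.file_name = meta.get("content")
                    elif resolved == (COMPCHEM_NS, "x-noFinalNewline"):
                        f.had_final_newline = meta.get("content") != "true"
        deck.files.append(f)
    return deck


# ---------------------------------------------------------------------------
# Streaming extraction (expat; memory bounded by one file's content)


class _StreamHandler:
    def __init__(self):
        self.deck = InputDeck()
        self.ns_stack: dict[str, list[str]] = {}
        self.depth = 0
        self.file: InputFile | None = None
        self.file_depth = -1
        self.in_metadata_list = False
        self.scalar_buf: list[str] | None = None

    def _resolve(self, value: str) -> tuple[str | None, str]:
        if ":" not in value:
            return (None, value)
        prefix, _, local = value.partition(":")
        stack = self.ns_stack.get(prefix)
        return (stack[-1], local) if stack else (None, value)

    def start_ns(self, prefix, uri):
        self.ns_stack.setdefault(prefix or "", []).append(uri)

    def end_ns(self, prefix):
        self.ns_stack.get(prefix or "", [None]).pop()

    def start(self, name, attrs):
        self.depth += 1
        uri, _, local = name.rpartition(" ")
        if uri == CML_NS and local == "module":
            ref = self._resolve(attrs.get("dictRef", ""))
            if ref == (COMPCHEM_NS, "inputFileList") and self.deck.title is None:
                self.deck.title = attrs.get("title")
            elif ref == (COMPCHEM_NS, "inputFile") and self.file is None:
                self.file = InputFile(title=attrs.get("title"))
                self.file_depth = self.depth
        elif self.file is not None and self.depth == self.file_depth + 1:
            if uri == CML_NS and local == "scalar":
                self.scalar_buf = []
            elif uri == CML_NS and local == "metadataList":
                self.in_metadata_list = True
        elif (
            self.in_metadata_list
            and self.depth == self.file_depth + 2
            and uri == CML_NS
            and local == "metadata"
        ):
            resolved = self._resolve(attrs.get("name", ""))
            if resolved == (COMPCHEM_NS, "inputFileName"):
                self.file.file_name = attrs.get("content")
            elif resolved == (COMPCHEM_NS, "x-noFinalNewline"):
                self.file.had_final_newline = attrs.get("content") != "true"

    def chars(self, data):
        if self.scalar_buf is not None:
            self.scalar_buf.append(data)

    def end(self, name):
        uri, _, local = name.rpartition(" ")
        if self.scalar_buf is not None and self.depth == self.file_depth + 1:
            if uri == CML_NS and local == "scalar":
                self.file.lines.append("".join(self.scalar_buf))
            self.scalar_buf = None
        elif self.in_metadata_list and self.depth == self.file_depth + 1:
            if uri == CML_NS and local == "metadataList":
                self.in_metadata_list = False
        elif self.file is not None and self.depth == self.file_depth:
            self.deck.files.append(self.file)
            self.file = None
            self.file_depth = -1
        self.depth -= 1


def extract_input_deck_streaming(source) -> InputDeck:
    """Streaming equivalent of :func:`extract_input_deck`.

    *source* is bytes or a binary file-like object; the document is never
    materialized, so memory use is bounded by the largest single embedded
    file, not by document size.  A malformed or truncated stream raises
    :class:`~cmlcompchem.core.CmlParseError` and no partial deck is
    returned.
    """
    if isinstance(source, (bytes, bytearray)):
        source = io.BytesIO(bytes(source))
    handler = _StreamHandler()
    parser = xml.parsers.expat.ParserCreate(namespace_separator=" ")
    parser.buffer_text = True
    parser.StartNamespaceDeclHandler = handler.start_ns
    parser.EndNamespaceDeclHandler = handler.end_ns
    parser.StartElementHandler = handler.start
    parser.EndElementHandler = handler.end
    parser.CharacterDataHandler = handler.chars
    try:
        while True:
            chunk = source.read(65536)
            if not chunk:
                parser.Parse(b"", True)
                break
            parser.Parse(chunk, False)
    except xml.parsers.expat.ExpatError as exc:
        raise CmlParseError(f"streaming parse failed: {exc}") from exc
    return handler.deck


def reconstruct_file(f: InputFile, line_ending: str = "\n") -> bytes:
    """Rebuild the file's bytes: each line followed by *line_ending*
    (``\\n`` or ``\\r\\n``); an empty file yields empty bytes."""
    if line_ending not in ("\n", "\r\n"):
        raise CmlStructureError(f"unsupported line ending {line_ending!r}")
    return "".join(line + line_ending for line in f.lines).encode("ascii")
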