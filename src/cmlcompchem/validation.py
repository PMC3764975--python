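"""Convention-level document validation.

Checks a CML document against the structural rules the CompChem formats in
this package define — not against the full CML XSD schema.  The rules,
with their must/should severities:

==============================  ========  =========================================
code                            severity  rule
==============================  ========  =========================================
units-missing                   error     every numeric scalar carries a units attr
dictref-unresolvable            error     every dictRef is a QName with a bound prefix
atom-incomplete                 error     every atom has elementType and x3/y3/z3
mo-*                            error     molecular-orbital constraints (see mo module)
inputfile-intruder              warning   inputFile modules hold only metadataList
                                          and string scalars
inputfile-name-missing          warning   inputFile modules name their file
non-ascii-line                  error     input-deck line text is ASCII
==============================  ========  =========================================

The strict writer cannot produce a document that fails any *error* rule;
the validator exists for documents from other producers and for
hand-edited files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import (
    CML_NS,
    COMPCHEM_NS,
    CmlDocument,
    CmlNode,
    CmlStructureError,
    XSD_NS,
    is_qname,
    resolve_qname_value,
    split_qname,
)

__all__ = ["ValidationIssue", "ValidationReport", "validate_document"]

_NUMERIC_TYPES = {(XSD_NS, "double"), (XSD_NS, "integer"), (XSD_NS, "float")}


@dataclass(frozen=True)
class ValidationIssue:
    """One finding: severity (error/warning), a stable short code, a path
    expression locating the offending node, and a human-readable message."""

    severity: str
    code: str
    location: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    @property
    def counts(self) -> dict[str, int]:
        return {"error": len(self.errors), "warning": len(self.warnings)}

    def ok(self, strict: bool = False) -> bool:
        return not self.errors and not (strict and self.warnings)

    def __str__(self) -> str:
        if not self.issues:
            return "valid: no issues"
        lines = [
            f"{i.severity.upper():7s} {i.code}: {i.message}\n        at {i.location}"
            for i in self.issues
        ]
        c = self.counts
        lines.append(f"{c['error']} error(s), {c['warning']} warning(s)")
        return "\n".join(lines)


def _resolved_element(node: CmlNode, scope: dict[str, str]):
    prefix = node.prefix
    uri = scope.get(prefix) if prefix is not None else scope.get("")
    return (uri, node.local_name)


def validate_document(doc: CmlDocument) -> ValidationReport:
    """Apply every convention rule; findings are returned, never raised."""
    report = ValidationReport()

    def add(severity, code, location, message):
        report.issues.append(ValidationIssue(severity, code, location, message))

    def walk(node: CmlNode, scope: dict[str, str], path: str, in_input_file: bool):
        scope = {**scope, **node.ns_decls}
        uri, local = _resolved_element(node, scope)
        is_cml = uri == CML_NS

        ref = node.get("dictRef")
        if ref is not None:
            prefix = split_qname(ref)[0] if is_qname(ref) else None
            if prefix is None or (prefix not in scope):
                add(
                    "error",
                    "dictref-unresolvable",
                    path,
                    f"dictRef {ref!r} is not a QName with an in-scope prefix",
                )

        if is_cml and local == "scalar":
            dt = node.get("dataType")
            if dt is not None and resolve_qname_value(dt, scope) in _NUMERIC_TYPES:
                if node.get("units") is None:
                    add(
                        "error",
                        "units-missing",
                        path,
                        f"numeric scalar ({dt}) without a units attribute",
                    )
            if in_input_file:
                bad = next((ch for ch in node.text if ord(ch) > 127), None)
                if bad is not None:
                    add(
                        "error",
                        "non-ascii-line",
                        path,
                        f"non-ASCII character {bad!r} in input-deck line",
                    )

        if is_cml and local == "atom":
            missing = [
                a
                for a in ("elementType", "x3", "y3", "z3")
                if not node.get(a)
            ]
            if missing:
                add(
                    "error",
                    "atom-incomplete",
                    path,
                    f"atom {node.get('id', '?')!r} missing {', '.join(missing)}",
                )
            else:
                for axis in ("x3", "y3", "z3"):
                    try:
                        float(node.attributes[axis])
                    except ValueError:
                        add(
                            "error",
                            "atom-incomplete",
                            path,
                            f"atom coordinate {axis}={node.attributes[axis]!r} "
                            "is not a number",
                        )

        is_input_file = (
            is_cml
            and local == "module"
            and ref is not None
            and resolve_qname_value(ref, scope) == (COMPCHEM_NS, "inputFile")
        )
        if is_input_file:
            has_name = False
            for i, child in enumerate(node.children, start=1):
                child_scope = {**scope, **child.ns_decls}
                curi, clocal = _resolved_element(child, child_scope)
                if curi == CML_NS and clocal == "metadataList":
                    for meta in child.children:
                        name = meta.get("name", "")
                        if resolve_qname_value(name, child_scope) == (
                            COMPCHEM_NS,
                            "inputFileName",
                        ):
                            has_name = True
                elif curi == CML_NS and clocal == "scalar":
                    dt = child.get("dataType")
                    if dt is not None and resolve_qname_value(dt, child_scope) != (
                        XSD_NS,
                        "string",
                    ):
                        add(
                            "warning",
                            "inputfile-intruder",
                            f"{path}/{child.qname}[{i}]",
                            f"input-file scalar with dataType {dt!r} "
                            "(expected xsd:string)",
                        )
                else:
                    add(
                        "warning",
                        "inputfile-intruder",
                        f"{path}/{child.qname}[{i}]",
                        f"unexpected {child.qname} inside an inputFile module",
                    )
            if not has_name:
                add(
                    "warning",
                    "inputfile-name-missing",
                    path,
                    "inputFile module has no compchem:inputFileName metadata",
                )

        # Positional child paths (1-based, per element name).
        counters: dict[str, int] = {}
        for child in node.children:
            counters[child.qname] = counters.get(child.qname, 0) + 1
            walk(
                child,
                scope,
                f"{path}/{child.qname}[{counters[child.qname]}]",
                in_input_file or is_input_file,
            )

    walk(doc.root, {}, f"/{doc.root.qname}", False)

    # Molecular-orbital constraints, per container.
    from .mo import read_molecular_orbitals, validate_mo_set

    try:
        mo_set = read_molecular_orbitals(doc)
    except CmlStructureError as exc:
        add("error", "mo-structure", "/", str(exc))
    else:
        if mo_set is not None:
            for issue in validate_mo_set(mo_set):
                add(issue.severity, issue.code, issue.location, issue.message)

    return report
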