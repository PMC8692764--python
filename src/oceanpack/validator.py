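"""Transferability and reusability-indicator checks for data packages.

Three families of checks, all producing located, coded issues:

* transferability — every resource file exists and matches its declared
  MD5 checksum, so a multi-file package survives transfer intact;
* cell conformance — each cell parses to its declared type, datetimes
  match their declared pattern, and numeric values respect inclusive
  min/max constraints (e.g. latitude in [-90, 90], which catches swapped
  latitude/longitude columns);
* annotation audit — each column carries its ontology triad (type, unit,
  device) and every referenced term resolves in the term graph.

Severity policy: broken files, bad cells and unknown terms are errors;
an incomplete annotation triad is a warning — real deposited packages
routinely lack device terms, which limits reuse but does not corrupt it.
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass, field as dc_field
from pathlib import Path

from .errors import HeaderMismatchError, MissingResourceError
from .ontology import TermGraph
from .package_model import (
    FieldSpec,
    PackageDescriptor,
    ParsedTable,
    TypedCellError,
    load_resource,
)

ISSUE_CODES = (
    "MISSING_FILE",
    "CHECKSUM_MISMATCH",
    "TYPE_ERROR",
    "FORMAT_ERROR",
    "CONSTRAINT_VIOLATION",
    "HEADER_MISMATCH",
    "MISSING_ANNOTATION",
    "UNKNOWN_TERM",
)


@dataclass(frozen=True, order=True)
class Issue:
    """One located validation finding.

    ``row`` is the 1-based data-row index (header excluded); ``row`` and
    ``column`` are set only for cell-scoped issues.
    """

    resource: str
    row: int | None
    column: str | None
    code: str
    severity: str
    detail: str = ""

    def __post_init__(self):
        assert self.code in ISSUE_CODES, self.code
        assert self.severity in ("error", "warning"), self.severity

    @property
    def sort_key(self):
        return (self.resource, self.row if self.row is not None else -1,
                self.column or "", self.code)


@dataclass
class ValidationReport:
    """All issues found for one package, in deterministic order."""

    package_name: str
    issues: list[Issue] = dc_field(default_factory=list)

    @property
    def counts(self) -> Counter:
        return Counter(i.code for i in self.issues)

    @property
    def passed(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def errors(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "error"]

    def warnings(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "warning"]

    def code_multiset(self) -> Counter:
        return self.counts

    def to_dict(self) -> dict:
        return {
            "package": self.package_name,
            "pass": self.passed,
            "counts": dict(sorted(self.counts.items())),
            "issues": [
                {"resource": i.resource, "row": i.row, "column": i.column,
                 "code": i.code, "severity": i.severity, "detail": i.detail}
                for i in self.issues
            ],
        }


def _md5_file(path: Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def verify_transferability(pkg: PackageDescriptor, base_dir) -> ValidationReport:
    """Check that every resource file exists and matches its MD5."""
    base = Path(base_dir)
    issues = []
    for res in pkg.resources:
        path = base / res.path
        if not path.is_file():
            issues.append(Issue(res.name, None, None, "MISSING_FILE", "error",
                                f"resource file not found: {res.path}"))
            continue
        try:
            digest = _md5_file(path)
        except OSError as exc:
            issues.append(Issue(res.name, None, None, "MISSING_FILE", "error",
                                f"resource file unreadable: {exc}"))
            continue
        if res.md5 is not None and digest != res.md5:
            issues.append(Issue(
                res.name, None, None, "CHECKSUM_MISMATCH", "error",
                f"declared md5 {res.md5}, computed {digest}",
            ))
    issues.sort(key=lambda i: i.sort_key)
    return ValidationReport(pkg.name, issues)


def validate_cells(table: ParsedTable, specs: list[FieldSpec]) -> list[Issue]:
    """Per-cell type/format/constraint checks; nulls generate no issues."""
    spec_names = [s.name for s in specs]
    if spec_names != table.columns:
        return [Issue(table.resource_name, None, None, "HEADER_MISMATCH", "error",
                      f"specs {spec_names} != table columns {table.columns}")]
    issues = []
    for row_idx, row in enumerate(table.rows, start=1):
        for cell, spec in zip(row, specs):
            if cell is None:
                continue
            if isinstance(cell, TypedCellError):
                code = "FORMAT_ERROR" if cell.kind == "format" else "TYPE_ERROR"
                issues.append(Issue(
                    table.resource_name, row_idx, spec.name, code, "error",
                    f"value {cell.raw!r} does not conform to declared "
                    f"{spec.declared_type}"
                    + (f" with format {spec.format!r}" if cell.kind == "format" else ""),
                ))
                continue
            if spec.constraints and isinstance(cell, (int, float)):
                lo = spec.constraints.get("minimum")
                hi = spec.constraints.get("maximum")
                # bounds are inclusive: exactly -90/90 passes
                if (lo is not None and cell < lo) or (hi is not None and cell > hi):
                    issues.append(Issue(
                        table.resource_name, row_idx, spec.name,
                        "CONSTRAINT_VIOLATION", "error",
                        f"value {cell} outside [{lo}, {hi}]",
                    ))
    return issues


def audit_annotations(pkg: PackageDescriptor, graph: TermGraph) -> list[Issue]:
    """Annotation-completeness and term-resolution audit.

    A field lacking its rdfType, a numeric field lacking its unit term,
    and a numeric field lacking its device term each yield one
    MISSING_ANNOTATION warning.  Any annotation whose CURIE is absent
    from the graph yields an UNKNOWN_TERM error.
    """
    issues = []
    for res in pkg.resources:
        for f in res.fields:
            numeric = f.declared_type in ("number", "integer")
            missing = []
            if f.rdf_type is None:
                missing.append("rdfType")
            if numeric and f.unit_rdf_type is None:
                missing.append("pm:unitRdfType")
            if numeric and f.measurement_source_rdf_type is None:
                missing.append("pm:measurementSourceRdfType")
            for key in missing:
                issues.append(Issue(
                    res.name, None, f.name, "MISSING_ANNOTATION", "warning",
                    f"field lacks {key} annotation",
                ))
            for key, term in (
                ("rdfType", f.rdf_type),
                ("pm:unitRdfType", f.unit_rdf_type),
                ("pm:measurementSourceRdfType", f.measurement_source_rdf_type),
            ):
                if term is not None and term.curie not in graph:
                    issues.append(Issue(
                        res.name, None, f.name, "UNKNOWN_TERM", "error",
                        f"{key} term {term.curie} not found in term graph",
                    ))
    return issues


def validate_package(
    pkg: PackageDescriptor, base_dir, graph: TermGraph | None = None
) -> ValidationReport:
    """Run every check family and merge into one ordered report.

    Validation reports rather than raises: unreadable resources and
    header mismatches become issues, so one broken file never hides
    findings in the others.
    """
    report = verify_transferability(pkg, base_dir)
    issues = list(report.issues)
    broken = {i.resource for i in issues if i.code == "MISSING_FILE"}
    for res in pkg.resources:
        if res.name in broken:
            continue
        try:
            table = load_resource(pkg, res.name, base_dir)
        except HeaderMismatchError as exc:
            issues.append(Issue(res.name, None, None, "HEADER_MISMATCH", "error",
                                str(exc)))
            continue
        except MissingResourceError as exc:
            issues.append(Issue(res.name, None, None, "MISSING_FILE", "error",
                                str(exc)))
            continue
        issues.extend(validate_cells(table, res.fields))
    if graph is not None:
        issues.extend(audit_annotations(pkg, graph))
    issues.sort(key=lambda i: i.sort_key)
    return ValidationReport(pkg.name, issues)
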