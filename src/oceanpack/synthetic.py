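"""Deterministic generators for test packages and study-like datasets.

Everything downstream — the validator, the harmonizer, the statistics —
is exercised against synthetic data whose ground truth is recorded in a
manifest at generation time, so every check has an exact oracle:

* :func:`generate_package` writes a complete on-disk data package
  (descriptor + TSV resources with correct checksums) and optionally
  injects known defects, each mapped to the exact issue the validator
  must report;
* :func:`generate_redfield_data` emulates open-ocean nutrient
  stoichiometry: phosphate = nitrate/16 + noise, with optional
  freshwater-like outliers (high nitrate, near-zero phosphate) tagged
  with freshwater ENVO context;
* :func:`generate_community_depth_data` emulates depth-structured
  microbial communities with per-taxon monotone (logistic-in-depth)
  abundance trends of known sign.

All randomness flows through one explicitly seeded generator; identical
(parameters, seed) yield byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .analysis import CommunityMatrix
from .package_model import (
    FieldSpec,
    OntologyTermRef,
    PackageDescriptor,
    ResourceSpec,
    curie_to_purl,
    save_descriptor,
)

DEFAULT_MIN_READS = 100_000

_T = OntologyTermRef


# ---------------------------------------------------------------------------
# error-injected packages

INJECTION_KINDS = (
    "corrupt_bytes", "delete_file", "type_error", "format_error",
    "constraint", "strip_annotation", "unknown_term",
)


@dataclass(frozen=True)
class Injection:
    """One deliberate defect to plant in a generated package."""

    kind: str
    resource: str = "samples"
    row: int | None = None        # 1-based data row for cell-scoped kinds
    field: str | None = None

    def __post_init__(self):
        if self.kind not in INJECTION_KINDS:
            raise ParameterError(f"unknown injection kind {self.kind!r}")


@dataclass
class PackageManifest:
    """Ground truth for one generated package."""

    seed: int
    name: str
    n_samples: int
    injections: list = dc_field(default_factory=list)
    expected_issues: list = dc_field(default_factory=list)
    # sample_id -> {"nitrate": value-or-None, "phosphate": value-or-None}
    sample_truth: dict = dc_field(default_factory=dict)

    def expected_issue_multiset(self) -> Counter:
        return Counter(
            (e["resource"], e["row"], e["column"], e["code"])
            for e in self.expected_issues
        )

    def to_json(self) -> str:
        out = asdict(self)
        out["injections"] = [asdict(i) if not isinstance(i, dict) else i
                             for i in self.injections]
        return json.dumps(out, indent=2) + "\n"


def _sample_fields() -> list[FieldSpec]:
    return [
        FieldSpec("sample_id", "string", rdf_type=_T("TEMP:0000010"),
                  searchable=True),
        FieldSpec("sample_accession", "string", rdf_type=_T("TEMP:0000010")),
        FieldSpec("collection_datetime", "datetime",
                  format="%Y-%m-%dT%H:%M:%SZ", rdf_type=_T("TEMP:0000012")),
        FieldSpec("latitude", "number",
                  constraints={"minimum": -90, "maximum": 90},
                  rdf_type=_T("PMO:00000076"), unit_rdf_type=_T("UO:0000185"),
                  measurement_source_rdf_type=_T("TEMP:0000013"),
                  searchable=True),
        FieldSpec("longitude", "number",
                  constraints={"minimum": -180, "maximum": 180},
                  rdf_type=_T("TEMP:0000011"), unit_rdf_type=_T("UO:0000185"),
                  measurement_source_rdf_type=_T("TEMP:0000013")),
        FieldSpec("biome", "string", rdf_type=_T("ENVO:00000428")),
        FieldSpec("env_feature", "string", rdf_type=_T("ENVO:00002297")),
        FieldSpec("env_material", "string", rdf_type=_T("ENVO:00010483")),
    ]


def _chemistry_fields() -> list[FieldSpec]:
    return [
        FieldSpec("sample_id", "string", rdf_type=_T("TEMP:0000010")),
        FieldSpec("depth", "number", rdf_type=_T("TEMP:0000023"),
                  unit_rdf_type=_T("UO:0000008"),
                  measurement_source_rdf_type=_T("TEMP:0000014")),
        FieldSpec("temperature", "number", rdf_type=_T("ENVO:09200014"),
                  unit_rdf_type=_T("UO:0000027"),
                  measurement_source_rdf_type=_T("TEMP:0000014")),
        FieldSpec("nitrate", "number", missing_values=["NA"],
                  rdf_type=_T("ENVO:3100022"), unit_rdf_type=_T("UO:0000064"),
                  measurement_source_rdf_type=_T("OBI:0400115"),
                  searchable=True),
        FieldSpec("phosphate", "number", missing_values=["NA"],
                  rdf_type=_T("TEMP:0000001"), unit_rdf_type=_T("UO:0000064"),
                  measurement_source_rdf_type=_T("OBI:0001057"),
                  searchable=True),
    ]


_MARINE_CONTEXT = ("ENVO:00000447", "ENVO:01001581", "ENVO:00002006")


def _render_rows(rows: list[dict], field_names: list[str]) -> str:
    lines = ["\t".join(field_names)]
    for r in rows:
        lines.append("\t".join(str(r[c]) for c in field_names))
    return "\n".join(lines) + "\n"


def generate_package(
    out_dir,
    n_samples: int = 20,
    injections: tuple[Injection, ...] = (),
    seed: int = 0,
    name: str | None = None,
) -> tuple[PackageDescriptor, PackageManifest]:
    """Write a two-resource nutrient package under ``out_dir``.

    Content-level defects (bad cells, out-of-range latitude, stripped or
    unknown annotations) are planted *before* checksums are computed, so
    only the intended issue fires; byte corruption and file deletion
    happen *after*, so they trip the transferability checks.  The
    returned manifest records the exact multiset of issues the validator
    must report.
    """
    if n_samples < 1:
        raise ParameterError("n_samples must be >= 1")
    injections = tuple(injections)
    kinds = Counter((i.kind, i.resource) for i in injections)
    if kinds[("delete_file", "samples")] and kinds[("corrupt_bytes", "samples")]:
        raise ParameterError("cannot corrupt a file that is also deleted")
    if kinds[("delete_file", "chemistry")] and kinds[("corrupt_bytes", "chemistry")]:
        raise ParameterError("cannot corrupt a file that is also deleted")

    rng = np.random.default_rng(seed)
    name = name or f"synthetic-nutrients-{seed}"
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    sample_rows, chem_rows, truth = [], [], {}
    for i in range(n_samples):
        sid = f"S{seed:04d}.{i:03d}"
        nitrate = float(rng.gamma(2.0, 8.0))
        phosphate = max(0.0, nitrate / 16.0 + rng.normal(0.0, 0.2))
        nitrate_null = rng.random() < 0.1
        phosphate_null = rng.random() < 0.1
        sample_rows.append({
            "sample_id": sid,
            "sample_accession": f"SRR{seed % 100:02d}{1000 + i}",
            "collection_datetime": "2012-07-16T10:30:00Z",
            "latitude": round(float(rng.uniform(-80, 80)), 4),
            "longitude": round(float(rng.uniform(-179, 179)), 4),
            "biome": curie_to_purl(_MARINE_CONTEXT[0]),
            "env_feature": curie_to_purl(_MARINE_CONTEXT[1]),
            "env_material": curie_to_purl(_MARINE_CONTEXT[2]),
        })
        chem_rows.append({
            "sample_id": sid,
            "depth": round(float(rng.uniform(5, 1000)), 1),
            "temperature": round(float(rng.uniform(2, 28)), 2),
            "nitrate": "NA" if nitrate_null else round(nitrate, 3),
            "phosphate": "NA" if phosphate_null else round(phosphate, 3),
        })
        truth[sid] = {
            "nitrate": None if nitrate_null else round(nitrate, 3),
            "phosphate": None if phosphate_null else round(phosphate, 3),
        }

    resources = {
        "samples": (_sample_fields(), sample_rows, "samples.tsv"),
        "chemistry": (_chemistry_fields(), chem_rows, "chemistry.tsv"),
    }
    expected: list[dict] = []

    def expect(resource, row, column, code, severity="error"):
        expected.append({"resource": resource, "row": row, "column": column,
                         "code": code, "severity": severity})

    # content-level injections (present when checksummed)
    for inj in injections:
        fields, rows, _ = resources[inj.resource]
        fmap = {f.name: f for f in fields}
        if inj.kind == "type_error":
            f = fmap[inj.field]
            if f.declared_type not in ("number", "integer"):
                raise ParameterError(
                    f"type_error injection targets non-numeric field {inj.field!r}"
                )
            rows[inj.row - 1][inj.field] = "not-a-number"
            expect(inj.resource, inj.row, inj.field, "TYPE_ERROR")
        elif inj.kind == "format_error":
            f = fmap[inj.field]
            if f.declared_type != "datetime":
                raise ParameterError("format_error targets a datetime field")
            rows[inj.row - 1][inj.field] = "16/07/2012"
            expect(inj.resource, inj.row, inj.field, "FORMAT_ERROR")
        elif inj.kind == "constraint":
            # the classic swapped-coordinates defect: latitude of 150
            fld = inj.field or "latitude"
            rows[inj.row - 1][fld] = 250.0 if fld == "longitude" else 150.0
            expect(inj.resource, inj.row, fld, "CONSTRAINT_VIOLATION")
        elif inj.kind == "strip_annotation":
            f = fmap[inj.field]
            f.measurement_source_rdf_type = None
            expect(inj.resource, None, inj.field, "MISSING_ANNOTATION",
                   "warning")
        elif inj.kind == "unknown_term":
            f = fmap[inj.field]
            f.rdf_type = _T("ENVO:9999999")
            expect(inj.resource, None, inj.field, "UNKNOWN_TERM")

    # write resources and checksum them
    specs = []
    for res_name, (fields, rows, fname) in resources.items():
        text = _render_rows(rows, [f.name for f in fields])
        data = text.encode("utf-8")
        (out_dir / fname).write_bytes(data)
        specs.append(ResourceSpec(
            name=res_name, path=fname,
            md5=hashlib.md5(data).hexdigest(), fields=fields,
        ))

    pkg = PackageDescriptor(
        name=name,
        title=f"Synthetic nutrient package (seed {seed})",
        resources=specs,
        licenses=[{"name": "CC-BY-4.0", "path": "https://creativecommons.org/licenses/by/4.0/"}],
        sources=[{"title": "oceanpack synthetic fixture generator", "path": ""}],
    )
    (out_dir / "datapackage.json").write_text(save_descriptor(pkg),
                                              encoding="utf-8")

    # post-checksum injections (trip the transferability checks)
    for inj in injections:
        fname = resources[inj.resource][2]
        if inj.kind == "corrupt_bytes":
            # flip the last digit in the file: a single-byte change that
            # breaks the checksum but keeps every cell parseable
            path = out_dir / fname
            data = bytearray(path.read_bytes())
            for pos in range(len(data) - 1, -1, -1):
                if 0x30 <= data[pos] <= 0x39:
                    data[pos] = 0x30 + (data[pos] - 0x30 + 1) % 10
                    break
            path.write_bytes(bytes(data))
            expect(inj.resource, None, None, "CHECKSUM_MISMATCH")
        elif inj.kind == "delete_file":
            (out_dir / fname).unlink()
            expect(inj.resource, None, None, "MISSING_FILE")
            # a deleted resource is never loaded, so any cell-scoped
            # defects planted in it can no longer be observed
            expected[:] = [
                e for e in expected
                if not (e["resource"] == inj.resource and e["code"] in
                        ("TYPE_ERROR", "FORMAT_ERROR", "CONSTRAINT_VIOLATION"))
            ]

    manifest = PackageManifest(
        seed=seed, name=name, n_samples=n_samples,
        injections=list(injections), expected_issues=expected,
        sample_truth=truth,
    )
    (out_dir / "manifest.json").write_text(manifest.to_json(), encoding="utf-8")
    return pkg, manifest


def random_injections(rng: np.random.Generator, n: int,
                      n_samples: int) -> list[Injection]:
    """Draw ``n`` compatible injections for a package of ``n_samples``.

    Cell-scoped defects target distinct cells so each maps to exactly one
    expected issue; file-scoped kinds are drawn at most once per file.
    """
    out: list[Injection] = []
    cell_kinds = [
        ("type_error", "chemistry", ["nitrate", "phosphate", "depth",
                                     "temperature"]),
        ("format_error", "samples", ["collection_datetime"]),
        ("constraint", "samples", ["latitude", "longitude"]),
    ]
    strip_candidates = [("chemistry", f) for f in
                        ["nitrate", "phosphate", "depth", "temperature"]]
    unknown_candidates = [("samples", "biome"), ("samples", "env_feature"),
                          ("chemistry", "nitrate")]
    cell_by_kind = {k: (res, flds) for k, res, flds in cell_kinds}
    used_cells: set[tuple] = set()
    used_file: set[tuple] = set()
    used_ann: set[tuple] = set()
    for _ in range(n):
        for _attempt in range(500):
            kind = INJECTION_KINDS[rng.integers(len(INJECTION_KINDS))]
            if kind in ("corrupt_bytes", "delete_file"):
                res = ("samples", "chemistry")[rng.integers(2)]
                if (res, "file") in used_file:
                    continue
                used_file.add((res, "file"))
                out.append(Injection(kind, resource=res))
                break
            if kind == "strip_annotation":
                res, fld = strip_candidates[rng.integers(len(strip_candidates))]
                if (res, fld, kind) in used_ann:
                    continue
                used_ann.add((res, fld, kind))
                out.append(Injection(kind, resource=res, field=fld))
                break
            if kind == "unknown_term":
                res, fld = unknown_candidates[rng.integers(len(unknown_candidates))]
                if (res, fld, kind) in used_ann:
                    continue
                used_ann.add((res, fld, kind))
                out.append(Injection(kind, resource=res, field=fld))
                break
            res, fields = cell_by_kind[kind]
            fld = fields[rng.integers(len(fields))]
            row = int(rng.integers(1, n_samples + 1))
            if (res, row, fld) in used_cells:
                continue
            used_cells.add((res, row, fld))
            out.append(Injection(kind, resource=res, row=row, field=fld))
            break
    return out


# ---------------------------------------------------------------------------
# Redfield-structured nutrient data

@dataclass
class RedfieldManifest:
    seed: int
    n: int
    true_slope: float
    noise_sd: float
    outlier_ids: list = dc_field(default_factory=list)


def generate_redfield_data(
    n: int = 1000,
    true_slope: float = 1.0 / 16.0,
    noise_sd: float = 0.2,
    n_outliers: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, RedfieldManifest]:
    """Nutrient table with phosphate = slope * nitrate + noise, floored at 0.

    Nitrate is gamma-distributed (shape 2, scale 8), spanning the 0-40 uM
    regime typical of open-ocean profiles.  ``n_outliers`` extra rows
    emulate anthropogenically influenced freshwater lakes: nitrate around
    37-40 uM with near-zero phosphate, tagged with freshwater ENVO biome
    and feature context so a context filter can remove them.
    """
    if n < 10:
        raise ParameterError("n must be >= 10")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    nitrate = rng.gamma(2.0, 8.0, n)
    phosphate = np.maximum(0.0, true_slope * nitrate + rng.normal(0, noise_sd, n))
    df = pd.DataFrame({
        "sample_id": [f"R{seed:04d}.{i:04d}" for i in range(n)],
        "nitrate": nitrate,
        "phosphate": phosphate,
        "biome": "ENVO:00000447",
        "env_feature": "ENVO:01001581",
    })
    outlier_ids = []
    if n_outliers:
        o_nitrate = rng.uniform(37.0, 40.0, n_outliers)
        o_phosphate = np.abs(rng.normal(0.0, 0.02, n_outliers))
        extra = pd.DataFrame({
            "sample_id": [f"R{seed:04d}.L{i:03d}" for i in range(n_outliers)],
            "nitrate": o_nitrate,
            "phosphate": o_phosphate,
            "biome": "ENVO:01000252",       # freshwater lake biome
            "env_feature": "ENVO:00000021",  # freshwater lake
        })
        outlier_ids = list(extra["sample_id"])
        df = pd.concat([df, extra], ignore_index=True)
    manifest = RedfieldManifest(seed=seed, n=n, true_slope=true_slope,
                                noise_sd=noise_sd, outlier_ids=outlier_ids)
    return df, manifest


# ---------------------------------------------------------------------------
# depth-structured communities

@dataclass
class CommunityManifest:
    seed: int
    n_samples: int
    taxa: list
    effect_signs: dict
    depth_range: tuple
    shallow_ids: list = dc_field(default_factory=list)


DEFAULT_TAXA_SPEC = (
    ("Prochlorococcus_low_light", +1, 2.0),
    ("Nitrosopelagicus_like", +1, 1.5),
    ("Prochlorococcus_high_light", -1, 2.0),
    ("Prochlorococcus_surface", -1, 1.2),
    ("Pelagibacter_like", 0, 0.0),
    ("Roseobacter_like", 0, 0.0),
)


def generate_community_depth_data(
    n_samples: int = 40,
    taxa_spec=DEFAULT_TAXA_SPEC,
    depth_range: tuple[float, float] = (25.0, 125.0),
    total_reads_range: tuple[int, int] = (150_000, 1_000_000),
    n_shallow: int = 0,
    seed: int = 0,
) -> tuple[CommunityMatrix, pd.Series, CommunityManifest]:
    """Taxon counts whose relative abundances trend monotonely with depth.

    Each taxon's expected share follows a logistic-in-depth curve with
    the sign and steepness from ``taxa_spec``; counts are multinomial
    draws at a sampled sequencing total.  ``n_shallow`` samples get
    totals below the conventional 100k-read threshold to exercise the
    shallow-sample filter.
    """
    taxa_spec = list(taxa_spec)
    if len(taxa_spec) < 2:
        raise ParameterError("need at least 2 taxa")
    signs = {s for _, s, m in taxa_spec if m > 0 and s != 0}
    if signs and signs != {+1, -1}:
        raise ParameterError(
            "taxa with non-zero effects must include opposing signs; "
            "all-same-sign trends degenerate under renormalization"
        )
    rng = np.random.default_rng(seed)
    lo, hi = depth_range
    depths = np.sort(rng.uniform(lo, hi, n_samples))
    mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
    z = (depths - mid) / half  # in [-1, 1]

    base = rng.uniform(0.5, 1.5, len(taxa_spec))
    weights = np.empty((n_samples, len(taxa_spec)))
    for j, (_, sign, mag) in enumerate(taxa_spec):
        weights[:, j] = base[j] * np.exp(sign * mag * z)
    probs = weights / weights.sum(axis=1, keepdims=True)

    totals = rng.integers(total_reads_range[0], total_reads_range[1],
                          n_samples)
    shallow_idx = rng.choice(n_samples, size=n_shallow, replace=False)
    totals[shallow_idx] = rng.integers(10_000, DEFAULT_MIN_READS,
                                       n_shallow)

    counts = np.vstack([rng.multinomial(t, p) for t, p in zip(totals, probs)])
    ids = [f"C{seed:04d}.{i:03d}" for i in range(n_samples)]
    names = [t[0] for t in taxa_spec]
    cm = CommunityMatrix(pd.DataFrame(counts, index=ids, columns=names),
                         mode="counts")
    depth_series = pd.Series(depths, index=ids, name="depth")
    manifest = CommunityManifest(
        seed=seed, n_samples=n_samples, taxa=names,
        effect_signs={t[0]: t[1] for t in taxa_spec},
        depth_range=depth_range,
        shallow_ids=[ids[i] for i in sorted(shallow_idx)],
    )
    return cm, depth_series, manifest
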