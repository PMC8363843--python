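"""Staged phenotype import: TSV parsing, validation ledger, trait
description and transactional loading.

Mirrors a three-stage upload: (1) the file is parsed against a fixed
template (one measurement per row: trait, method, unit, germplasm, value,
location, year, replicate), (2) the whole file passes through ordered
data-level validation checks collected in a ledger (failures cite row
numbers and never raise), and (3) each distinct trait-method-unit tuple is
resolved against the store — a trait whose name matches an existing trait
exactly is *locked*: its definition, data type and previously used
method/unit pairings cannot be changed.  Only a fully green ledger may be
loaded, and loading is all-or-nothing.
"""
from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .errors import PhenotypeLoadError, TraitDescriptionError
from .store import Store

TEMPLATE_COLUMNS = ("trait", "method", "unit", "germplasm", "value", "location", "year", "replicate")

#: cell values treated as a missing measurement (row dropped with a count)
MISSING_VALUE_SENTINELS = ("", "NA", "na", "NaN", ".")

_YEAR_RE = re.compile(r"^(18|19|20|21)\d\d$")


@dataclass
class PhenotypeRow:
    row_number: int  # 1-based line number in the file
    trait: str
    method: str
    unit: str
    germplasm: str
    value: str
    location: str
    year: str
    replicate: str

    @property
    def value_missing(self) -> bool:
        return self.value.strip() in MISSING_VALUE_SENTINELS

    def measurement_key(self):
        return (self.trait, self.method, self.unit, self.germplasm,
                self.location, self.year, self.replicate)


@dataclass
class CheckResult:
    name: str
    status: str  # 'pass' | 'fail'
    messages: list = field(default_factory=list)


@dataclass
class ValidationLedger:
    """Ordered validation outcomes; loading is permitted iff all pass."""

    checks: list = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(c.status == "pass" for c in self.checks)

    def failing_rows(self) -> set:
        rows = set()
        for c in self.checks:
            for _, row_numbers in c.messages:
                rows.update(row_numbers)
        return rows

    def format(self) -> str:
        out = []
        for c in self.checks:
            mark = "PASS" if c.status == "pass" else "FAIL"
            out.append(f"[{mark}] {c.name}")
            for msg, row_numbers in c.messages:
                rows = ", ".join(str(r) for r in sorted(row_numbers))
                out.append(f"       {msg} (row {rows})")
        return "\n".join(out)


@dataclass
class TraitDescription:
    trait_name: str
    definition: str = ""
    data_type: Optional[str] = None  # 'quantitative' | 'qualitative' | None -> infer
    ontology_xref: Optional[str] = None


@dataclass(frozen=True)
class TraitTuple:
    trait_id: int
    method_id: int
    unit_id: int
    trait_name: str
    method_name: str
    unit_name: str
    data_type: str
    locked: bool


@dataclass
class LoadCounts:
    inserted: int = 0
    dropped_missing_value: int = 0


def _is_number(text: str) -> bool:
    try:
        v = float(text)
    except (TypeError, ValueError):
        return False
    return v == v and v not in (float("inf"), float("-inf"))


# ---------------------------------------------------------------------------
# Stage 1: parse
# ---------------------------------------------------------------------------


def parse_phenotype_tsv(stream, header_map: Optional[dict] = None):
    """Parse a template TSV into rows plus structural findings.

    The header is matched order-insensitively against the template column
    set (optionally renamed through ``header_map``: file column -> template
    column).  Lines starting with '#' are comments.  Returns
    ``(rows, findings)`` where findings are (row_number, message) pairs for
    missing columns and ragged rows.
    """
    header_map = header_map or {}
    findings: list[tuple[int, str]] = []
    rows: list[PhenotypeRow] = []
    reader = csv.reader(stream, delimiter="\t")
    header = None
    index = {}
    n_cols = 0
    for lineno, rec in enumerate(reader, start=1):
        if not rec or (rec[0].startswith("#") and header is None):
            continue
        if header is None:
            header = [header_map.get(h.strip(), h.strip().lower()) for h in rec]
            missing = [c for c in TEMPLATE_COLUMNS if c not in header]
            for col in missing:
                findings.append((lineno, f"missing required column '{col}'"))
            if missing:
                return [], findings
            index = {c: header.index(c) for c in TEMPLATE_COLUMNS}
            n_cols = len(header)
            continue
        if len(rec) != n_cols:
            findings.append((lineno, f"ragged row: {len(rec)} fields, header has {n_cols}"))
            continue
        rows.append(
            PhenotypeRow(
                row_number=lineno,
                **{c: rec[index[c]].strip() for c in TEMPLATE_COLUMNS},
            )
        )
    if header is None:
        findings.append((0, "empty file: no header row found"))
    return rows, findings


# ---------------------------------------------------------------------------
# Stage 2: validation ledger
# ---------------------------------------------------------------------------


def validate_rows(store: Store, rows: Sequence[PhenotypeRow], project: str, genus: str) -> ValidationLedger:
    """Run the ordered data-level checks over a parsed file.

    Checks (in order): required fields present; germplasm exists in the
    store by exact uniquename; value type matches the trait's data type for
    traits already known for the genus; replicate is a positive integer;
    year is plausible; duplicate measurement keys (within the file and
    against stored measurements for the project).  Failures are ledger
    entries citing row numbers, never exceptions.
    """
    ledger = ValidationLedger()

    def check(name: str, failures: dict):
        status = "pass" if not failures else "fail"
        messages = [(msg, sorted(rownums)) for msg, rownums in sorted(failures.items())]
        ledger.checks.append(CheckResult(name, status, messages))

    # 1. required fields present (value may be a missing sentinel: dropped later)
    fail1: dict[str, set] = {}
    for r in rows:
        for col in ("trait", "method", "unit", "germplasm", "location", "year", "replicate"):
            if not getattr(r, col):
                fail1.setdefault(f"empty '{col}' field", set()).add(r.row_number)
    check("required-fields-present", fail1)

    # 2. germplasm exists (exact uniquename)
    fail2: dict[str, set] = {}
    known: dict[str, bool] = {}
    for r in rows:
        acc = r.germplasm
        if acc not in known:
            known[acc] = store.germplasm_by_uniquename(acc) is not None
        if acc and not known[acc]:
            fail2.setdefault(f"unknown germplasm accession '{acc}'", set()).add(r.row_number)
    check("germplasm-exists", fail2)

    # 3. value type matches known trait data_type
    fail3: dict[str, set] = {}
    trait_types: dict[str, Optional[str]] = {}
    for r in rows:
        if r.trait not in trait_types:
            row = store.conn.execute(
                "SELECT data_type FROM cvterm WHERE name=? AND cv='trait' AND genus=?",
                (r.trait, genus),
            ).fetchone()
            trait_types[r.trait] = row[0] if row else None
        dtype = trait_types[r.trait]
        if dtype == "quantitative" and not r.value_missing and not _is_number(r.value):
            fail3.setdefault(
                f"non-numeric value for quantitative trait '{r.trait}'", set()
            ).add(r.row_number)
    check("value-type-matches-trait", fail3)

    # 4. replicate positive integer
    fail4: dict[str, set] = {}
    for r in rows:
        if not re.match(r"^[1-9]\d*$", r.replicate or ""):
            fail4.setdefault(f"replicate '{r.replicate}' is not a positive integer", set()).add(r.row_number)
    check("replicate-positive-integer", fail4)

    # 5. year plausible
    fail5: dict[str, set] = {}
    for r in rows:
        if r.year and not _YEAR_RE.match(r.year):
            fail5.setdefault(f"implausible year '{r.year}'", set()).add(r.row_number)
    check("year-plausible", fail5)

    # 6. duplicate measurement keys within the file (duplicates against
    # already-stored measurements are rejected at load time by the DB
    # constraint, keeping a re-exported file re-validatable)
    fail6: dict[str, set] = {}
    seen: dict[tuple, int] = {}
    for r in rows:
        key = r.measurement_key()
        if key in seen:
            fail6.setdefault(
                f"duplicate measurement key {key}", set()
            ).update({seen[key], r.row_number})
        else:
            seen[key] = r.row_number
    check("duplicate-measurement-key", fail6)

    return ledger


# ---------------------------------------------------------------------------
# Stage 3: trait description
# ---------------------------------------------------------------------------


def _get_or_create_cvterm(store: Store, name: str, cv: str, genus: str = "",
                          definition: str = "", data_type: Optional[str] = None,
                          ontology_xref: Optional[str] = None) -> int:
    row = store.conn.execute(
        "SELECT cvterm_id FROM cvterm WHERE name=? AND cv=? AND genus=?", (name, cv, genus)
    ).fetchone()
    if row is not None:
        return row[0]
    cur = store.conn.execute(
        "INSERT INTO cvterm (name, cv, genus, definition, data_type, ontology_xref) "
        "VALUES (?,?,?,?,?,?)",
        (name, cv, genus, definition, data_type, ontology_xref),
    )
    store._commit()
    return cur.lastrowid


def _infer_data_type(values: Iterable[str]) -> str:
    vals = [v for v in values if v.strip() not in MISSING_VALUE_SENTINELS]
    return "quantitative" if vals and all(_is_number(v) for v in vals) else "qualitative"


def describe_traits(
    store: Store,
    rows: Sequence[PhenotypeRow],
    provided: Sequence[TraitDescription] = (),
    genus: str = "",
) -> dict[tuple, TraitTuple]:
    """Resolve every distinct (trait, method, unit) tuple in the file.

    A trait whose name matches an existing trait for the genus exactly is
    locked: a provided description may not change its data type, and the
    method/unit pairing must be one already used with that trait in stored
    measurements.  New traits require a description (or fall back to data
    type inference from the file's values when a description without an
    explicit type is supplied).
    """
    by_name = {d.trait_name: d for d in provided}
    tuples = {}
    values_by_trait: dict[str, list] = {}
    for r in rows:
        tuples.setdefault((r.trait, r.method, r.unit), []).append(r)
        values_by_trait.setdefault(r.trait, []).append(r.value)

    undescribed = []
    resolved: dict[tuple, TraitTuple] = {}
    for (trait, method, unit), group in tuples.items():
        existing = store.conn.execute(
            "SELECT cvterm_id, definition, data_type FROM cvterm "
            "WHERE name=? AND cv='trait' AND genus=?",
            (trait, genus),
        ).fetchone()
        if existing is not None:
            trait_id, definition, data_type = existing
            desc = by_name.get(trait)
            if desc is not None and desc.data_type not in (None, data_type):
                raise TraitDescriptionError(
                    f"trait '{trait}' is locked with data_type '{data_type}'; "
                    f"cannot redefine as '{desc.data_type}'"
                )
            used = set(
                store.conn.execute(
                    "SELECT m.name, u.name FROM phenotype ph "
                    "JOIN cvterm m ON m.cvterm_id=ph.assay_id "
                    "JOIN cvterm u ON u.cvterm_id=ph.unit_id WHERE ph.attr_id=?",
                    (trait_id,),
                )
            )
            if used and (method, unit) not in used:
                raise TraitDescriptionError(
                    f"trait '{trait}' is locked to method/unit pairs {sorted(used)}; "
                    f"({method!r}, {unit!r}) conflicts"
                )
            locked = True
        else:
            desc = by_name.get(trait)
            if desc is None:
                undescribed.append(trait)
                continue
            data_type = desc.data_type or _infer_data_type(values_by_trait[trait])
            trait_id = _get_or_create_cvterm(
                store, trait, "trait", genus,
                definition=desc.definition, data_type=data_type,
                ontology_xref=desc.ontology_xref,
            )
            locked = False
        method_id = _get_or_create_cvterm(store, method, "method", genus)
        unit_id = _get_or_create_cvterm(store, unit, "unit", genus)
        resolved[(trait, method, unit)] = TraitTuple(
            trait_id, method_id, unit_id, trait, method, unit, data_type, locked
        )
    if undescribed:
        raise TraitDescriptionError(
            "new trait(s) need a description before loading: "
            + ", ".join(sorted(set(undescribed)))
        )
    return resolved


# ---------------------------------------------------------------------------
# Stage 4: load
# ---------------------------------------------------------------------------


def load_phenotypes(
    store: Store,
    rows: Sequence[PhenotypeRow],
    project: str,
    trait_map: dict[tuple, TraitTuple],
    ledger: Optional[ValidationLedger] = None,
) -> LoadCounts:
    """Insert one measurement per row with a non-missing value.

    Refuses to load when a ledger with failures is supplied (the load
    gate).  Transactional: a constraint violation aborts citing the row.
    """
    if ledger is not None and not ledger.passed:
        raise PhenotypeLoadError("validation ledger has failing checks; load refused")
    counts = LoadCounts()
    proj = store.get_or_create_project(project)
    with store.transaction():
        for r in rows:
            if r.value_missing:
                counts.dropped_missing_value += 1
                continue
            tt = trait_map[(r.trait, r.method, r.unit)]
            germ = store.germplasm_by_uniquename(r.germplasm)
            if germ is None:
                raise PhenotypeLoadError(
                    f"row {r.row_number}: unknown germplasm '{r.germplasm}'"
                )
            try:
                store.conn.execute(
                    "INSERT INTO phenotype (attr_id, assay_id, unit_id, stock_id, project_id,"
                    " value, location, year, replicate) VALUES (?,?,?,?,?,?,?,?,?)",
                    (
                        tt.trait_id, tt.method_id, tt.unit_id, germ.stock_id, proj.project_id,
                        r.value, r.location, r.year, int(r.replicate),
                    ),
                )
            except Exception as exc:
                raise PhenotypeLoadError(f"row {r.row_number}: {exc}") from exc
            counts.inserted += 1
    return counts


def import_phenotype_tsv(
    store: Store,
    stream,
    project: str,
    genus: str,
    descriptions: Sequence[TraitDescription] = (),
    header_map: Optional[dict] = None,
) -> tuple[ValidationLedger, LoadCounts]:
    """Run the full staged pipeline: parse, validate, describe, load."""
    rows, findings = parse_phenotype_tsv(stream, header_map=header_map)
    if findings:
        msgs = "; ".join(f"row {n}: {m}" for n, m in findings)
        raise PhenotypeLoadError(f"structural problems in TSV: {msgs}")
    ledger = validate_rows(store, rows, project, genus)
    if not ledger.passed:
        raise PhenotypeLoadError("validation failed:\n" + ledger.format())
    trait_map = describe_traits(store, rows, descriptions, genus)
    counts = load_phenotypes(store, rows, project, trait_map, ledger)
    return ledger, counts


def export_phenotypes_tsv(store: Store, project: str) -> str:
    """Re-export stored measurements for a project as a template TSV."""
    rows = store.conn.execute(
        "SELECT t.name, m.name, u.name, s.uniquename, ph.value, ph.location, ph.year, ph.replicate "
        "FROM phenotype ph JOIN project p ON p.project_id=ph.project_id "
        "JOIN cvterm t ON t.cvterm_id=ph.attr_id "
        "JOIN cvterm m ON m.cvterm_id=ph.assay_id "
        "JOIN cvterm u ON u.cvterm_id=ph.unit_id "
        "JOIN stock s ON s.stock_id=ph.stock_id "
        "WHERE p.name=? ORDER BY ph.phenotype_id",
        (project,),
    ).fetchall()
    out = ["\t".join(TEMPLATE_COLUMNS) + "\n"]
    for r in rows:
        out.append("\t".join(str(x) for x in r) + "\n")
    return "".join(out)
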