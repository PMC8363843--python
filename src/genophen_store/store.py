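"""Normalized relational store for genotype and phenotype data.

The schema follows the GMOD Chado core layout (project, stock, feature,
feature_relationship, featureloc, cvterm, genotype, phenotype) with two
backward-compatible extensions:

* a ``genotype_call`` linker table gathering one genotype observation per
  (project, variant, marker, germplasm) with a JSON metadata column for
  per-call quality metrics (the VCF FORMAT subfields), and
* three added foreign keys on ``phenotype`` (stock_id, unit_id, project_id)
  so each measurement carries its full trait-method-unit tuple.

The backing engine is embedded SQLite with foreign keys enforced; JSON
metadata is stored as text and read through the stdlib ``json`` module.
Coordinates are interbase (0-based, half-open), the Chado convention;
user-facing APIs convert from 1-based inclusive positions at the boundary.
"""
from __future__ import annotations

import contextlib
import json
import re
import sqlite3
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .errors import (
    DuplicateCallError,
    MissingRecordError,
    StoreError,
    UpgradeRequiredError,
)

SCHEMA_VERSION = 1

# Declared Chado-core shape used by the structural backward-compatibility
# test: removing the extensions listed below must leave every core table
# and core column intact.
CHADO_CORE_TABLES = frozenset(
    {
        "project",
        "projectprop",
        "stock",
        "feature",
        "feature_relationship",
        "featureloc",
        "cvterm",
        "genotype",
        "phenotype",
    }
)
EXTENSION_TABLES = frozenset({"genotype_call"})
PHENOTYPE_EXTENSION_COLUMNS = frozenset({"stock_id", "unit_id", "project_id"})
CHADO_CORE_COLUMNS = {
    "project": {"project_id", "name"},
    "stock": {"stock_id", "name", "uniquename", "genus", "type"},
    "feature": {"feature_id", "name", "uniquename", "type", "residues"},
    "feature_relationship": {"feature_relationship_id", "subject_id", "object_id", "type"},
    "featureloc": {"featureloc_id", "feature_id", "srcfeature_id", "fmin", "fmax", "strand"},
    "cvterm": {"cvterm_id", "name", "cv", "definition"},
    "genotype": {"genotype_id", "allele_string", "description"},
    "phenotype": {"phenotype_id", "attr_id", "assay_id", "value"},
}

_DDL = """
CREATE TABLE IF NOT EXISTS schema_info (
  version INTEGER NOT NULL
);
CREATE TABLE IF NOT EXISTS project (
  project_id INTEGER PRIMARY KEY,
  name TEXT NOT NULL UNIQUE CHECK (name <> '')
);
CREATE TABLE IF NOT EXISTS projectprop (
  projectprop_id INTEGER PRIMARY KEY,
  project_id INTEGER NOT NULL REFERENCES project(project_id),
  key TEXT NOT NULL,
  value TEXT,
  UNIQUE (project_id, key)
);
CREATE TABLE IF NOT EXISTS stock (
  stock_id INTEGER PRIMARY KEY,
  name TEXT NOT NULL,
  uniquename TEXT NOT NULL UNIQUE,
  genus TEXT NOT NULL CHECK (genus <> ''),
  type TEXT NOT NULL DEFAULT 'accession'
);
CREATE TABLE IF NOT EXISTS cvterm (
  cvterm_id INTEGER PRIMARY KEY,
  name TEXT NOT NULL,
  cv TEXT NOT NULL,
  genus TEXT NOT NULL DEFAULT '',
  definition TEXT,
  data_type TEXT CHECK (data_type IN ('quantitative', 'qualitative') OR data_type IS NULL),
  ontology_xref TEXT,
  UNIQUE (name, cv, genus)
);
CREATE TABLE IF NOT EXISTS feature (
  feature_id INTEGER PRIMARY KEY,
  name TEXT NOT NULL,
  uniquename TEXT NOT NULL UNIQUE,
  type TEXT NOT NULL CHECK (type IN ('variant', 'marker', 'backbone')),
  subtype TEXT,
  residues TEXT,
  CHECK (type = 'backbone' OR residues IS NULL)
);
CREATE TABLE IF NOT EXISTS feature_relationship (
  feature_relationship_id INTEGER PRIMARY KEY,
  subject_id INTEGER NOT NULL REFERENCES feature(feature_id),
  object_id INTEGER NOT NULL REFERENCES feature(feature_id),
  type TEXT NOT NULL,
  UNIQUE (subject_id, object_id, type)
);
CREATE TABLE IF NOT EXISTS featureloc (
  featureloc_id INTEGER PRIMARY KEY,
  feature_id INTEGER NOT NULL REFERENCES feature(feature_id),
  srcfeature_id INTEGER NOT NULL REFERENCES feature(feature_id),
  fmin INTEGER NOT NULL CHECK (fmin >= 0),
  fmax INTEGER NOT NULL,
  strand INTEGER NOT NULL DEFAULT 0 CHECK (strand IN (-1, 0, 1)),
  assembly TEXT NOT NULL DEFAULT 'default',
  CHECK (fmin < fmax),
  UNIQUE (feature_id, srcfeature_id, fmin, assembly)
);
CREATE TABLE IF NOT EXISTS genotype (
  genotype_id INTEGER PRIMARY KEY,
  allele_string TEXT NOT NULL UNIQUE,
  description TEXT
);
CREATE TABLE IF NOT EXISTS genotype_call (
  call_id INTEGER PRIMARY KEY,
  project_id INTEGER NOT NULL REFERENCES project(project_id),
  variant_id INTEGER NOT NULL REFERENCES feature(feature_id),
  marker_id INTEGER NOT NULL REFERENCES feature(feature_id),
  stock_id INTEGER NOT NULL REFERENCES stock(stock_id),
  genotype_id INTEGER NOT NULL REFERENCES genotype(genotype_id),
  metadata TEXT NOT NULL DEFAULT '{}',
  UNIQUE (project_id, variant_id, marker_id, stock_id)
);
CREATE TABLE IF NOT EXISTS phenotype (
  phenotype_id INTEGER PRIMARY KEY,
  attr_id INTEGER NOT NULL REFERENCES cvterm(cvterm_id),
  assay_id INTEGER NOT NULL REFERENCES cvterm(cvterm_id),
  unit_id INTEGER NOT NULL REFERENCES cvterm(cvterm_id),
  stock_id INTEGER NOT NULL REFERENCES stock(stock_id),
  project_id INTEGER NOT NULL REFERENCES project(project_id),
  value TEXT NOT NULL CHECK (value <> ''),
  location TEXT NOT NULL,
  year TEXT NOT NULL,
  replicate INTEGER NOT NULL CHECK (replicate >= 1),
  UNIQUE (attr_id, stock_id, project_id, location, year, replicate)
);
"""

_ALLELE_RE = re.compile(r"^[ACGTN-]+$")


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Project:
    project_id: int
    name: str


@dataclass(frozen=True)
class Germplasm:
    stock_id: int
    name: str
    uniquename: str
    genus: str
    type: str = "accession"


@dataclass(frozen=True)
class SequenceFeature:
    feature_id: int
    name: str
    uniquename: str
    feature_type: str
    subtype: Optional[str] = None


@dataclass(frozen=True)
class GenotypeRecord:
    genotype_id: int
    allele_string: str


@dataclass(frozen=True)
class VariantLocation:
    """Placement of a variant on a backbone, interbase coordinates."""

    backbone: str  # backbone feature uniquename
    fmin: int
    fmax: int
    strand: int = 0
    assembly: str = "default"


# ---------------------------------------------------------------------------
# Allele-string canonicalization
# ---------------------------------------------------------------------------


def render_allele_string(alleles: Sequence[str]) -> str:
    """Canonical text form of an unordered allele multiset.

    Alleles are sorted lexicographically (phase is discarded: 0|1 and 1|0
    share one genotype record).  Single-base multisets concatenate
    ("A","G" -> "AG"); if any allele is multi-base the alleles are joined
    with commas ("A","ATG" -> "A,ATG").
    """
    if not alleles:
        raise StoreError("empty allele list: missing calls must be skipped, never stored")
    cleaned = []
    for a in alleles:
        a = str(a).upper()
        if not _ALLELE_RE.match(a):
            raise StoreError(f"invalid allele {a!r}: alleles are strings over A,C,G,T,N,-")
        cleaned.append(a)
    cleaned.sort()
    if any(len(a) > 1 for a in cleaned):
        return ",".join(cleaned)
    return "".join(cleaned)


def split_allele_string(allele_string: str) -> list[str]:
    """Inverse of :func:`render_allele_string` (order = sorted)."""
    if "," in allele_string:
        return allele_string.split(",")
    return list(allele_string)


# ---------------------------------------------------------------------------
# Store
# ---------------------------------------------------------------------------


class Store:
    """Handle on an initialized warehouse database.

    Opening a path (or ``":memory:"``) initializes the schema idempotently;
    reopening an existing store is a no-op unless its recorded schema
    version differs, in which case :class:`UpgradeRequiredError` is raised.

    Parameters
    ----------
    path:
        SQLite database file, or ``":memory:"`` for an ephemeral store.
    duplicate_call_policy:
        ``"reject"`` (default) aborts an import that re-inserts an existing
        (project, variant, marker, stock) key; ``"upsert"`` replaces it.
    marker_suffix:
        Default assay suffix appended to a variant uniquename to synthesize
        its marker name (VCFs carry no marker names).
    batch_size:
        Default number of calls per bulk-insert batch.
    """

    def __init__(
        self,
        path: str = ":memory:",
        *,
        duplicate_call_policy: str = "reject",
        marker_suffix: str = ".assay",
        batch_size: int = 1000,
    ):
        if duplicate_call_policy not in ("reject", "upsert"):
            raise StoreError(f"unknown duplicate-call policy {duplicate_call_policy!r}")
        if batch_size < 1:
            raise StoreError("batch_size must be >= 1")
        self.path = str(path)
        self.duplicate_call_policy = duplicate_call_policy
        self.marker_suffix = marker_suffix
        self.batch_size = batch_size
        self.conn = sqlite3.connect(self.path)
        self.conn.isolation_level = None  # autocommit; transactions are explicit
        self.conn.execute("PRAGMA foreign_keys = ON")
        self._in_txn = False
        self._init_schema()

    @contextlib.contextmanager
    def transaction(self):
        """All-or-nothing scope: every write inside commits together.

        Nested use joins the outer transaction.  On exception the whole
        scope rolls back and the exception propagates.
        """
        if self._in_txn:
            yield
            return
        self.conn.execute("BEGIN")
        self._in_txn = True
        try:
            yield
        except BaseException:
            self.conn.rollback()
            raise
        else:
            self.conn.commit()
        finally:
            self._in_txn = False

    def _commit(self) -> None:
        if not self._in_txn:
            self.conn.commit()

    @classmethod
    def from_config(cls, config_path) -> "Store":
        """Open a store from a key-value YAML config.

        Recognized keys: ``engine`` (must be ``sqlite``), ``path``,
        ``duplicate_call_policy``, ``marker_suffix``, ``batch_size``.
        """
        with open(config_path) as fh:
            cfg = yaml.safe_load(fh) or {}
        engine = cfg.get("engine", "sqlite")
        if engine != "sqlite":
            raise StoreError(f"unsupported engine {engine!r}: this build ships sqlite only")
        return cls(
            cfg.get("path", ":memory:"),
            duplicate_call_policy=cfg.get("duplicate_call_policy", "reject"),
            marker_suffix=cfg.get("marker_suffix", ".assay"),
            batch_size=int(cfg.get("batch_size", 1000)),
        )

    @staticmethod
    def schema_ddl() -> str:
        """The schema DDL, for inspection (``genophen schema`` in the CLI)."""
        return _DDL

    def _init_schema(self) -> None:
        self.conn.executescript(_DDL)
        row = self.conn.execute("SELECT version FROM schema_info").fetchone()
        if row is None:
            self.conn.execute("INSERT INTO schema_info (version) VALUES (?)", (SCHEMA_VERSION,))
            self._commit()
        elif row[0] != SCHEMA_VERSION:
            raise UpgradeRequiredError(
                f"store schema version {row[0]} != library version {SCHEMA_VERSION}; "
                "an explicit upgrade is required"
            )

    def close(self) -> None:
        self.conn.close()

    # -- small helpers ----------------------------------------------------

    def count(self, table: str) -> int:
        if not re.match(r"^[A-Za-z_][A-Za-z0-9_]*$", table):
            raise StoreError(f"bad table name {table!r}")
        return self.conn.execute(f"SELECT COUNT(*) FROM {table}").fetchone()[0]

    def table_columns(self, table: str) -> set:
        return {r[1] for r in self.conn.execute(f"PRAGMA table_info({table})")}

    def tables(self) -> set:
        rows = self.conn.execute(
            "SELECT name FROM sqlite_master WHERE type='table' AND name NOT LIKE 'sqlite_%'"
        )
        return {r[0] for r in rows}

    # -- projects ---------------------------------------------------------

    def get_or_create_project(self, name: str, properties: Optional[Mapping] = None) -> Project:
        if not name:
            raise StoreError("project name must be non-empty")
        row = self.conn.execute("SELECT project_id FROM project WHERE name=?", (name,)).fetchone()
        if row is None:
            cur = self.conn.execute("INSERT INTO project (name) VALUES (?)", (name,))
            project_id = cur.lastrowid
        else:
            project_id = row[0]
        for key, value in (properties or {}).items():
            self.conn.execute(
                "INSERT INTO projectprop (project_id, key, value) VALUES (?,?,?) "
                "ON CONFLICT(project_id, key) DO UPDATE SET value=excluded.value",
                (project_id, str(key), str(value)),
            )
        self._commit()
        return Project(project_id, name)

    # -- germplasm --------------------------------------------------------

    def get_or_create_germplasm(
        self,
        name: str,
        uniquename: str,
        genus: str,
        type: str = "accession",
        mode: str = "insert",
    ) -> Germplasm:
        """Resolve a germplasm accession, creating it under mode='insert'.

        mode='fail' returns an existing record or raises a descriptive
        :class:`MissingRecordError` naming the accession; neither mode ever
        creates a duplicate.
        """
        row = self.conn.execute(
            "SELECT stock_id, name, uniquename, genus, type FROM stock WHERE uniquename=?",
            (uniquename,),
        ).fetchone()
        if row is not None:
            return Germplasm(*row)
        if mode == "fail":
            raise MissingRecordError(
                f"germplasm accession {uniquename!r} does not exist (resolution mode 'fail')"
            )
        if mode != "insert":
            raise StoreError(f"unknown resolution mode {mode!r}")
        cur = self.conn.execute(
            "INSERT INTO stock (name, uniquename, genus, type) VALUES (?,?,?,?)",
            (name, uniquename, genus, type),
        )
        self._commit()
        return Germplasm(cur.lastrowid, name, uniquename, genus, type)

    def germplasm_by_uniquename(self, uniquename: str) -> Optional[Germplasm]:
        row = self.conn.execute(
            "SELECT stock_id, name, uniquename, genus, type FROM stock WHERE uniquename=?",
            (uniquename,),
        ).fetchone()
        return Germplasm(*row) if row else None

    # -- features ---------------------------------------------------------

    def _feature_row(self, uniquename: str):
        return self.conn.execute(
            "SELECT feature_id, name, uniquename, type, subtype FROM feature WHERE uniquename=?",
            (uniquename,),
        ).fetchone()

    def feature_by_uniquename(self, uniquename: str) -> Optional[SequenceFeature]:
        row = self._feature_row(uniquename)
        if row is None:
            return None
        return SequenceFeature(row[0], row[1], row[2], row[3], row[4])

    def add_backbone(self, name: str, residues: Optional[str] = None) -> SequenceFeature:
        """Get-or-create a backbone sequence feature, storing residues if given."""
        row = self._feature_row(name)
        if row is not None:
            if row[3] != "backbone":
                raise StoreError(f"feature {name!r} exists with type {row[3]!r}, not backbone")
            if residues is not None:
                self.conn.execute(
                    "UPDATE feature SET residues=? WHERE feature_id=?", (residues.upper(), row[0])
                )
                self._commit()
            return SequenceFeature(row[0], row[1], row[2], row[3], row[4])
        cur = self.conn.execute(
            "INSERT INTO feature (name, uniquename, type, residues) VALUES (?,?,?,?)",
            (name, name, "backbone", residues.upper() if residues is not None else None),
        )
        self._commit()
        return SequenceFeature(cur.lastrowid, name, name, "backbone", None)

    def load_reference_fasta(self, source) -> int:
        """Load backbone residues from a FASTA file or handle; returns contigs read."""
        from Bio import SeqIO

        n = 0
        for rec in SeqIO.parse(source, "fasta"):
            self.add_backbone(rec.id, str(rec.seq))
            n += 1
        return n

    def backbone_residues(self, uniquename: str) -> Optional[str]:
        row = self.conn.execute(
            "SELECT residues FROM feature WHERE uniquename=? AND type='backbone'", (uniquename,)
        ).fetchone()
        return row[0] if row else None

    def get_or_create_variant_and_marker(
        self,
        variant_uniquename: str,
        location: Optional[VariantLocation] = None,
        mode: str = "insert",
        marker_suffix: Optional[str] = None,
        subtype: Optional[str] = None,
    ) -> tuple[SequenceFeature, SequenceFeature]:
        """Resolve a variant and its linked marker.

        The marker uniquename is ``variant_uniquename + suffix`` (markers do
        not exist in VCF, so they are synthesized per assay).  The location,
        when given, is recorded once per (variant, backbone, fmin, assembly);
        a conflicting fmax/strand for the same key raises.
        """
        suffix = self.marker_suffix if marker_suffix is None else marker_suffix
        vrow = self._feature_row(variant_uniquename)
        if vrow is None:
            if mode == "fail":
                raise MissingRecordError(
                    f"variant {variant_uniquename!r} does not exist (resolution mode 'fail')"
                )
            if mode != "insert":
                raise StoreError(f"unknown resolution mode {mode!r}")
            cur = self.conn.execute(
                "INSERT INTO feature (name, uniquename, type, subtype) VALUES (?,?,?,?)",
                (variant_uniquename, variant_uniquename, "variant", subtype),
            )
            variant = SequenceFeature(cur.lastrowid, variant_uniquename, variant_uniquename, "variant", subtype)
        else:
            variant = SequenceFeature(vrow[0], vrow[1], vrow[2], vrow[3], vrow[4])
            if variant.feature_type != "variant":
                raise StoreError(f"feature {variant_uniquename!r} is a {variant.feature_type}, not a variant")

        marker_name = variant_uniquename + suffix
        mrow = self._feature_row(marker_name)
        if mrow is None:
            cur = self.conn.execute(
                "INSERT INTO feature (name, uniquename, type, subtype) VALUES (?,?,?,?)",
                (marker_name, marker_name, "marker", subtype),
            )
            marker = SequenceFeature(cur.lastrowid, marker_name, marker_name, "marker", subtype)
            self.conn.execute(
                "INSERT OR IGNORE INTO feature_relationship (subject_id, object_id, type) "
                "VALUES (?,?,'is_marker_of')",
                (marker.feature_id, variant.feature_id),
            )
        else:
            marker = SequenceFeature(mrow[0], mrow[1], mrow[2], mrow[3], mrow[4])

        if location is not None:
            self._record_location(variant.feature_id, location)
        self._commit()
        return variant, marker

    def _record_location(self, variant_id: int, loc: VariantLocation) -> None:
        brow = self._feature_row(loc.backbone)
        if brow is None or brow[3] != "backbone":
            raise MissingRecordError(f"backbone {loc.backbone!r} does not exist")
        backbone_id = brow[0]
        residues = self.backbone_residues(loc.backbone)
        if not (0 <= loc.fmin < loc.fmax):
            raise StoreError(f"invalid interbase range fmin={loc.fmin} fmax={loc.fmax}")
        if residues is not None and loc.fmax > len(residues):
            raise StoreError(
                f"fmax {loc.fmax} exceeds backbone {loc.backbone!r} length {len(residues)}"
            )
        existing = self.conn.execute(
            "SELECT fmax, strand FROM featureloc WHERE feature_id=? AND srcfeature_id=? "
            "AND fmin=? AND assembly=?",
            (variant_id, backbone_id, loc.fmin, loc.assembly),
        ).fetchone()
        if existing is not None:
            if (existing[0], existing[1]) != (loc.fmax, loc.strand):
                raise StoreError(
                    f"conflicting location for variant_id={variant_id} on {loc.backbone} "
                    f"fmin={loc.fmin} assembly={loc.assembly!r}: stored fmax/strand "
                    f"{existing} != {(loc.fmax, loc.strand)}"
                )
            return
        self.conn.execute(
            "INSERT INTO featureloc (feature_id, srcfeature_id, fmin, fmax, strand, assembly) "
            "VALUES (?,?,?,?,?,?)",
            (variant_id, backbone_id, loc.fmin, loc.fmax, loc.strand, loc.assembly),
        )

    # -- genotypes --------------------------------------------------------

    def canonical_genotype(self, alleles: Sequence[str]) -> GenotypeRecord:
        """Return the shared genotype record for a sorted allele multiset.

        At most one row exists per distinct multiset; ["G","A"] and
        ["A","G"] resolve to the same record.
        """
        allele_string = render_allele_string(alleles)
        return self._genotype_for_string(allele_string)

    def _genotype_for_string(self, allele_string: str) -> GenotypeRecord:
        row = self.conn.execute(
            "SELECT genotype_id FROM genotype WHERE allele_string=?", (allele_string,)
        ).fetchone()
        if row is not None:
            return GenotypeRecord(row[0], allele_string)
        cur = self.conn.execute(
            "INSERT INTO genotype (allele_string, description) VALUES (?,?)",
            (allele_string, allele_string),
        )
        self._commit()
        return GenotypeRecord(cur.lastrowid, allele_string)

    # -- calls ------------------------------------------------------------

    def add_call(
        self,
        project_id: int,
        variant_id: int,
        marker_id: int,
        stock_id: int,
        genotype_id: int,
        metadata: Optional[Mapping] = None,
    ) -> int:
        """Insert a single genotype call honouring the duplicate policy."""
        payload = json.dumps(metadata or {}, sort_keys=True)
        sql = (
            "INSERT OR REPLACE" if self.duplicate_call_policy == "upsert" else "INSERT"
        ) + " INTO genotype_call (project_id, variant_id, marker_id, stock_id, genotype_id, metadata) VALUES (?,?,?,?,?,?)"
        try:
            cur = self.conn.execute(
                sql, (project_id, variant_id, marker_id, stock_id, genotype_id, payload)
            )
        except sqlite3.IntegrityError as exc:
            if "UNIQUE" in str(exc):
                raise DuplicateCallError(
                    "duplicate genotype call key (project_id, variant_id, marker_id, stock_id)="
                    f"({project_id}, {variant_id}, {marker_id}, {stock_id})"
                ) from exc
            raise
        self._commit()
        return cur.lastrowid

    def call_metadata(self, call_id: int) -> dict:
        row = self.conn.execute(
            "SELECT metadata FROM genotype_call WHERE call_id=?", (call_id,)
        ).fetchone()
        if row is None:
            raise MissingRecordError(f"no genotype call with id {call_id}")
        return json.loads(row[0])
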