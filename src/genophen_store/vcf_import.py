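"""Validating, batched bulk import of VCF genotype calls.

Reproduces the loader semantics of the warehouse: VCF v4.0+ is validated
up front, germplasm and variants are resolved (created on the fly or
required to pre-exist, per configuration), the GT field is translated to
nucleotide alleles and canonicalized, missing calls ("./.") are skipped
entirely to keep storage proportional to observed data, and all FORMAT
subfields other than GT travel verbatim into the call's metadata map.
Inserts go through the backend's bulk path (``executemany``) in
configurable batches inside one transaction: an error anywhere leaves
zero rows from the import.
"""
from __future__ import annotations

import gzip
import io
import json
import re
import sqlite3
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Optional, TextIO

from .errors import (
    DuplicateCallError,
    MissingRecordError,
    VcfImportError,
    VcfParseError,
)
from .store import Store, VariantLocation, render_allele_string


class _MissingType:
    """Sentinel for a skipped (missing) genotype call."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "MISSING"

    def __bool__(self):
        return False


MISSING = _MissingType()

_VERSION_RE = re.compile(r"^##fileformat=VCFv(\d+)\.(\d+)", re.IGNORECASE)
_GT_TOKEN_RE = re.compile(r"^(\.|\d+)$")
_FORMAT_HEADER_RE = re.compile(
    r"^##FORMAT=<ID=([^,>]+),Number=([^,>]+),Type=([^,>]+)"
)

#: standard fixed VCF columns up to FORMAT
VCF_FIXED_COLUMNS = ("#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT")


@dataclass(frozen=True)
class Finding:
    """One validation finding; line is 1-based within the stream."""

    line: int
    message: str


@dataclass
class ImportConfig:
    """Configuration for one VCF import run.

    ``germplasm_mode`` / ``variant_mode`` are ``insert`` (create missing
    records from the file) or ``fail`` (abort naming the missing record).
    ``sample_name_map`` maps VCF sample ids to germplasm uniquenames;
    identity by default.
    """

    project_name: str
    genus: str = "unknown"
    germplasm_mode: str = "insert"
    variant_mode: str = "insert"
    batch_size: int = 1000
    marker_suffix: Optional[str] = None
    sample_name_map: Optional[Mapping[str, str]] = None
    assembly_label: str = "default"

    def __post_init__(self):
        if self.batch_size < 1:
            raise VcfImportError("batch_size must be >= 1")
        for mode in (self.germplasm_mode, self.variant_mode):
            if mode not in ("insert", "fail"):
                raise VcfImportError(f"unknown resolution mode {mode!r}")


@dataclass
class ImportReport:
    """Counts and findings from one import.

    Invariant (when error-free): ``calls_inserted + calls_skipped_missing
    == variants_seen * samples_seen``.  Partial-missing calls (e.g. "./1")
    are counted within ``calls_skipped_missing`` and broken out in
    ``calls_partial_missing``.
    """

    variants_seen: int = 0
    samples_seen: int = 0
    calls_inserted: int = 0
    calls_skipped_missing: int = 0
    calls_partial_missing: int = 0
    germplasm_created: int = 0
    variants_created: int = 0
    errors: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _open_text(source) -> TextIO:
    if hasattr(source, "read"):
        return source
    path = str(source)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, encoding="utf-8")


# ---------------------------------------------------------------------------
# GT translation
# ---------------------------------------------------------------------------


def translate_gt(gt_field: str, ref: str, alts):
    """Translate a VCF GT field into a nucleotide allele list.

    Any ploidy is accepted (indices separated by ``/`` or ``|``).  Returns
    :data:`MISSING` when every index is "." and — per the package's design
    choice — also when only some indices are "." (a half-specified call has
    no canonical allele string; the importer counts these separately).

    Raises :class:`VcfParseError` on non-numeric tokens or allele indices
    beyond the ALT list.
    """
    tokens = re.split(r"[/|]", gt_field.strip())
    if not tokens or tokens == [""]:
        raise VcfParseError(f"empty GT field {gt_field!r}")
    for tok in tokens:
        if not _GT_TOKEN_RE.match(tok):
            raise VcfParseError(f"malformed GT token {tok!r} in {gt_field!r}")
    if any(tok == "." for tok in tokens):
        return MISSING
    alleles = []
    n_alt = len(alts)
    for tok in tokens:
        idx = int(tok)
        if idx == 0:
            alleles.append(ref)
        elif idx <= n_alt:
            alleles.append(alts[idx - 1])
        else:
            raise VcfParseError(
                f"GT allele index {idx} out of range for {n_alt} ALT allele(s)"
            )
    return alleles


def gt_is_partial_missing(gt_field: str) -> bool:
    tokens = re.split(r"[/|]", gt_field.strip())
    dots = sum(t == "." for t in tokens)
    return 0 < dots < len(tokens)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_vcf(source) -> list[Finding]:
    """Validate a VCF stream against the v4.0+ subset the loader supports.

    Returns a list of findings (empty means valid): unsupported/missing
    fileformat line, missing #CHROM header, per-line column-count
    mismatches, malformed GT fields and ALT indices out of range.
    """
    findings: list[Finding] = []
    fh = _open_text(source)
    n_columns = None
    saw_fileformat = False
    saw_chrom = False
    for lineno, raw in enumerate(fh, start=1):
        line = raw.rstrip("\n")
        if not line:
            continue
        if lineno == 1 or (line.startswith("##") and not saw_chrom):
            m = _VERSION_RE.match(line)
            if m:
                saw_fileformat = True
                if int(m.group(1)) < 4:
                    findings.append(
                        Finding(lineno, f"unsupported version VCFv{m.group(1)}.{m.group(2)}: VCF v4.0+ required")
                    )
            elif lineno == 1:
                findings.append(Finding(1, "missing ##fileformat line (VCF v4.0+ required)"))
        if line.startswith("##"):
            continue
        if line.startswith("#CHROM"):
            saw_chrom = True
            cols = line.split("\t")
            if tuple(cols[: len(VCF_FIXED_COLUMNS)]) != VCF_FIXED_COLUMNS[: len(cols)]:
                findings.append(Finding(lineno, "malformed #CHROM header columns"))
            n_columns = len(cols)
            continue
        if not saw_chrom:
            findings.append(Finding(lineno, "data line before #CHROM header"))
            continue
        cols = line.split("\t")
        if n_columns is not None and len(cols) != n_columns:
            findings.append(
                Finding(lineno, f"column count {len(cols)} does not match header ({n_columns})")
            )
            continue
        if len(cols) < 10:
            continue  # sites-only file: nothing further to check
        alts = [] if cols[4] == "." else cols[4].split(",")
        fmt = cols[8].split(":")
        try:
            gt_idx = fmt.index("GT")
        except ValueError:
            findings.append(Finding(lineno, "FORMAT lacks GT subfield"))
            continue
        for si, sample_field in enumerate(cols[9:]):
            sub = sample_field.split(":")
            gt = sub[gt_idx] if gt_idx < len(sub) else None
            if gt is None:
                findings.append(Finding(lineno, f"sample column {si + 1} lacks a GT value"))
                continue
            tokens = re.split(r"[/|]", gt)
            for tok in tokens:
                if not _GT_TOKEN_RE.match(tok):
                    findings.append(
                        Finding(lineno, f"malformed GT {gt!r} in sample column {si + 1}")
                    )
                    break
                if tok != "." and int(tok) > len(alts):
                    findings.append(
                        Finding(
                            lineno,
                            f"GT allele index {tok} out of range in sample column {si + 1} "
                            f"({len(alts)} ALT allele(s))",
                        )
                    )
                    break
    if not saw_fileformat:
        if not any("fileformat" in f.message for f in findings):
            findings.insert(0, Finding(1, "missing ##fileformat line (VCF v4.0+ required)"))
    if not saw_chrom:
        findings.append(Finding(0, "missing #CHROM header line"))
    return findings


# ---------------------------------------------------------------------------
# Import
# ---------------------------------------------------------------------------


def _typed(value: str, vcf_type: str):
    if value == ".":
        return None
    try:
        if vcf_type == "Integer":
            return int(value)
        if vcf_type == "Float":
            return float(value)
    except ValueError:
        return value
    return value


def import_vcf(store: Store, source, config: ImportConfig) -> ImportReport:
    """Import all non-missing genotype calls from a VCF stream.

    One genotype_call row is written per non-missing GT with every FORMAT
    subfield except GT stored verbatim (typed by the FORMAT header Type
    declaration when present).  The entire import is one transaction:
    resolution failures in ``fail`` mode, malformed records and duplicate
    call keys under the ``reject`` policy abort with zero rows retained.
    """
    report = ImportReport()
    fh = _open_text(source)
    conn = store.conn
    suffix = config.marker_suffix if config.marker_suffix is not None else store.marker_suffix
    name_map = dict(config.sample_name_map or {})
    format_types: dict[str, str] = {}
    samples: list[str] = []
    stock_ids: list[int] = []
    batch: list[tuple] = []
    genotype_cache: dict[str, int] = {}

    def flush():
        if not batch:
            return
        sql = (
            "INSERT OR REPLACE" if store.duplicate_call_policy == "upsert" else "INSERT"
        ) + (
            " INTO genotype_call (project_id, variant_id, marker_id, stock_id,"
            " genotype_id, metadata) VALUES (?,?,?,?,?,?)"
        )
        try:
            conn.executemany(sql, batch)
        except sqlite3.IntegrityError:
            # Re-probe row by row to name the offending key before rolling back.
            for row in batch:
                try:
                    conn.execute(sql, row)
                except sqlite3.IntegrityError as exc2:
                    if "UNIQUE" in str(exc2):
                        raise DuplicateCallError(
                            "duplicate genotype call key (project_id, variant_id, "
                            f"marker_id, stock_id)=({row[0]}, {row[1]}, {row[2]}, {row[3]})"
                        ) from exc2
                    raise
            raise
        batch.clear()

    def genotype_id_for(alleles) -> int:
        allele_string = render_allele_string(alleles)
        gid = genotype_cache.get(allele_string)
        if gid is None:
            gid = store._genotype_for_string(allele_string).genotype_id
            genotype_cache[allele_string] = gid
        return gid

    try:
      with store.transaction():
        project = store.get_or_create_project(config.project_name)
        stocks_before = store.count("stock")
        variants_before = conn.execute(
            "SELECT COUNT(*) FROM feature WHERE type='variant'"
        ).fetchone()[0]

        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                m = _FORMAT_HEADER_RE.match(line)
                if m:
                    format_types[m.group(1)] = m.group(3)
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                report.samples_seen = len(samples)
                for s in samples:
                    uniq = name_map.get(s, s)
                    existed = store.germplasm_by_uniquename(uniq) is not None
                    g = store.get_or_create_germplasm(
                        s, uniq, config.genus, mode=config.germplasm_mode
                    )
                    if not existed:
                        report.germplasm_created += 1
                    stock_ids.append(g.stock_id)
                continue
            if not samples:
                raise VcfImportError(f"line {lineno}: data before #CHROM header")

            cols = line.split("\t")
            if len(cols) != 9 + len(samples):
                raise VcfImportError(
                    f"line {lineno}: column count {len(cols)} does not match header"
                )
            chrom, pos_s, vid, ref, alt = cols[0], cols[1], cols[2], cols[3], cols[4]
            pos = int(pos_s)
            alts = [] if alt == "." else alt.split(",")
            report.variants_seen += 1

            uniquename = vid if vid not in (".", "") else f"{chrom}_{pos}"
            store.add_backbone(chrom)  # no residues; placement target only
            subtype = "SNP" if len(ref) == 1 and all(len(a) == 1 for a in alts) else "indel"
            existed = store.feature_by_uniquename(uniquename) is not None
            variant, marker = store.get_or_create_variant_and_marker(
                uniquename,
                location=VariantLocation(
                    backbone=chrom,
                    fmin=pos - 1,
                    fmax=pos - 1 + len(ref),
                    strand=1,
                    assembly=config.assembly_label,
                ),
                mode=config.variant_mode,
                marker_suffix=suffix,
                subtype=subtype,
            )
            if not existed:
                report.variants_created += 1

            fmt = cols[8].split(":")
            try:
                gt_idx = fmt.index("GT")
            except ValueError:
                raise VcfImportError(f"line {lineno}: FORMAT lacks GT subfield")
            other_keys = [(i, k) for i, k in enumerate(fmt) if k != "GT"]
            gt_cache: dict[str, object] = {}

            for si, sample_field in enumerate(cols[9:]):
                sub = sample_field.split(":")
                gt = sub[gt_idx]
                resolved = gt_cache.get(gt)
                if resolved is None:
                    try:
                        alleles = translate_gt(gt, ref, alts)
                    except VcfParseError as exc:
                        raise VcfImportError(
                            f"line {lineno}, sample {samples[si]!r}: {exc}"
                        ) from exc
                    resolved = MISSING if alleles is MISSING else genotype_id_for(alleles)
                    gt_cache[gt] = resolved
                if resolved is MISSING:
                    report.calls_skipped_missing += 1
                    if gt_is_partial_missing(gt):
                        report.calls_partial_missing += 1
                    continue
                metadata = {}
                for i, key in other_keys:
                    if i < len(sub):
                        metadata[key] = _typed(sub[i], format_types.get(key, "String"))
                batch.append(
                    (
                        project.project_id,
                        variant.feature_id,
                        marker.feature_id,
                        stock_ids[si],
                        resolved,
                        json.dumps(metadata, sort_keys=True),
                    )
                )
                report.calls_inserted += 1
                if len(batch) >= config.batch_size:
                    flush()

        flush()
        report.germplasm_created = store.count("stock") - stocks_before
        report.variants_created = (
            conn.execute("SELECT COUNT(*) FROM feature WHERE type='variant'").fetchone()[0]
            - variants_before
        )
    except (VcfImportError, DuplicateCallError, MissingRecordError):
        raise
    except Exception as exc:
        raise VcfImportError(f"import aborted: {exc}") from exc
    return report
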