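"""Variant-by-germplasm genotype matrix engine.

Queries are two-stage: the set of variants matching the filter criteria is
retrieved first from the small variant-focused materialized view, and the
genotype calls for those variants are then fetched from the much larger
call-focused view through its primary-key index.  Each matrix cell shows
the consensus call for a (variant, germplasm) pair across every marker and
project in scope: agreeing calls render as the shared allele string,
disagreeing calls render as the IUPAC code of the allele union (or
slash-joined alleles when not all are single bases), and missing data
renders as an empty cell.  Every mview-backed query has an equivalent
direct normalized-join form (``use_mview=False``) used by the benchmark
harness and the correctness tests.

Range filters accept 1-based inclusive coordinates (the biologist
convention) and convert to interbase internally.  Exports stream the full
filtered set as a CSV matrix or a classic 11-column TASSEL-compatible
HapMap table.
"""
from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import ExportFormatError, InvalidFilterError, MissingRecordError
from .iupac import iupac_code
from .store import Store, split_allele_string

#: rendering of a cell with no stored call
EMPTY = ""

DEFAULT_PAGE_SIZE = 100

HAPMAP_COLUMNS = (
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
)
HAPMAP_CENTER = "genophen-store"


@dataclass
class MatrixFilter:
    """Filter criteria for one matrix query.

    ``germplasm`` is the ordered list of accession uniquenames shown as
    columns (at least one required).  ``range`` is (backbone, start, end)
    in 1-based inclusive coordinates.  ``polymorphic_pair`` keeps only
    variants whose consensus calls for the two named accessions are both
    present and differ; both members must be in the germplasm list.
    """

    germplasm: Sequence[str]
    range: Optional[tuple] = None  # (backbone, start_1based, end_1based)
    polymorphic_pair: Optional[tuple] = None
    variant_name_pattern: Optional[str] = None  # SQL LIKE pattern
    variant_type: Optional[str] = None  # e.g. 'SNP', 'indel'
    page: int = 1
    page_size: int = DEFAULT_PAGE_SIZE

    def validate(self) -> None:
        if not self.germplasm:
            raise InvalidFilterError("at least one germplasm accession is required")
        if self.polymorphic_pair is not None:
            a, b = self.polymorphic_pair
            if a not in self.germplasm or b not in self.germplasm:
                raise InvalidFilterError(
                    "polymorphic pair members must be drawn from the germplasm list"
                )
        if self.range is not None:
            _, start, end = self.range
            if start > end:
                raise InvalidFilterError(f"range start {start} > end {end}")
        if self.page < 1 or self.page_size < 1:
            raise InvalidFilterError("page and page_size must be >= 1")


@dataclass
class MatrixPage:
    """One page of the rendered matrix.

    ``variants`` lists (variant_name, backbone, position_1based) in
    (backbone, position) order; ``cells[variant_name][germplasm]`` is the
    rendered consensus or :data:`EMPTY`; ``total_variants`` counts the
    full (unpaginated) filtered set.
    """

    germplasm: list
    variants: list
    cells: dict
    total_variants: int


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _stock_ids(store: Store, uniquenames: Sequence[str]) -> list[int]:
    ids = []
    for u in uniquenames:
        g = store.germplasm_by_uniquename(u)
        if g is None:
            raise MissingRecordError(f"unknown germplasm accession {u!r}")
        ids.append(g.stock_id)
    return ids


def _known_backbones(store: Store, use_mview: bool) -> list[str]:
    if use_mview:
        rows = store.conn.execute(
            "SELECT DISTINCT backbone_name FROM mview_ndg_variants ORDER BY backbone_name"
        )
    else:
        rows = store.conn.execute(
            "SELECT DISTINCT uniquename FROM feature WHERE type='backbone' ORDER BY uniquename"
        )
    return [r[0] for r in rows]


def render_consensus(allele_strings) -> str:
    """Merge one cell's stored allele strings into a single rendered call."""
    strings = set(allele_strings)
    if not strings:
        return EMPTY
    if len(strings) == 1:
        return next(iter(strings))
    union = set()
    for s in strings:
        union.update(split_allele_string(s))
    if all(len(a) == 1 and a in "ACGT" for a in union):
        return iupac_code(union)
    return "/".join(sorted(union))


def _chunks(seq, size=500):
    for i in range(0, len(seq), size):
        yield seq[i : i + size]


# ---------------------------------------------------------------------------
# stage 1: variant selection
# ---------------------------------------------------------------------------


def select_variants(
    store: Store,
    flt: MatrixFilter,
    use_mview: bool = True,
    paginate: bool = True,
):
    """Return (variant id list, total count) for the location-level filters.

    Variants are ordered by (backbone, fmin, variant_id); the range filter
    converts 1-based inclusive user coordinates to interbase containment
    (start-1 <= fmin <= end-1).  The polymorphic-pair filter is call-level
    and applied by :func:`fetch_matrix` / :func:`polymorphic_filter`.
    Pagination is applied after filtering; the total reflects the
    unpaginated filter.
    """
    flt.validate()
    where, params = [], []
    if flt.range is not None:
        backbone, start, end = flt.range
        known = _known_backbones(store, use_mview)
        if backbone not in known:
            raise MissingRecordError(
                f"unknown backbone {backbone!r}; known backbones: {', '.join(known)}"
            )
        where.append("backbone_name = ? AND fmin BETWEEN ? AND ?")
        params += [backbone, start - 1, end - 1]
    if flt.variant_name_pattern:
        where.append("variant_name LIKE ?")
        params.append(flt.variant_name_pattern)
    if flt.variant_type:
        where.append("variant_subtype = ?")
        params.append(flt.variant_type)
    clause = (" WHERE " + " AND ".join(where)) if where else ""

    if use_mview:
        sql = (
            "SELECT variant_id, MIN(backbone_name) AS bb, MIN(fmin) AS f "
            "FROM mview_ndg_variants" + clause + " GROUP BY variant_id ORDER BY bb, f, variant_id"
        )
    else:
        sql = (
            "SELECT v.feature_id AS variant_id, MIN(b.uniquename) AS bb, MIN(fl.fmin) AS f "
            "FROM featureloc fl "
            "JOIN feature v ON v.feature_id = fl.feature_id AND v.type='variant' "
            "JOIN feature b ON b.feature_id = fl.srcfeature_id"
            + clause.replace("backbone_name", "b.uniquename")
            .replace("fmin", "fl.fmin")
            .replace("variant_name", "v.uniquename")
            .replace("variant_subtype", "v.subtype")
            + " GROUP BY v.feature_id ORDER BY bb, f, variant_id"
        )
    ids = [r[0] for r in store.conn.execute(sql, params)]
    total = len(ids)
    if paginate:
        lo = (flt.page - 1) * flt.page_size
        ids = ids[lo : lo + flt.page_size]
    return ids, total


# ---------------------------------------------------------------------------
# stage 2: calls and consensus
# ---------------------------------------------------------------------------


def consensus_map(
    store: Store,
    variant_ids: Sequence[int],
    stock_ids: Sequence[int],
    use_mview: bool = True,
) -> dict:
    """Rendered consensus for every (variant_id, stock_id) cell with calls."""
    gathered: dict[tuple, set] = {}
    stock_list = list(stock_ids)
    for chunk in _chunks(list(variant_ids)):
        vmarks = ",".join("?" * len(chunk))
        smarks = ",".join("?" * len(stock_list))
        if use_mview:
            sql = (
                f"SELECT variant_id, stock_id, allele_string FROM mview_ndg_calls "
                f"WHERE variant_id IN ({vmarks}) AND stock_id IN ({smarks})"
            )
        else:
            sql = (
                f"SELECT gc.variant_id, gc.stock_id, g.allele_string "
                f"FROM genotype_call gc JOIN genotype g ON g.genotype_id = gc.genotype_id "
                f"WHERE gc.variant_id IN ({vmarks}) AND gc.stock_id IN ({smarks})"
            )
        for vid, sid, alleles in store.conn.execute(sql, [*chunk, *stock_list]):
            gathered.setdefault((vid, sid), set()).add(alleles)
    return {key: render_consensus(strings) for key, strings in gathered.items()}


def consensus_call(store: Store, variant: str, germplasm: str, use_mview: bool = True) -> str:
    """Consensus call for one (variant uniquename, germplasm uniquename) cell."""
    feat = store.feature_by_uniquename(variant)
    if feat is None:
        return EMPTY
    g = store.germplasm_by_uniquename(germplasm)
    if g is None:
        return EMPTY
    return consensus_map(store, [feat.feature_id], [g.stock_id], use_mview).get(
        (feat.feature_id, g.stock_id), EMPTY
    )


def polymorphic_filter(
    store: Store,
    variant_ids: Sequence[int],
    pair: tuple,
    use_mview: bool = True,
) -> list[int]:
    """Keep variants whose consensus calls for the pair both exist and differ.

    ``pair`` is (uniquename A, uniquename B).  Variants where either member
    has no call are excluded: a difference cannot be asserted against
    missing data.
    """
    sid_a, sid_b = _stock_ids(store, list(pair))
    cons = consensus_map(store, variant_ids, [sid_a, sid_b], use_mview)
    kept = []
    for vid in variant_ids:
        a = cons.get((vid, sid_a), EMPTY)
        b = cons.get((vid, sid_b), EMPTY)
        if a != EMPTY and b != EMPTY and a != b:
            kept.append(vid)
    return kept


def _variant_meta(store: Store, variant_ids: Sequence[int], use_mview: bool) -> dict:
    """variant_id -> (name, backbone, pos_1based, strand, assembly)."""
    meta = {}
    for chunk in _chunks(list(variant_ids)):
        marks = ",".join("?" * len(chunk))
        if use_mview:
            sql = (
                f"SELECT variant_id, variant_name, MIN(backbone_name), MIN(fmin), MIN(strand),"
                f" MIN(assembly) FROM mview_ndg_variants WHERE variant_id IN ({marks})"
                " GROUP BY variant_id, variant_name"
            )
        else:
            sql = (
                f"SELECT v.feature_id, v.uniquename, MIN(b.uniquename), MIN(fl.fmin),"
                f" MIN(fl.strand), MIN(fl.assembly) "
                f"FROM featureloc fl JOIN feature v ON v.feature_id = fl.feature_id "
                f"JOIN feature b ON b.feature_id = fl.srcfeature_id "
                f"WHERE v.feature_id IN ({marks}) GROUP BY v.feature_id, v.uniquename"
            )
        for vid, name, bb, fmin, strand, assembly in store.conn.execute(sql, chunk):
            meta[vid] = (name, bb, fmin + 1, strand, assembly)
    return meta


def fetch_matrix(store: Store, flt: MatrixFilter, use_mview: bool = True, paginate: bool = True) -> MatrixPage:
    """Run the full two-stage matrix query and render one page."""
    ids, _ = select_variants(store, flt, use_mview=use_mview, paginate=False)
    stock_ids = _stock_ids(store, flt.germplasm)
    if flt.polymorphic_pair is not None:
        ids = polymorphic_filter(store, ids, flt.polymorphic_pair, use_mview)
    total = len(ids)
    if paginate:
        lo = (flt.page - 1) * flt.page_size
        ids = ids[lo : lo + flt.page_size]
    cons = consensus_map(store, ids, stock_ids, use_mview)
    meta = _variant_meta(store, ids, use_mview)
    variants = [(meta[v][0], meta[v][1], meta[v][2]) for v in ids]
    cells = {}
    for vid in ids:
        name = meta[vid][0]
        cells[name] = {
            u: cons.get((vid, sid), EMPTY) for u, sid in zip(flt.germplasm, stock_ids)
        }
    return MatrixPage(
        germplasm=list(flt.germplasm), variants=variants, cells=cells, total_variants=total
    )


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------


def allele_frequencies(store: Store, variant: str) -> dict[str, float]:
    """Observed allele proportions across all stored calls for a variant.

    Each call contributes every allele of its multiset (a diploid "AG"
    adds one A and one G).  Proportions sum to 1 when any calls exist;
    an unknown or call-less variant yields an empty map.
    """
    feat = store.feature_by_uniquename(variant)
    if feat is None:
        raise MissingRecordError(f"unknown variant {variant!r}")
    counts: dict[str, int] = {}
    for (alleles,) in store.conn.execute(
        "SELECT g.allele_string FROM genotype_call gc "
        "JOIN genotype g ON g.genotype_id = gc.genotype_id WHERE gc.variant_id = ?",
        (feat.feature_id,),
    ):
        for a in split_allele_string(alleles):
            counts[a] = counts.get(a, 0) + 1
    total = sum(counts.values())
    return {a: c / total for a, c in sorted(counts.items())}


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def export_matrix(store: Store, flt: MatrixFilter, format: str = "csv", use_mview: bool = True) -> str:
    """Export the full filtered matrix (all pages) as CSV or HapMap text."""
    if format not in ("csv", "hapmap"):
        raise ExportFormatError(f"unsupported export format {format!r}")
    page = fetch_matrix(store, flt, use_mview=use_mview, paginate=False)
    if format == "csv":
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(["variant", "backbone", "position", *page.germplasm])
        for name, backbone, pos in page.variants:
            writer.writerow([name, backbone, pos, *(page.cells[name][g] for g in page.germplasm)])
        return buf.getvalue()

    # HapMap: classic 11 metadata columns then one column per germplasm;
    # missing cells render "NN", unavailable metadata renders "NA".
    ids, _ = select_variants(store, flt, use_mview=use_mview, paginate=False)
    out = ["\t".join([*HAPMAP_COLUMNS, *page.germplasm]) + "\n"]
    name_meta = {}
    for vid, meta in _variant_meta(store, ids, use_mview).items():
        name_meta[meta[0]] = meta
    for name, backbone, pos in page.variants:
        observed = set()
        for g in page.germplasm:
            cell = page.cells[name][g]
            if cell != EMPTY:
                observed.update(split_allele_string(cell) if cell not in ("",) else [])
        alleles = "/".join(sorted(a for a in observed if len(a) == 1 and a in "ACGT")) or "NA"
        strand = {1: "+", -1: "-"}.get(name_meta[name][3], "+")
        assembly = name_meta[name][4] or "NA"
        row = [
            name, alleles, backbone, str(pos), strand, assembly,
            HAPMAP_CENTER, "NA", "NA", "NA", "NA",
        ]
        for g in page.germplasm:
            cell = page.cells[name][g]
            row.append("NN" if cell == EMPTY else cell)
        out.append("\t".join(row) + "\n")
    return "".join(out)
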