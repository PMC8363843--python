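"""Generic materialized views and the benchmark harness.

Three denormalized tables are maintained by full rebuild (drop +
repopulate), matching materialized-view semantics:

* ``mview_ndg_calls`` — one row per genotype call with compiled display
  names, serving both variant- and germplasm-focused queries;
* ``mview_ndg_variants`` — one row per variant location (so multiple
  assemblies per variant cost nothing in the much larger call view), with
  a compound (backbone, fmin) index serving range queries;
* ``mview_phenotype`` — one row per (trait tuple, germplasm, project,
  site-year), averaging quantitative replicates arithmetically and
  reducing qualitative replicates to category counts plus the modal
  category (ties broken to the lexicographically smallest).

The benchmark harness times five named query states — Unfiltered, Range
and Polymorphic genotype-matrix queries; Quantitative Measurement
Distribution and per-genus Summary phenotype queries — through the
mview-backed path and the equivalent direct normalized-join path,
asserting result equality before reporting median timings.
"""
from __future__ import annotations

import json
import statistics
import time
from dataclasses import dataclass, field

from .errors import MviewRefreshError
from .store import Store

_CALL_MVIEW_SQL = """
CREATE TABLE mview_ndg_calls AS
SELECT gc.call_id, gc.variant_id, gc.marker_id, gc.stock_id, gc.project_id, gc.genotype_id,
       v.uniquename AS variant_name, v.subtype AS variant_subtype,
       m.uniquename AS marker_name,
       s.name AS germplasm_name, s.uniquename AS germplasm_uniquename, s.genus AS genus,
       p.name AS project_name,
       g.allele_string, gc.metadata
FROM genotype_call gc
JOIN feature v ON v.feature_id = gc.variant_id
JOIN feature m ON m.feature_id = gc.marker_id
JOIN stock s ON s.stock_id = gc.stock_id
JOIN project p ON p.project_id = gc.project_id
JOIN genotype g ON g.genotype_id = gc.genotype_id
"""

_VARIANT_MVIEW_SQL = """
CREATE TABLE mview_ndg_variants AS
SELECT fl.featureloc_id, v.feature_id AS variant_id, v.uniquename AS variant_name,
       v.subtype AS variant_subtype,
       b.uniquename AS backbone_name, fl.fmin, fl.fmax, fl.strand, fl.assembly
FROM featureloc fl
JOIN feature v ON v.feature_id = fl.feature_id AND v.type = 'variant'
JOIN feature b ON b.feature_id = fl.srcfeature_id
"""


def refresh_call_mview(store: Store) -> int:
    """Rebuild mview_ndg_calls; returns the row count (1:1 with calls)."""
    c = store.conn
    with store.transaction():
        c.execute("DROP TABLE IF EXISTS mview_ndg_calls")
        c.execute(_CALL_MVIEW_SQL)
        c.execute("CREATE INDEX idx_mvc_variant ON mview_ndg_calls (variant_id)")
        c.execute("CREATE INDEX idx_mvc_stock_variant ON mview_ndg_calls (stock_id, variant_id)")
        c.execute("CREATE INDEX idx_mvc_project ON mview_ndg_calls (project_id)")
    return store.count("mview_ndg_calls")


def refresh_variant_mview(store: Store) -> int:
    """Rebuild mview_ndg_variants; one row per variant location."""
    c = store.conn
    with store.transaction():
        c.execute("DROP TABLE IF EXISTS mview_ndg_variants")
        c.execute(_VARIANT_MVIEW_SQL)
        c.execute("CREATE INDEX idx_mvv_backbone_fmin ON mview_ndg_variants (backbone_name, fmin)")
        c.execute("CREATE INDEX idx_mvv_variant ON mview_ndg_variants (variant_id)")
    return store.count("mview_ndg_variants")


def refresh_phenotype_mview(store: Store) -> int:
    """Rebuild mview_phenotype: replicate groups averaged or counted.

    Quantitative groups take the arithmetic mean of replicate values (in
    phenotype_id order, so the float arithmetic is reproducible);
    qualitative groups record category counts and the modal category.
    A non-numeric value inside a quantitative group aborts the refresh
    naming the offending measurement.
    """
    c = store.conn
    rows = c.execute(
        "SELECT ph.phenotype_id, ph.attr_id, ph.assay_id, ph.unit_id, ph.stock_id, ph.project_id,"
        " t.name, t.data_type, m.name, u.name, s.name, s.uniquename, s.genus, p.name,"
        " ph.location, ph.year, ph.value "
        "FROM phenotype ph "
        "JOIN cvterm t ON t.cvterm_id = ph.attr_id "
        "JOIN cvterm m ON m.cvterm_id = ph.assay_id "
        "JOIN cvterm u ON u.cvterm_id = ph.unit_id "
        "JOIN stock s ON s.stock_id = ph.stock_id "
        "JOIN project p ON p.project_id = ph.project_id "
        "ORDER BY ph.phenotype_id"
    ).fetchall()

    groups: dict[tuple, dict] = {}
    for r in rows:
        (pid, attr_id, assay_id, unit_id, stock_id, project_id, trait, dtype,
         method, unit, germ_name, germ_uniq, genus, project, location, year, value) = r
        key = (attr_id, assay_id, unit_id, stock_id, project_id, location, year)
        g = groups.setdefault(
            key,
            {
                "trait_name": trait, "method_name": method, "unit_name": unit,
                "germplasm_name": germ_name, "germplasm_uniquename": germ_uniq,
                "genus": genus, "project_name": project, "data_type": dtype,
                "values": [], "ids": [],
            },
        )
        g["values"].append(value)
        g["ids"].append(pid)

    out = []
    for key, g in groups.items():
        attr_id, assay_id, unit_id, stock_id, project_id, location, year = key
        n = len(g["values"])
        if g["data_type"] == "quantitative":
            floats = []
            for pid, v in zip(g["ids"], g["values"]):
                try:
                    floats.append(float(v))
                except ValueError:
                    raise MviewRefreshError(
                        f"non-numeric value {v!r} in quantitative replicate group "
                        f"(phenotype_id={pid}, trait='{g['trait_name']}')"
                    )
            mean_value = sum(floats) / n
            summary, categories = None, None
        else:
            counts: dict[str, int] = {}
            for v in g["values"]:
                counts[v] = counts.get(v, 0) + 1
            best = max(counts.values())
            summary = min(k for k, v in counts.items() if v == best)
            categories = json.dumps(dict(sorted(counts.items())), sort_keys=True)
            mean_value = None
        out.append(
            (attr_id, assay_id, unit_id, stock_id, project_id,
             g["trait_name"], g["method_name"], g["unit_name"],
             g["germplasm_name"], g["germplasm_uniquename"], g["genus"], g["project_name"],
             location, year, g["data_type"], mean_value, summary, categories, n)
        )

    with store.transaction():
        c.execute("DROP TABLE IF EXISTS mview_phenotype")
        c.execute(
            "CREATE TABLE mview_phenotype ("
            " trait_id INTEGER, method_id INTEGER, unit_id INTEGER,"
            " stock_id INTEGER, project_id INTEGER,"
            " trait_name TEXT, method_name TEXT, unit_name TEXT,"
            " germplasm_name TEXT, germplasm_uniquename TEXT, genus TEXT, project_name TEXT,"
            " location TEXT, year TEXT, data_type TEXT,"
            " mean_value REAL, summary TEXT, categories TEXT, n_replicates INTEGER)"
        )
        c.executemany(
            "INSERT INTO mview_phenotype VALUES (" + ",".join("?" * 19) + ")", out
        )
        c.execute("CREATE INDEX idx_mvp_trait_project ON mview_phenotype (trait_id, project_id)")
        c.execute("CREATE INDEX idx_mvp_stock ON mview_phenotype (stock_id)")
    return len(out)


def refresh_all(store: Store) -> dict:
    return {
        "calls": refresh_call_mview(store),
        "variants": refresh_variant_mview(store),
        "phenotypes": refresh_phenotype_mview(store),
    }


# ---------------------------------------------------------------------------
# Benchmark harness
# ---------------------------------------------------------------------------


@dataclass
class BenchmarkRow:
    query: str
    mview_median_ms: float
    mview_spread_ms: tuple
    direct_median_ms: float
    direct_spread_ms: tuple
    n_result_rows: int
    paths_equal: bool


@dataclass
class BenchmarkResult:
    scale: str
    repetitions: int
    seed: int
    rows: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "scale": self.scale,
                "repetitions": self.repetitions,
                "seed": self.seed,
                "queries": [vars(r) for r in self.rows],
            },
            indent=2,
            default=list,
        )

    def format_table(self) -> str:
        hdr = f"{'query':<14} {'mview ms':>10} {'direct ms':>10} {'rows':>8} {'equal':>6}"
        lines = [hdr, "-" * len(hdr)]
        for r in self.rows:
            lines.append(
                f"{r.query:<14} {r.mview_median_ms:>10.2f} {r.direct_median_ms:>10.2f} "
                f"{r.n_result_rows:>8} {str(r.paths_equal):>6}"
            )
        return "\n".join(lines)


def _time_paths(fn, repetitions: int):
    """Run fn(use_mview) both ways; return results + timing lists (ms)."""
    results, timings = {}, {}
    for use_mview in (True, False):
        samples = []
        result = None
        for _ in range(repetitions):
            t0 = time.perf_counter()
            result = fn(use_mview)
            samples.append((time.perf_counter() - t0) * 1000.0)
        results[use_mview] = result
        timings[use_mview] = samples
    return results, timings


def run_benchmark(
    scale: str = "small",
    repetitions: int = 9,
    seed: int = 1,
    store: Store | None = None,
) -> BenchmarkResult:
    """Seed a store at the given scale and time the five query states.

    Each query runs ``repetitions`` times per path (mview-backed vs direct
    normalized joins); the two paths' results must be identical —
    correctness precedes timing — and medians plus (min, max) spreads are
    reported.  An already-seeded store may be passed to skip seeding.
    """
    from dataclasses import replace

    from . import matrix as mx
    from . import summary as sm
    from .fixtures import PRESETS, seed_store, trait_plan

    spec = PRESETS[scale]
    spec = replace(spec, seed=seed)
    if store is None:
        store = Store()
        seed_store(store, spec)

    germ = spec.sample_names()[: min(7, spec.n_samples)]
    pair = (germ[0], germ[1])
    # range covering the middle half of the first backbone
    bb = spec.backbone_names()[0]
    lo = spec.backbone_length // 4
    hi = 3 * spec.backbone_length // 4
    project = spec.project_name
    trait = next(t["trait"] for t in trait_plan(spec) if t["data_type"] == "quantitative")

    queries = {
        "unfiltered": lambda use_mview: mx.fetch_matrix(
            store, mx.MatrixFilter(germplasm=germ), use_mview=use_mview
        ),
        "range": lambda use_mview: mx.fetch_matrix(
            store, mx.MatrixFilter(germplasm=germ, range=(bb, lo, hi)), use_mview=use_mview
        ),
        "polymorphic": lambda use_mview: mx.fetch_matrix(
            store,
            mx.MatrixFilter(germplasm=germ, polymorphic_pair=pair),
            use_mview=use_mview,
        ),
        "distribution": lambda use_mview: sm.distribution(
            store, trait, project, use_mview=use_mview
        ),
        "summary": lambda use_mview: sm.genus_summary(store, spec.genus, use_mview=use_mview),
    }

    result = BenchmarkResult(scale=scale, repetitions=repetitions, seed=seed)
    for name, fn in queries.items():
        res, timings = _time_paths(fn, repetitions)
        equal = res[True] == res[False]
        if name in ("unfiltered", "range", "polymorphic"):
            n_rows = res[True].total_variants
        elif name == "distribution":
            n_rows = len(res[True].entries)
        else:
            n_rows = len(res[True])
        result.rows.append(
            BenchmarkRow(
                query=name,
                mview_median_ms=statistics.median(timings[True]),
                mview_spread_ms=(min(timings[True]), max(timings[True])),
                direct_median_ms=statistics.median(timings[False]),
                direct_spread_ms=(min(timings[False]), max(timings[False])),
                n_result_rows=n_rows,
                paths_equal=equal,
            )
        )
    return result
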