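"""Chart-ready phenotype summaries.

Computes the data series behind trait distribution displays: replicates
are averaged per germplasm but site-years (location-year combinations of
a field trial) remain separate.  Quantitative traits get the per-site-year
value vector plus box statistics — median, quartiles under the midpoint
convention, and the 95% confidence interval of the median via the
box-plot notch formula median ± 1.58·IQR/√n; violin densities are left to
the renderer, which receives the raw per-germplasm means.  Qualitative
traits get per-site-year category frequencies (one modal category per
germplasm, ties to the lexicographically smallest).  A germplasm of
interest can be highlighted with its own value per site-year.

Every query has an mview-backed and a direct normalized-join form so the
benchmark harness and the equivalence tests can compare them.
"""
from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .errors import ExportFormatError, MissingRecordError
from .store import Store


@dataclass(frozen=True)
class BoxStats:
    median: float
    q1: float
    q3: float
    ci_low: float
    ci_high: float
    n: int


@dataclass
class SiteYearEntry:
    label: str  # "<location> <year>"
    location: str
    year: str
    values: dict  # quantitative: germplasm -> replicate mean; qualitative: category -> frequency
    box: Optional[BoxStats] = None
    highlight: Optional[object] = None  # highlighted germplasm's value or category


@dataclass
class DistributionSeries:
    trait_name: str
    project_name: str
    data_type: str
    highlight_germplasm: Optional[str] = None
    entries: list = field(default_factory=list)


def box_stats(values) -> BoxStats:
    """Median, midpoint-convention quartiles and notch CI of the median."""
    arr = np.asarray(sorted(values), dtype=float)
    q1, median, q3 = (float(q) for q in np.percentile(arr, [25, 50, 75], method="midpoint"))
    n = len(arr)
    half = 1.58 * (q3 - q1) / math.sqrt(n)
    return BoxStats(median, q1, q3, median - half, median + half, n)


def _mode(counter: dict) -> str:
    best = max(counter.values())
    return min(k for k, v in counter.items() if v == best)


def distribution(
    store: Store,
    trait: str,
    project: str,
    highlight_germplasm: Optional[str] = None,
    use_mview: bool = True,
) -> DistributionSeries:
    """Distribution series for one (trait, project), one entry per site-year."""
    if use_mview:
        rows = store.conn.execute(
            "SELECT location, year, germplasm_uniquename, data_type, mean_value, summary "
            "FROM mview_phenotype WHERE trait_name=? AND project_name=? "
            "ORDER BY location, year, germplasm_uniquename",
            (trait, project),
        ).fetchall()
    else:
        raw = store.conn.execute(
            "SELECT ph.location, ph.year, s.uniquename, t.data_type, ph.value "
            "FROM phenotype ph "
            "JOIN cvterm t ON t.cvterm_id = ph.attr_id "
            "JOIN stock s ON s.stock_id = ph.stock_id "
            "JOIN project p ON p.project_id = ph.project_id "
            "WHERE t.name=? AND p.name=? ORDER BY ph.phenotype_id",
            (trait, project),
        ).fetchall()
        groups: dict[tuple, dict] = {}
        for location, year, germ, dtype, value in raw:
            g = groups.setdefault((location, year, germ), {"dtype": dtype, "values": []})
            g["values"].append(value)
        rows = []
        for (location, year, germ), g in groups.items():
            if g["dtype"] == "quantitative":
                vals = [float(v) for v in g["values"]]
                rows.append((location, year, germ, g["dtype"], sum(vals) / len(vals), None))
            else:
                counts: dict[str, int] = {}
                for v in g["values"]:
                    counts[v] = counts.get(v, 0) + 1
                rows.append((location, year, germ, g["dtype"], None, _mode(counts)))
        rows.sort(key=lambda r: (r[0], r[1], r[2]))
    if not rows:
        raise MissingRecordError(
            f"no measurements for trait {trait!r} in project {project!r}"
        )

    data_type = rows[0][3]
    series = DistributionSeries(
        trait_name=trait, project_name=project, data_type=data_type,
        highlight_germplasm=highlight_germplasm,
    )
    by_siteyear: dict[tuple, list] = {}
    for location, year, germ, _, mean_value, summary in rows:
        by_siteyear.setdefault((location, year), []).append((germ, mean_value, summary))
    for (location, year) in sorted(by_siteyear):
        group = by_siteyear[(location, year)]
        entry = SiteYearEntry(
            label=f"{location} {year}", location=location, year=year, values={}
        )
        if data_type == "quantitative":
            entry.values = {germ: mean for germ, mean, _ in group}
            entry.box = box_stats(list(entry.values.values()))
            if highlight_germplasm is not None:
                entry.highlight = entry.values.get(highlight_germplasm)
        else:
            freqs: dict[str, int] = {}
            for germ, _, modal in group:
                freqs[modal] = freqs.get(modal, 0) + 1
                if highlight_germplasm is not None and germ == highlight_germplasm:
                    entry.highlight = modal
            entry.values = dict(sorted(freqs.items()))
        series.entries.append(entry)
    return series


def genus_summary(store: Store, genus: str, use_mview: bool = True) -> dict:
    """Magnitude of phenotypic data for a genus.

    Counts experiments (projects with measurements), traits, germplasm
    with measurements, site-years and total measurements.
    """
    if use_mview:
        row = store.conn.execute(
            "SELECT COUNT(DISTINCT project_id), COUNT(DISTINCT trait_id),"
            " COUNT(DISTINCT stock_id), COUNT(DISTINCT location || '␟' || year),"
            " COALESCE(SUM(n_replicates), 0) "
            "FROM mview_phenotype WHERE genus=?",
            (genus,),
        ).fetchone()
    else:
        row = store.conn.execute(
            "SELECT COUNT(DISTINCT ph.project_id), COUNT(DISTINCT ph.attr_id),"
            " COUNT(DISTINCT ph.stock_id), COUNT(DISTINCT ph.location || '␟' || ph.year),"
            " COUNT(*) "
            "FROM phenotype ph JOIN stock s ON s.stock_id = ph.stock_id WHERE s.genus=?",
            (genus,),
        ).fetchone()
    return {
        "experiments": row[0],
        "traits": row[1],
        "germplasm": row[2],
        "site_years": row[3],
        "measurements": row[4],
    }


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def export_series(series: DistributionSeries, format: str = "json") -> str:
    """Serialize a series for any charting front end (json or csv).

    The CSV form has one row per (site-year, germplasm) for quantitative
    traits and one row per (site-year, category) for qualitative traits;
    box statistics ride only in the JSON form.
    """
    if format == "json":
        return json.dumps(asdict(series), indent=2, sort_keys=True)
    if format == "csv":
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        key = "germplasm" if series.data_type == "quantitative" else "category"
        writer.writerow(["site_year", key, "value"])
        for entry in series.entries:
            for k, v in entry.values.items():
                writer.writerow([entry.label, k, v])
        return buf.getvalue()
    raise ExportFormatError(f"unsupported export format {format!r}")


def parse_series_json(text: str) -> DistributionSeries:
    """Inverse of the JSON form of :func:`export_series`."""
    doc = json.loads(text)
    series = DistributionSeries(
        trait_name=doc["trait_name"],
        project_name=doc["project_name"],
        data_type=doc["data_type"],
        highlight_germplasm=doc.get("highlight_germplasm"),
    )
    for e in doc["entries"]:
        box = BoxStats(**e["box"]) if e.get("box") else None
        series.entries.append(
            SiteYearEntry(
                label=e["label"], location=e["location"], year=e["year"],
                values=e["values"], box=box, highlight=e.get("highlight"),
            )
        )
    return series
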