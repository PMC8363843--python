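"""Two-stage matrix queries, consensus rendering, polymorphic filtering,
allele frequencies and exports."""
import csv
import io
import random

import pytest

from genophen_store import (
    EMPTY,
    ExportFormatError,
    InvalidFilterError,
    MatrixFilter,
    MissingRecordError,
    Store,
    allele_frequencies,
    consensus_call,
    export_matrix,
    fetch_matrix,
    polymorphic_filter,
    refresh_all,
    select_variants,
)
from genophen_store.matrix import render_consensus, consensus_map, _stock_ids
from genophen_store.store import VariantLocation


def _mini_store():
    """Hand-built store: 3 variants x 3 germplasm with known calls."""
    st = Store()
    p = st.get_or_create_project("P")
    st.add_backbone("Chr1")
    stocks = {u: st.get_or_create_germplasm(u, u, "Lens") for u in ("gA", "gB", "gC")}
    variants = {}
    for name, pos in (("v1", 100), ("v2", 150), ("v3", 200)):
        v, m = st.get_or_create_variant_and_marker(name, VariantLocation("Chr1", pos - 1, pos))
        variants[name] = (v, m)

    def call(vname, stock, alleles):
        v, m = variants[vname]
        g = st.canonical_genotype(alleles)
        st.add_call(p.project_id, v.feature_id, m.feature_id, stocks[stock].stock_id, g.genotype_id)

    call("v1", "gA", ["A", "A"])
    call("v1", "gB", ["A", "G"])
    call("v1", "gC", ["G", "G"])
    call("v2", "gA", ["C", "C"])
    call("v2", "gB", ["C", "C"])
    # gC has no call at v2; v3 has calls only for gB
    call("v3", "gB", ["T", "T"])
    refresh_all(st)
    return st


class TestSelectVariants:
    @pytest.mark.parametrize("use_mview", [True, False])
    def test_range_containment_is_1based_inclusive(self, use_mview):
        st = _mini_store()
        flt = MatrixFilter(germplasm=["gA"], range=("Chr1", 100, 150))
        ids, total = select_variants(st, flt, use_mview=use_mview)
        names = {
            st.conn.execute("SELECT uniquename FROM feature WHERE feature_id=?", (i,)).fetchone()[0]
            for i in ids
        }
        assert names == {"v1", "v2"} and total == 2

    def test_range_50_150_includes_pos_100(self):
        st = _mini_store()
        ids, total = select_variants(st, MatrixFilter(germplasm=["gA"], range=("Chr1", 50, 150)))
        assert total == 2  # v1 (100) and v2 (150), not v3 (200)

    def test_empty_germplasm_list_rejected(self):
        st = _mini_store()
        with pytest.raises(InvalidFilterError):
            select_variants(st, MatrixFilter(germplasm=[]))

    def test_unknown_backbone_lists_known_ones(self):
        st = _mini_store()
        with pytest.raises(MissingRecordError, match="Chr1"):
            select_variants(st, MatrixFilter(germplasm=["gA"], range=("ChrX", 1, 10)))

    def test_ordering_by_backbone_then_position(self, seeded):
        st, _ = seeded
        from genophen_store import SMALL

        germ = SMALL.sample_names()[:2]
        ids, _ = select_variants(st, MatrixFilter(germplasm=germ), paginate=False)
        meta = [
            st.conn.execute(
                "SELECT backbone_name, fmin FROM mview_ndg_variants WHERE variant_id=?", (i,)
            ).fetchone()
            for i in ids
        ]
        assert meta == sorted(meta)

    def test_pagination_concatenates_to_full_result(self, seeded):
        st, _ = seeded
        from genophen_store import SMALL

        germ = SMALL.sample_names()[:2]
        full, total = select_variants(
            st, MatrixFilter(germplasm=germ), paginate=False
        )
        paged = []
        page = 1
        while True:
            ids, t = select_variants(st, MatrixFilter(germplasm=germ, page=page, page_size=7))
            assert t == total
            if not ids:
                break
            paged.extend(ids)
            page += 1
        assert paged == full


class TestConsensus:
    def test_single_call_renders_allele_string(self):
        st = _mini_store()
        assert consensus_call(st, "v1", "gA") == "AA"

    def test_no_call_renders_empty(self):
        st = _mini_store()
        assert consensus_call(st, "v2", "gC") == EMPTY

    def test_disagreeing_single_base_calls_render_iupac_union(self, store):
        p = store.get_or_create_project("P")
        store.add_backbone("Chr1")
        v, m1 = store.get_or_create_variant_and_marker(
            "v1", VariantLocation("Chr1", 9, 10), marker_suffix=".a"
        )
        _, m2 = store.get_or_create_variant_and_marker(
            "v1", VariantLocation("Chr1", 9, 10), marker_suffix=".b"
        )
        s = store.get_or_create_germplasm("g", "g", "Lens")
        store.add_call(p.project_id, v.feature_id, m1.feature_id, s.stock_id,
                       store.canonical_genotype(["A", "A"]).genotype_id)
        store.add_call(p.project_id, v.feature_id, m2.feature_id, s.stock_id,
                       store.canonical_genotype(["G", "G"]).genotype_id)
        refresh_all(store)
        assert consensus_call(store, "v1", "g") == "R"

    @pytest.mark.parametrize(
        "strings,expected",
        [
            ({"AA"}, "AA"),
            ({"AA", "GG"}, "R"),
            ({"AC", "GT"}, "N"),
            ({"A,ATG", "AA"}, "A/ATG"),
            (set(), EMPTY),
        ],
    )
    def test_render_consensus_cases(self, strings, expected):
        assert render_consensus(strings) == expected


class TestPolymorphicFilter:
    def test_differing_calls_kept_missing_dropped(self):
        st = _mini_store()
        ids, _ = select_variants(st, MatrixFilter(germplasm=["gA", "gB"]), paginate=False)
        kept = polymorphic_filter(st, ids, ("gA", "gB"))
        names = {
            st.conn.execute("SELECT uniquename FROM feature WHERE feature_id=?", (i,)).fetchone()[0]
            for i in kept
        }
        # v1: AA vs AG differ -> kept; v2: CC vs CC same; v3: gA missing -> dropped
        assert names == {"v1"}

    def test_pair_must_be_in_germplasm_list(self):
        st = _mini_store()
        flt = MatrixFilter(germplasm=["gA"], polymorphic_pair=("gA", "gB"))
        with pytest.raises(InvalidFilterError):
            flt.validate()

    @pytest.mark.parametrize("trial_seed", range(5))
    def test_matches_bruteforce_scan_on_random_matrices(self, trial_seed):
        """Set-based filter equals the exhaustive cell-by-cell definition."""
        rng = random.Random(trial_seed)
        st = Store()
        p = st.get_or_create_project("P")
        st.add_backbone("Chr1")
        stocks = [st.get_or_create_germplasm(f"g{i}", f"g{i}", "Lens") for i in range(6)]
        vids = []
        for i in range(25):
            v, m = st.get_or_create_variant_and_marker(
                f"v{i}", VariantLocation("Chr1", i * 10, i * 10 + 1)
            )
            vids.append(v.feature_id)
            for s in stocks:
                if rng.random() < 0.25:
                    continue  # missing cell
                alleles = [rng.choice("ACGT") for _ in range(2)]
                g = st.canonical_genotype(alleles)
                try:
                    st.add_call(p.project_id, v.feature_id, m.feature_id, s.stock_id, g.genotype_id)
                except Exception:
                    pass
        refresh_all(st)
        pair = ("g0", "g1")
        kept = polymorphic_filter(st, vids, pair)
        sid = _stock_ids(st, list(pair))
        cons = consensus_map(st, vids, sid, use_mview=False)
        brute = [
            v for v in vids
            if cons.get((v, sid[0]), EMPTY) != EMPTY
            and cons.get((v, sid[1]), EMPTY) != EMPTY
            and cons.get((v, sid[0])) != cons.get((v, sid[1]))
        ]
        assert kept == brute

    def test_filter_nesting_is_monotone(self, seeded):
        st, _ = seeded
        from genophen_store import SMALL

        germ = SMALL.sample_names()[:4]
        bb = SMALL.backbone_names()[0]
        unfiltered = fetch_matrix(st, MatrixFilter(germplasm=germ), paginate=False)
        ranged = fetch_matrix(
            st, MatrixFilter(germplasm=germ, range=(bb, 1, SMALL.backbone_length)), paginate=False
        )
        poly = fetch_matrix(
            st,
            MatrixFilter(germplasm=germ, range=(bb, 1, SMALL.backbone_length),
                         polymorphic_pair=(germ[0], germ[1])),
            paginate=False,
        )
        names_u = {v[0] for v in unfiltered.variants}
        names_r = {v[0] for v in ranged.variants}
        names_p = {v[0] for v in poly.variants}
        assert names_p <= names_r <= names_u


class TestAlleleFrequencies:
    def test_counts_each_allele_occurrence(self):
        st = _mini_store()
        # v1: AA, AG, GG -> 3 A and 3 G over 6 alleles
        assert allele_frequencies(st, "v1") == {"A": 0.5, "G": 0.5}

    def test_single_call(self):
        st = _mini_store()
        assert allele_frequencies(st, "v3") == {"T": 1.0}

    def test_no_calls_empty_map(self, store):
        store.add_backbone("Chr1")
        store.get_or_create_variant_and_marker("v1", VariantLocation("Chr1", 0, 1))
        assert allele_frequencies(store, "v1") == {}

    def test_normalization(self, seeded):
        st, res = seeded
        for var in res["vcf_manifest"]["variants"][:10]:
            freqs = allele_frequencies(st, var["name"])
            if freqs:
                assert abs(sum(freqs.values()) - 1.0) < 1e-9

    def test_matches_fixture_manifest_tallies(self, seeded):
        st, res = seeded
        for var in res["vcf_manifest"]["variants"]:
            counts = var["allele_counts"]
            total = sum(counts.values())
            expected = {a: c / total for a, c in counts.items()}
            assert allele_frequencies(st, var["name"]) == pytest.approx(expected)


class TestExports:
    def test_csv_layout_and_roundtrip(self):
        st = _mini_store()
        flt = MatrixFilter(germplasm=["gA", "gB", "gC"])
        text = export_matrix(st, flt, format="csv")
        rows = list(csv.reader(io.StringIO(text)))
        assert rows[0] == ["variant", "backbone", "position", "gA", "gB", "gC"]
        assert len(rows) == 4  # header + 3 variants
        page = fetch_matrix(st, flt, paginate=False)
        for row in rows[1:]:
            name = row[0]
            assert row[3:] == [page.cells[name][g] for g in flt.germplasm]

    def test_hapmap_dialect(self):
        st = _mini_store()
        text = export_matrix(st, MatrixFilter(germplasm=["gA", "gB", "gC"]), format="hapmap")
        lines = text.splitlines()
        header = lines[0].split("\t")
        assert header[:11] == [
            "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
            "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
        ]
        assert header[11:] == ["gA", "gB", "gC"]
        v1 = next(l.split("\t") for l in lines[1:] if l.startswith("v1"))
        assert v1[1] == "A/G"  # observed alleles at v1
        assert v1[6] == "genophen-store"
        assert v1[7] == "NA"
        v2 = next(l.split("\t") for l in lines[1:] if l.startswith("v2"))
        assert v2[13] == "NN"  # gC missing at v2

    def test_unsupported_format_rejected(self):
        st = _mini_store()
        with pytest.raises(ExportFormatError):
            export_matrix(st, MatrixFilter(germplasm=["gA"]), format="xlsx")

    def test_export_covers_all_pages(self, seeded):
        st, _ = seeded
        from genophen_store import SMALL

        flt = MatrixFilter(germplasm=SMALL.sample_names()[:2], page_size=7)
        text = export_matrix(st, flt, format="csv")
        n_rows = len(text.strip().splitlines()) - 1
        _, total = select_variants(st, flt, paginate=False)
        assert n_rows == total > 7
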