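"""Schema initialization, entity get-or-create semantics and genotype
canonicalization in the relational store."""
import sqlite3

import pytest
from hypothesis import given, strategies as st

from genophen_store import (
    DuplicateCallError,
    MissingRecordError,
    Store,
    StoreError,
    UpgradeRequiredError,
    VariantLocation,
    render_allele_string,
    split_allele_string,
)
from genophen_store.store import (
    CHADO_CORE_COLUMNS,
    CHADO_CORE_TABLES,
    EXTENSION_TABLES,
    PHENOTYPE_EXTENSION_COLUMNS,
    SCHEMA_VERSION,
)


class TestInitSchema:
    def test_fresh_store_has_empty_tables(self, store):
        for table in CHADO_CORE_TABLES | EXTENSION_TABLES:
            assert store.count(table) == 0

    def test_reinitialization_is_idempotent(self, tmp_path):
        path = tmp_path / "wh.db"
        s1 = Store(str(path))
        s1.get_or_create_project("P1")
        ddl1 = {r for r in s1.conn.execute("SELECT sql FROM sqlite_master WHERE sql IS NOT NULL")}
        s1.close()
        s2 = Store(str(path))
        ddl2 = {r for r in s2.conn.execute("SELECT sql FROM sqlite_master WHERE sql IS NOT NULL")}
        assert ddl1 == ddl2
        assert s2.count("project") == 1

    def test_schema_version_mismatch_requires_upgrade(self, tmp_path):
        path = tmp_path / "wh.db"
        s = Store(str(path))
        s.conn.execute("UPDATE schema_info SET version=?", (SCHEMA_VERSION + 1,))
        s.conn.commit()
        s.close()
        with pytest.raises(UpgradeRequiredError):
            Store(str(path))

    def test_call_with_unknown_stock_violates_fk(self, store):
        p = store.get_or_create_project("P")
        store.add_backbone("Chr1")
        v, m = store.get_or_create_variant_and_marker(
            "Chr1_10", VariantLocation("Chr1", 9, 10)
        )
        g = store.canonical_genotype(["A", "A"])
        with pytest.raises(sqlite3.IntegrityError):
            store.conn.execute(
                "INSERT INTO genotype_call (project_id, variant_id, marker_id, stock_id, genotype_id)"
                " VALUES (?,?,?,?,?)",
                (p.project_id, v.feature_id, m.feature_id, 424242, g.genotype_id),
            )


class TestGermplasm:
    def test_get_or_create_is_idempotent(self, store):
        a = store.get_or_create_germplasm("CDC Gold AGL", "CDC-Gold-AGL", "Lens")
        b = store.get_or_create_germplasm("CDC Gold AGL", "CDC-Gold-AGL", "Lens")
        assert a.stock_id == b.stock_id
        assert store.count("stock") == 1

    def test_fail_mode_names_the_missing_accession(self, store):
        with pytest.raises(MissingRecordError, match="CDC-Impower-AGL"):
            store.get_or_create_germplasm("x", "CDC-Impower-AGL", "Lens", mode="fail")

    def test_distinct_uniquenames_get_distinct_ids(self, store):
        a = store.get_or_create_germplasm("A", "acc-A", "Lens")
        b = store.get_or_create_germplasm("B", "acc-B", "Lens")
        assert a.stock_id != b.stock_id


class TestVariantAndMarker:
    def test_marker_name_is_variant_plus_suffix(self, store):
        store.add_backbone("LcChr2")
        v, m = store.get_or_create_variant_and_marker(
            "LcChr2_3346700",
            VariantLocation("LcChr2", 3346699, 3346700),
            marker_suffix=".exome",
        )
        assert v.uniquename == "LcChr2_3346700"
        assert m.uniquename == "LcChr2_3346700.exome"
        # typed relationship links marker to variant
        rel = store.conn.execute(
            "SELECT subject_id, object_id, type FROM feature_relationship"
        ).fetchone()
        assert rel == (m.feature_id, v.feature_id, "is_marker_of")

    def test_repeat_call_returns_same_ids(self, store):
        store.add_backbone("LcChr2")
        loc = VariantLocation("LcChr2", 99, 100)
        first = store.get_or_create_variant_and_marker("LcChr2_100", loc)
        second = store.get_or_create_variant_and_marker("LcChr2_100", loc)
        assert first == second
        assert store.count("featureloc") == 1

    def test_fail_mode_raises_for_absent_variant(self, store):
        store.add_backbone("Chr1")
        with pytest.raises(MissingRecordError, match="Chr1_5"):
            store.get_or_create_variant_and_marker(
                "Chr1_5", VariantLocation("Chr1", 4, 5), mode="fail"
            )

    def test_multiple_assemblies_per_variant(self, store):
        store.add_backbone("Chr1")
        store.get_or_create_variant_and_marker(
            "v1", VariantLocation("Chr1", 9, 10, assembly="asm1")
        )
        store.get_or_create_variant_and_marker(
            "v1", VariantLocation("Chr1", 19, 20, assembly="asm2")
        )
        assert store.count("featureloc") == 2

    def test_conflicting_location_for_same_key_raises(self, store):
        store.add_backbone("Chr1", residues="ACGTACGTACGT")
        store.get_or_create_variant_and_marker("v1", VariantLocation("Chr1", 2, 3))
        with pytest.raises(StoreError, match="conflicting location"):
            store.get_or_create_variant_and_marker("v1", VariantLocation("Chr1", 2, 5))

    def test_location_beyond_backbone_length_rejected(self, store):
        store.add_backbone("Chr1", residues="ACGT")
        with pytest.raises(StoreError, match="exceeds"):
            store.get_or_create_variant_and_marker("v1", VariantLocation("Chr1", 2, 10))


class TestCanonicalGenotype:
    @pytest.mark.parametrize(
        "alleles,expected",
        [
            (["G", "A"], "AG"),
            (["A", "G"], "AG"),
            (["A", "A"], "AA"),
            (["A"], "A"),
            (["A", "ATG"], "A,ATG"),
            (["T", "G", "A"], "AGT"),
        ],
    )
    def test_canonical_rendering(self, store, alleles, expected):
        assert store.canonical_genotype(alleles).allele_string == expected

    def test_order_insensitive_sharing(self, store):
        a = store.canonical_genotype(["G", "A"])
        b = store.canonical_genotype(["A", "G"])
        assert a.genotype_id == b.genotype_id
        assert store.count("genotype") == 1

    def test_empty_allele_list_rejected(self, store):
        with pytest.raises(StoreError, match="skipped"):
            store.canonical_genotype([])

    @given(st.lists(st.sampled_from(["A", "C", "G", "T", "-", "AT", "GGC"]), min_size=1, max_size=4))
    def test_rendering_is_permutation_invariant_and_splittable(self, alleles):
        rendered = render_allele_string(alleles)
        assert rendered == render_allele_string(list(reversed(alleles)))
        if len(alleles) == 1 and len(alleles[0]) > 1:
            # documented corner: a haploid multi-base call renders as the
            # bare allele and is not distinguishable from the concatenated
            # single-base multiset with the same letters
            assert rendered == alleles[0]
        else:
            assert sorted(split_allele_string(rendered)) == sorted(a.upper() for a in alleles)


class TestDuplicateCallPolicy:
    def _setup(self, store):
        p = store.get_or_create_project("P")
        store.add_backbone("Chr1")
        v, m = store.get_or_create_variant_and_marker("Chr1_10", VariantLocation("Chr1", 9, 10))
        s = store.get_or_create_germplasm("g", "g", "Lens")
        g = store.canonical_genotype(["A", "A"])
        return p, v, m, s, g

    def test_reject_policy_raises_and_keeps_count(self, store):
        p, v, m, s, g = self._setup(store)
        store.add_call(p.project_id, v.feature_id, m.feature_id, s.stock_id, g.genotype_id)
        with pytest.raises(DuplicateCallError):
            store.add_call(p.project_id, v.feature_id, m.feature_id, s.stock_id, g.genotype_id)
        assert store.count("genotype_call") == 1

    def test_upsert_policy_replaces(self):
        store = Store(duplicate_call_policy="upsert")
        p, v, m, s, g = self._setup(store)
        store.add_call(p.project_id, v.feature_id, m.feature_id, s.stock_id, g.genotype_id)
        g2 = store.canonical_genotype(["A", "G"])
        store.add_call(p.project_id, v.feature_id, m.feature_id, s.stock_id, g2.genotype_id)
        assert store.count("genotype_call") == 1
        stored = store.conn.execute("SELECT genotype_id FROM genotype_call").fetchone()[0]
        assert stored == g2.genotype_id


class TestBackwardCompatibility:
    def test_dropping_extensions_leaves_core_shape(self, store):
        """Removing genotype_call and the three added phenotype columns must
        leave every declared Chado-core table and column intact."""
        tables = store.tables() - {"schema_info"}
        assert EXTENSION_TABLES <= tables
        assert tables - EXTENSION_TABLES >= CHADO_CORE_TABLES
        for table, core_cols in CHADO_CORE_COLUMNS.items():
            assert core_cols <= store.table_columns(table), table
        remaining = store.table_columns("phenotype") - PHENOTYPE_EXTENSION_COLUMNS
        assert CHADO_CORE_COLUMNS["phenotype"] <= remaining
        assert PHENOTYPE_EXTENSION_COLUMNS <= store.table_columns("phenotype")

    def test_referential_integrity_sweep(self, tiny_store):
        """Every foreign key in calls and measurements resolves."""
        st, _ = tiny_store
        for sql in (
            "SELECT COUNT(*) FROM genotype_call gc LEFT JOIN project p USING (project_id) WHERE p.project_id IS NULL",
            "SELECT COUNT(*) FROM genotype_call gc LEFT JOIN feature v ON v.feature_id=gc.variant_id WHERE v.feature_id IS NULL",
            "SELECT COUNT(*) FROM genotype_call gc LEFT JOIN feature m ON m.feature_id=gc.marker_id WHERE m.feature_id IS NULL",
            "SELECT COUNT(*) FROM genotype_call gc LEFT JOIN stock s USING (stock_id) WHERE s.stock_id IS NULL",
            "SELECT COUNT(*) FROM genotype_call gc LEFT JOIN genotype g USING (genotype_id) WHERE g.genotype_id IS NULL",
            "SELECT COUNT(*) FROM phenotype ph LEFT JOIN stock s USING (stock_id) WHERE s.stock_id IS NULL",
            "SELECT COUNT(*) FROM phenotype ph LEFT JOIN cvterm t ON t.cvterm_id=ph.attr_id WHERE t.cvterm_id IS NULL",
        ):
            assert st.conn.execute(sql).fetchone()[0] == 0

    def test_genotype_deduplication_matches_distinct_multisets(self, tiny_store):
        """genotype rows == distinct canonical allele multisets among calls."""
        st, _ = tiny_store
        distinct_used = st.conn.execute(
            "SELECT COUNT(DISTINCT g.allele_string) FROM genotype_call gc "
            "JOIN genotype g USING (genotype_id)"
        ).fetchone()[0]
        assert st.count("genotype") == distinct_used


def test_store_config_roundtrip(tmp_path):
    cfg = tmp_path / "store.yaml"
    cfg.write_text(
        "engine: sqlite\n"
        f"path: {tmp_path / 'wh.db'}\n"
        "duplicate_call_policy: upsert\n"
        "marker_suffix: '.exome'\n"
        "batch_size: 42\n"
    )
    s = Store.from_config(cfg)
    assert s.duplicate_call_policy == "upsert"
    assert s.marker_suffix == ".exome"
    assert s.batch_size == 42
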