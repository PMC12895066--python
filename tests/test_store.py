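"""Store lifecycle, bulk imports, sunburst counts, deletion, audit."""

import pytest

from genomedesk import (
    audit_store, bulk_import_metadata, bulk_import_regulons, delete_genome,
    import_genbank_file, open_store, taxonomy_sunburst,
)
from genomedesk.errors import NotFoundError, StoreError, ValidationError
from genomedesk.store import add_strain, load_taxonomy, taxon_lineage

from conftest import MINI_TAXONOMY, write_genbank


class TestOpenStore:
    def test_create_yields_empty_store(self, tmp_path):
        store = open_store(tmp_path / "s.sqlite", create=True)
        assert store.genome_ids() == []
        assert store.schema_version == 1

    def test_reopen_preserves_entity_counts(self, five_store, tmp_path):
        import shutil
        store, _, _ = five_store
        db = tmp_path / "again.sqlite"
        shutil.copy(store.path, db)
        reopened = open_store(db)
        assert reopened.entity_counts() == store.entity_counts()

    def test_random_bytes_is_invalid_store(self, tmp_path):
        bad = tmp_path / "garbage.sqlite"
        bad.write_bytes(b"\x13\x37" * 600)
        with pytest.raises(StoreError, match="invalid store"):
            open_store(bad)

    def test_missing_file_is_invalid(self, tmp_path):
        with pytest.raises(StoreError, match="invalid store"):
            open_store(tmp_path / "nope.sqlite")

    def test_newer_schema_is_unsupported(self, tmp_path):
        db = tmp_path / "future.sqlite"
        store = open_store(db, create=True)
        with store.conn:
            store.conn.execute("UPDATE meta SET value = '99' WHERE key = 'schema_version'")
        store.close()
        with pytest.raises(StoreError, match="unsupported schema"):
            open_store(db)


class TestMetadataImport:
    def _tsv(self, tmp_path, rows):
        path = tmp_path / "meta.tsv"
        lines = ["entity_name\tkey\tsource\tvalue"] + rows
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return path

    def test_valid_rows_imported(self, empty_store, tmp_path):
        for sid in ("S1", "S2"):
            add_strain(empty_store, sid)
        tsv = self._tsv(tmp_path, ["S1\tisolation_site\tfield notes\tsoil",
                                   "S1\tmedium\tlab\tLB",
                                   "S2\tisolation_site\tfield notes\tpond"])
        report = bulk_import_metadata(empty_store, "strain", tsv)
        assert report.n_imported == 3
        assert report.skipped == []

    def test_unknown_entity_reported_not_imported(self, empty_store, tmp_path):
        add_strain(empty_store, "S1")
        tsv = self._tsv(tmp_path, ["S1\tk\tsrc\tv", "GHOST\tk\tsrc\tv"])
        report = bulk_import_metadata(empty_store, "strain", tsv)
        assert report.n_imported == 1
        assert report.skipped == ["GHOST"]

    def test_empty_file_imports_nothing(self, empty_store, tmp_path):
        tsv = self._tsv(tmp_path, [])
        assert bulk_import_metadata(empty_store, "strain", tsv).n_imported == 0

    def test_all_rows_malformed_fails(self, empty_store, tmp_path):
        tsv = self._tsv(tmp_path, ["\t\tsrc\tv", "\tk\tsrc\tv"])
        with pytest.raises(ValidationError, match="every row malformed"):
            bulk_import_metadata(empty_store, "strain", tsv)

    def test_bad_kind_rejected(self, empty_store, tmp_path):
        with pytest.raises(ValidationError):
            bulk_import_metadata(empty_store, "genome", self._tsv(tmp_path, []))


class TestRegulonImport:
    @pytest.fixture
    def store_with_genome(self, empty_store, tmp_path):
        seq = "ATGAAAACCTAA" + "C" * 20 + "ATGGTTGGTTGA" + "A" * 20
        write_genbank(tmp_path / "g.gbk", "chr1", seq, [
            (0, 12, 1, {"locus_tag": ["reg1"], "translation": ["MKT"]}),
            (32, 44, 1, {"locus_tag": ["tgt1"], "translation": ["MVG"]}),
        ])
        import_genbank_file(empty_store, tmp_path / "g.gbk", genome_id="G1")
        return empty_store

    def _tsv(self, tmp_path, rows):
        path = tmp_path / "reg.tsv"
        header = ("regulon_name\tgenome\tregulator_locus_tag\ttarget_locus_tag\t"
                  "site_contig\tsite_start\tsite_end\tsite_strand\tsite_sequence")
        path.write_text("\n".join([header] + rows) + "\n", encoding="utf-8")
        return path

    def test_rows_group_into_one_regulon(self, store_with_genome, tmp_path):
        tsv = self._tsv(tmp_path, ["RegA\tG1\treg1\ttgt1\t\t\t\t\t",
                                   "RegA\tG1\treg1\treg1\t\t\t\t\t"])
        report = bulk_import_regulons(store_with_genome, tsv)
        assert report.n_imported == 2
        n_regulons = store_with_genome.conn.execute(
            "SELECT COUNT(*) FROM regulons").fetchone()[0]
        n_targets = store_with_genome.conn.execute(
            "SELECT COUNT(*) FROM regulon_targets").fetchone()[0]
        assert (n_regulons, n_targets) == (1, 2)

    def test_site_length_invariant_enforced(self, store_with_genome, tmp_path):
        good = self._tsv(tmp_path, ["RegA\tG1\treg1\ttgt1\tchr1\t20\t26\t1\tCCCCCC"])
        report = bulk_import_regulons(store_with_genome, good)
        assert report.n_imported == 1
        site = store_with_genome.conn.execute("SELECT * FROM sites").fetchone()
        assert len(site["sequence"]) == site["end"] - site["start"]
        bad = self._tsv(tmp_path, ["RegB\tG1\treg1\ttgt1\tchr1\t20\t26\t1\tCC"])
        report = bulk_import_regulons(store_with_genome, bad)
        assert report.n_imported == 0 and len(report.skipped) == 1

    def test_unknown_locus_tag_skipped(self, store_with_genome, tmp_path):
        tsv = self._tsv(tmp_path, ["RegA\tG1\treg1\tghost\t\t\t\t\t"])
        report = bulk_import_regulons(store_with_genome, tsv)
        assert report.n_imported == 0
        assert len(report.skipped) == 1


class TestSunburst:
    def test_two_genomes_same_genus_different_species(self, empty_store, tmp_path):
        load_taxonomy(empty_store, MINI_TAXONOMY)
        for gid, organism, taxon in (("gA", "Escherichia coli", "562"),
                                     ("gB", "Salmonella enterica", "28901")):
            write_genbank(tmp_path / f"{gid}.gbk", f"{gid}_c", "ATGAAAACCTAA",
                          [(0, 12, 1, {"locus_tag": ["x1"], "translation": ["MKT"]})],
                          organism=organism, taxon_id=taxon)
            import_genbank_file(empty_store, tmp_path / f"{gid}.gbk", genome_id=gid)
        root = taxonomy_sunburst(empty_store)
        assert root["count"] == 2

        def find(node, name):
            if node["name"] == name:
                return node
            for c in node["children"]:
                got = find(c, name)
                if got:
                    return got
        family = find(root, "Enterobacteriaceae")
        assert family["count"] == 2
        assert find(root, "Escherichia coli")["count"] == 1
        assert find(root, "Salmonella enterica")["count"] == 1

    def test_empty_store_has_zero_root_count(self, empty_store):
        root = taxonomy_sunburst(empty_store)
        assert root["count"] == 0 and root["children"] == []

    def test_counts_match_bruteforce_lineage_tally(self, five_store):
        store, manifest, _ = five_store
        # independent tally: walk each genome's lineage directly
        tally = {}
        for gid in store.genome_ids():
            taxon_id = store.conn.execute(
                "SELECT taxon_id FROM genomes WHERE genome_id = ?", (gid,)).fetchone()[0]
            for node in taxon_lineage(store, taxon_id):
                tally[node["name"]] = tally.get(node["name"], 0) + 1

        def walk(node):
            if node["rank"] not in ("root", "genome"):
                assert node["count"] == tally[node["name"]], node["name"]
            children_sum = sum(c["count"] for c in node["children"])
            if node["children"]:
                assert children_sum == node["count"]
            for c in node["children"]:
                walk(c)
        root = taxonomy_sunburst(store)
        assert root["count"] == len(manifest["genomes"])
        walk(root)


class TestDeleteGenome:
    def test_deleting_only_genome_removes_orphan_proteins(self, empty_store, tmp_path):
        write_genbank(tmp_path / "g.gbk", "c1", "ATGAAAACCTAA",
                      [(0, 12, 1, {"locus_tag": ["x"], "translation": ["MKT"]})])
        import_genbank_file(empty_store, tmp_path / "g.gbk", genome_id="G1")
        report = delete_genome(empty_store, "G1")
        assert report["proteins"] == 1
        assert empty_store.entity_counts()["proteins"] == 0
        assert audit_store(empty_store) == []

    def test_shared_protein_retained(self, empty_store, tmp_path):
        write_genbank(tmp_path / "g.gbk", "c1", "ATGAAAACCTAA",
                      [(0, 12, 1, {"locus_tag": ["x"], "translation": ["MKT"]})])
        import_genbank_file(empty_store, tmp_path / "g.gbk", genome_id="G1")
        import_genbank_file(empty_store, tmp_path / "g.gbk", genome_id="G2")
        assert empty_store.entity_counts()["proteins"] == 1
        delete_genome(empty_store, "G1")
        assert empty_store.entity_counts()["proteins"] == 1
        assert audit_store(empty_store) == []

    def test_delete_then_reimport_is_identity(self, five_store_copy):
        from genomedesk import assign_orthologs, load_reference, predict_operons
        store, manifest, coll = five_store_copy
        gid = manifest["genomes"][0]
        before = store.entity_counts()
        hashes_before = store.protein_hashes()
        delete_genome(store, gid)
        import_genbank_file(store, coll / f"{gid}.gbk")
        ref = load_reference(coll / manifest["reference"])
        assign_orthologs(store, ref, gid)
        predict_operons(store, gid)
        assert store.entity_counts() == before
        assert store.protein_hashes() == hashes_before
        assert audit_store(store) == []

    def test_unknown_genome_not_found(self, empty_store):
        with pytest.raises(NotFoundError, match="not found"):
            delete_genome(empty_store, "ghost")


def test_loaded_collection_passes_audit(five_store):
    store, _, _ = five_store
    assert audit_store(store) == []
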