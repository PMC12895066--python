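"""Similarity ranking vs a DP oracle, NJ topology recovery, neighborhoods,
functional profiles, conserved operons/regulons."""

import itertools
import random

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from genomedesk import (
    build_neighborhood, bulk_import_regulons, conserved_operons,
    conserved_regulons, functional_profile, import_genbank_file,
    load_reference, assign_orthologs, similar_proteins,
)
from genomedesk.compare import (
    FunctionalProfile, GeneGlyph, NeighborhoodRow, NeighborhoodView,
    guide_tree, render_svg,
)
from genomedesk.errors import ValidationError

from conftest import read_truth_gene_og, write_genbank

BLOSUM62 = substitution_matrices.load("BLOSUM62")
NEG = float("-inf")


def gotoh_score(a, b, open_cost=11, extend_cost=1):
    """Independent global affine-gap DP (first gap residue costs ``open_cost``,
    each further residue ``extend_cost``)."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = -open_cost - (i - 1) * extend_cost
    for j in range(1, m + 1):
        Iy[0][j] = -open_cost - (j - 1) * extend_cost
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = BLOSUM62[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s
            Ix[i][j] = max(M[i - 1][j] - open_cost, Ix[i - 1][j] - extend_cost,
                           Iy[i - 1][j] - open_cost)
            Iy[i][j] = max(M[i][j - 1] - open_cost, Iy[i][j - 1] - extend_cost,
                           Ix[i][j - 1] - open_cost)
    return max(M[n][m], Ix[n][m], Iy[n][m])


def test_dp_oracle_agrees_with_alignment_backend():
    from genomedesk.compare import make_aligner
    rng = random.Random(42)
    aligner = make_aligner()
    aas = "ACDEFGHIKLMNPQRSTVWY"
    for _ in range(20):
        a = "".join(rng.choice(aas) for _ in range(rng.randint(5, 40)))
        b = "".join(rng.choice(aas) for _ in range(rng.randint(5, 40)))
        assert aligner.score(a, b) == pytest.approx(gotoh_score(a, b))


def _family_store(store, tmp_path, proteins, og="OGF01"):
    """One tiny genome per protein, all assigned to one ortholog group."""
    for i, aa in enumerate(proteins):
        nt = "ATG" + "GCA" * (len(aa) - 1) + "TAA"
        write_genbank(tmp_path / f"m{i}.gbk", f"m{i}_c", nt,
                      [(0, len(nt), 1,
                        {"locus_tag": [f"m{i}_g"], "translation": [aa]})])
        import_genbank_file(store, tmp_path / f"m{i}.gbk", genome_id=f"m{i}")
    lines = ["protein_seq\tog_id\tlevel\tcog_category"]
    lines += [f"{aa}\t{og}\tBacteria\tJ" for aa in set(proteins)]
    ref_path = tmp_path / "fam_ref.tsv"
    ref_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    ref = load_reference(ref_path)
    for i in range(len(proteins)):
        assign_orthologs(store, ref, f"m{i}")
    return store


class TestSimilarProteins:
    def test_lonely_anchor_returns_only_itself(self, empty_store, tmp_path):
        _family_store(empty_store, tmp_path, ["MKTAYIAKQR"])
        hits = similar_proteins(empty_store, "m0", "m0_g", max_n=10)
        assert len(hits) == 1 and hits[0].normalized_distance == 0.0

    def test_identical_candidate_has_distance_zero(self, empty_store, tmp_path):
        _family_store(empty_store, tmp_path, ["MKTAYIAKQR", "MKTAYIAKQR"])
        hits = similar_proteins(empty_store, "m0", "m0_g", max_n=10)
        assert [h.genome_id for h in hits] == ["m0", "m1"]
        assert hits[1].normalized_distance == 0.0

    def test_ranking_matches_dp_oracle(self, empty_store, tmp_path):
        base = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQV"[:56]
        rng = random.Random(9)
        members = [base]
        for k in (1, 3, 6, 10, 15):  # planted mutation counts
            seq = list(base)
            for pos in rng.sample(range(1, len(base)), k):
                seq[pos] = rng.choice("ACDEFGHIKLMNPQRSTVWY".replace(seq[pos], ""))
            members.append("".join(seq))
        _family_store(empty_store, tmp_path, members)
        hits = similar_proteins(empty_store, "m0", "m0_g", max_n=10)
        oracle_scores = {f"m{i}": gotoh_score(base, aa) for i, aa in enumerate(members)}
        expected = ["m0"] + sorted(
            (g for g in oracle_scores if g != "m0"),
            key=lambda g: (-oracle_scores[g], g))
        assert [h.genome_id for h in hits] == expected
        for h in hits:
            assert h.score == pytest.approx(oracle_scores[h.genome_id])

    def test_max_n_bounds_enforced(self, empty_store, tmp_path):
        _family_store(empty_store, tmp_path, ["MKTAYIAKQR"])
        for bad in (9, 0, 201):
            with pytest.raises(ValidationError, match="max_n"):
                similar_proteins(empty_store, "m0", "m0_g", max_n=bad)

    def test_max_n_truncates(self, empty_store, tmp_path):
        _family_store(empty_store, tmp_path, ["MKTAYIAKQR"] * 15)
        hits = similar_proteins(empty_store, "m0", "m0_g", max_n=10)
        assert len(hits) == 10


def _tree_splits(tree):
    tips = frozenset(t.name for t in tree.tips())
    splits = set()
    for node in tree.traverse():
        if node.is_tip() or node is tree:
            continue
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(tips) - 1:
            splits.add(min(side, tips - side, key=sorted))
    return splits


def _additive_distances(split, lengths):
    """4-leaf tree distances: split ((A,B),(C,D)) with branch lengths
    a, b, c, d and internal m."""
    (A, B), (C, D) = split
    a, b, c, d, m = lengths
    ids = [A, B, C, D]
    dist = {frozenset((A, B)): a + b, frozenset((C, D)): c + d,
            frozenset((A, C)): a + m + c, frozenset((A, D)): a + m + d,
            frozenset((B, C)): b + m + c, frozenset((B, D)): b + m + d}
    mat = np.zeros((4, 4))
    for i, x in enumerate(ids):
        for j, y in enumerate(ids):
            if i != j:
                mat[i, j] = dist[frozenset((x, y))]
    return ids, mat


def bruteforce_quartet(ids, mat):
    """Pick the quartet split by the four-point condition (smallest pair-sum)."""
    i = {x: k for k, x in enumerate(ids)}
    A, B, C, D = ids
    sums = {
        frozenset((frozenset((A, B)), frozenset((C, D)))):
            mat[i[A], i[B]] + mat[i[C], i[D]],
        frozenset((frozenset((A, C)), frozenset((B, D)))):
            mat[i[A], i[C]] + mat[i[B], i[D]],
        frozenset((frozenset((A, D)), frozenset((B, C)))):
            mat[i[A], i[D]] + mat[i[B], i[C]],
    }
    return min(sums, key=sums.get)


class TestGuideTree:
    def test_two_leaves_split_distance_at_midpoint(self):
        tree = guide_tree(["x", "y"], np.array([[0, 0.4], [0.4, 0]]))
        tips = {t.name: t.length for t in tree.tips()}
        assert tips == {"x": pytest.approx(0.2), "y": pytest.approx(0.2)}

    @pytest.mark.parametrize("seed", range(8))
    def test_recovers_planted_additive_quartets(self, seed):
        rng = random.Random(seed)
        lengths = [rng.uniform(0.05, 0.5) for _ in range(5)]
        ids, mat = _additive_distances((("A", "B"), ("C", "D")), lengths)
        tree = guide_tree(ids, mat)
        # our tree must display the AB|CD split and agree with the
        # independent four-point oracle
        oracle = bruteforce_quartet(ids, mat)
        assert frozenset((frozenset("AB"), frozenset("CD"))) == oracle
        splits = _tree_splits(tree)
        assert splits <= {frozenset("AB"), frozenset("CD")} and splits

    def test_recovers_planted_five_leaf_caterpillar(self):
        # ((A:.1,B:.2):.15,(C:.1,(D:.05,E:.07):.12):.2) — additive by construction
        ids = list("ABCDE")
        paths = {"A": [".r", "ab"], "B": [".r", "ab"], "C": [".r", "cde"],
                 "D": [".r", "cde", "de"], "E": [".r", "cde", "de"]}
        blen = {("A", "ab"): 0.1, ("B", "ab"): 0.2, ("C", "cde"): 0.1,
                ("D", "de"): 0.05, ("E", "de"): 0.07}
        inner = {"ab": 0.15, "cde": 0.2, "de": 0.12}

        def dist(x, y):
            px, py = paths[x][1:], paths[y][1:]
            shared = set(px) & set(py)
            d = blen[(x, px[-1])] + blen[(y, py[-1])]
            # sorted: float summation order must not depend on set hashing
            d += sum(inner[e] for e in sorted(set(px) ^ set(py)))
            return d
        mat = np.zeros((5, 5))
        for i, x in enumerate(ids):
            for j, y in enumerate(ids):
                if i != j:
                    mat[i, j] = dist(x, y)
        tree = guide_tree(ids, mat)
        splits = _tree_splits(tree)
        # the two internal edges of the true topology: AB|CDE and DE|ABC
        assert splits == {frozenset("AB"), frozenset("ABC")}
        # path distances in the NJ tree reproduce the additive inputs
        tipmap = {t.name: t for t in tree.tips()}
        for x, y in itertools.combinations(ids, 2):
            assert tipmap[x].distance(tipmap[y]) == pytest.approx(dist(x, y), abs=1e-9)

    def test_identical_sequences_give_zero_tree(self):
        tree = guide_tree(["a", "b", "c", "d"], np.zeros((4, 4)))
        tips = list(tree.tips())
        for x, y in itertools.combinations(tips, 2):
            assert x.distance(y) == pytest.approx(0.0)

    def test_single_leaf(self):
        tree = guide_tree(["only"], np.zeros((1, 1)))
        assert [t.name for t in tree.tips()] or tree.name == "only"


class TestNeighborhood:
    def test_five_rows_with_consistent_colors(self, five_store):
        store, manifest, coll = five_store
        anchor_genome = manifest["genomes"][0]
        view = build_neighborhood(store, anchor_genome, f"{anchor_genome}_0001",
                                  max_n=10, window_bp=10_000)
        assert len(view.rows) == 5
        assert {r.genome_id for r in view.rows} == set(manifest["genomes"])
        # the anchor's own family is color 0 in every row it appears
        truth = read_truth_gene_og(coll, manifest)
        og_of = {(r["genome"], r["locus_tag"]): r["og_id"] for r in truth}
        anchor_og = og_of[(anchor_genome, f"{anchor_genome}_0001")]
        assert view.colors[anchor_og] == 0
        # identical og -> identical color everywhere; og->color is a bijection
        seen = {}
        for row in view.rows:
            for g in row.genes:
                truth_og = og_of[(row.genome_id, g.locus_tag)] or None
                assert g.og_id == truth_og
                if g.og_id is not None:
                    assert g.color_index == view.colors[g.og_id]
                    seen.setdefault(g.og_id, g.color_index)
        assert len(set(seen.values())) == len(seen)

    def test_planted_conserved_block_shares_colors_across_all_rows(self, five_store):
        store, manifest, _ = five_store
        anchor_genome = manifest["genomes"][0]
        view = build_neighborhood(store, anchor_genome, f"{anchor_genome}_0001",
                                  max_n=10, window_bp=10_000)
        block = manifest["neighborhood_block_ogs"]
        for row in view.rows:
            row_ogs = {g.og_id for g in row.genes}
            assert set(block) <= row_ogs, f"block missing in row {row.genome_id}"

    def test_tree_leaf_order_equals_row_order(self, five_store):
        from skbio import TreeNode
        import io
        store, manifest, _ = five_store
        anchor_genome = manifest["genomes"][1]
        view = build_neighborhood(store, anchor_genome, f"{anchor_genome}_0002",
                                  max_n=10)
        tree = TreeNode.read(io.StringIO(view.tree_newick))
        assert [t.name for t in tree.tips()] == \
            [f"{r.genome_id}|{r.locus_tag}" for r in view.rows]

    def test_minus_strand_hit_mirrors_row(self, empty_store, tmp_path):
        # anchor on the minus strand with a neighbor upstream (left): after
        # reorientation the neighbor must appear to the anchor's right and
        # the anchor must point rightward (+1).
        seq = "ATGGTTGGTTGA" + "C" * 88 + "TTAGGTTTTCAT" + "A" * 20
        write_genbank(tmp_path / "g.gbk", "c1", seq, [
            (0, 12, 1, {"locus_tag": ["nbr"], "translation": ["MVG"]}),
            (100, 112, -1, {"locus_tag": ["anchor"], "translation": ["MKT"]})])
        import_genbank_file(empty_store, tmp_path / "g.gbk", genome_id="G1")
        ref = tmp_path / "ref.tsv"
        ref.write_text("protein_seq\tog_id\tlevel\nMKT\tOGA\tBacteria\n"
                       "MVG\tOGB\tBacteria\n", encoding="utf-8")
        assign_orthologs(empty_store, load_reference(ref), "G1")
        view = build_neighborhood(empty_store, "G1", "anchor", max_n=10,
                                  window_bp=2000)
        row = view.rows[0]
        by_tag = {g.locus_tag: g for g in row.genes}
        assert by_tag["anchor"].strand == 1
        assert by_tag["nbr"].start > by_tag["anchor"].start

    def test_view_building_is_idempotent(self, five_store):
        store, manifest, _ = five_store
        g = manifest["genomes"][2]
        a = build_neighborhood(store, g, f"{g}_0001", max_n=10)
        b = build_neighborhood(store, g, f"{g}_0001", max_n=10)
        assert a.to_dict() == b.to_dict() and a.tree_newick == b.tree_newick

    def test_svg_renders_all_rows(self, five_store):
        store, manifest, _ = five_store
        g = manifest["genomes"][0]
        view = build_neighborhood(store, g, f"{g}_0001", max_n=10)
        svg = render_svg(view)
        assert svg.startswith("<svg") and svg.count("<polygon") >= len(view.rows)


def _view_from_cogs(cog_lists):
    rows = [NeighborhoodRow(gene_id=f"r{i}", genome_id=f"g{i}", locus_tag=f"l{i}",
                            genes=[GeneGlyph(locus_tag=f"l{i}_{j}", start=0, end=10,
                                             strand=1, og_id=None, color_index=None,
                                             cog=c)
                                   for j, c in enumerate(cogs)])
            for i, cogs in enumerate(cog_lists)]
    return NeighborhoodView(anchor_gene_id="r0", og_level="Bacteria",
                            window_bp=1000, rows=rows, tree_newick=";")


class TestFunctionalProfile:
    def test_single_category(self):
        profile = functional_profile(_view_from_cogs([["J", "J"], ["J"]]))
        assert profile.entries == [("J", 3)] and profile.total == 3

    def test_multiletter_counts_each_letter(self):
        profile = functional_profile(_view_from_cogs([["KT"]]))
        assert dict(profile.entries) == {"K": 1, "T": 1} and profile.total == 2

    def test_unlabeled_counts_as_unclassified(self):
        profile = functional_profile(_view_from_cogs([[None, "J"]]))
        assert dict(profile.entries) == {"unclassified": 1, "J": 1}

    def test_fixture_profile_equals_hand_tally(self, five_store):
        store, manifest, _ = five_store
        g = manifest["genomes"][0]
        view = build_neighborhood(store, g, f"{g}_0001", max_n=10)
        tally = {}
        for row in view.rows:
            for glyph in row.genes:
                letters = list(glyph.cog) if glyph.cog else ["unclassified"]
                for letter in letters:
                    tally[letter] = tally.get(letter, 0) + 1
        profile = functional_profile(view)
        assert dict(profile.entries) == tally
        assert profile.total == sum(tally.values())


class TestConservedOperons:
    def test_identical_planted_operons_share_all_ogs(self, five_store):
        store, manifest, _ = five_store
        g0 = manifest["genomes"][0]
        op = store.conn.execute(
            "SELECT operon_id FROM operons WHERE genome_id = ? ORDER BY start LIMIT 1",
            (g0,)).fetchone()[0]
        size = store.conn.execute(
            "SELECT COUNT(*) FROM operon_genes WHERE operon_id = ?", (op,)).fetchone()[0]
        results = conserved_operons(store, op, min_shared=2)
        assert len(results) == len(manifest["genomes"]) - 1
        assert all(n == size for _, n in results)

    def test_min_shared_bound_excludes(self, five_store):
        store, manifest, _ = five_store
        g0 = manifest["genomes"][0]
        # pick the planted 3-gene operon: min_shared=4 must return nothing
        for op_row in store.conn.execute(
                "SELECT operon_id FROM operons WHERE genome_id = ?", (g0,)):
            size = store.conn.execute(
                "SELECT COUNT(*) FROM operon_genes WHERE operon_id = ?",
                (op_row[0],)).fetchone()[0]
            if size == 3:
                assert conserved_operons(store, op_row[0], min_shared=4) == []
                return
        pytest.fail("no 3-gene operon in fixture")

    def test_matches_bruteforce_og_intersection(self, five_store):
        store, manifest, _ = five_store
        level = "Bacteria"

        def og_set(operon_id):
            ogs = set()
            for (gene_id,) in store.conn.execute(
                    "SELECT gene_id FROM operon_genes WHERE operon_id = ?", (operon_id,)):
                gene = store.gene(gene_id)
                for og, lvl in store.protein_ogs(gene["protein_hash"]):
                    if lvl == level:
                        ogs.add(og)
            return ogs

        all_ops = [(r[0], r[1]) for r in store.conn.execute(
            "SELECT operon_id, genome_id FROM operons")]
        for query_id, query_genome in all_ops[:6]:
            expected = []
            for other_id, genome in all_ops:
                if other_id == query_id or genome == query_genome:
                    continue
                shared = len(og_set(query_id) & og_set(other_id))
                if shared >= 2:
                    expected.append((other_id, shared, genome))
            expected.sort(key=lambda r: (-r[1], r[2], r[0]))
            got = conserved_operons(store, query_id, min_shared=2, og_level=level)
            assert got == [(oid, n) for oid, n, _ in expected]


class TestConservedRegulons:
    def _plant(self, store, manifest, tmp_path, regulator_slot=5):
        g0, g1 = manifest["genomes"][0], manifest["genomes"][1]
        header = ("regulon_name\tgenome\tregulator_locus_tag\ttarget_locus_tag\t"
                  "site_contig\tsite_start\tsite_end\tsite_strand\tsite_sequence")
        rows = []
        for g in (g0, g1):
            reg = f"{g}_{regulator_slot:04d}" if regulator_slot else ""
            for target_slot in (1, 2, 3):
                rows.append(f"RegA\t{g}\t{reg}\t{g}_{target_slot:04d}\t\t\t\t\t")
        tsv = tmp_path / "regulons.tsv"
        tsv.write_text("\n".join([header] + rows) + "\n", encoding="utf-8")
        report = bulk_import_regulons(store, tsv)
        assert report.n_imported == 6
        return f"RegA@{g0}"

    def test_identical_planted_regulons_found(self, five_store_copy, tmp_path):
        store, manifest, _ = five_store_copy
        rid = self._plant(store, manifest, tmp_path)
        results = conserved_regulons(store, rid, min_shared=2)
        assert len(results) == 1 and results[0][1] == 3

    def test_differing_regulator_ogs_excluded(self, five_store_copy, tmp_path):
        store, manifest, _ = five_store_copy
        g0, g1 = manifest["genomes"][0], manifest["genomes"][1]
        header = ("regulon_name\tgenome\tregulator_locus_tag\ttarget_locus_tag\t"
                  "site_contig\tsite_start\tsite_end\tsite_strand\tsite_sequence")
        # same shared targets, but regulators from different families:
        # slot 5 and slot 6 carry different planted OGs
        rows = []
        for g, reg_slot in ((g0, 5), (g1, 6)):
            for target_slot in (1, 2, 3):
                rows.append(f"RegB\t{g}\t{g}_{reg_slot:04d}\t{g}_{target_slot:04d}"
                            "\t\t\t\t\t")
        tsv = tmp_path / "regulons2.tsv"
        tsv.write_text("\n".join([header] + rows) + "\n", encoding="utf-8")
        bulk_import_regulons(store, tsv)
        assert conserved_regulons(store, f"RegB@{g0}", min_shared=2) == []
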