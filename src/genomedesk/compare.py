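"""Ortholog-anchored comparative analysis.

Starting from an anchor gene, the module ranks the proteins of the
anchor's ortholog group by global alignment score (BLOSUM62, affine gaps
open 11 / extend 1), builds a neighbor-joining guide tree on normalized
alignment distances, assembles gene-neighborhood rows around each hit in
tree leaf order with genes colored by ortholog group, and summarizes the
neighborhood's functional-category profile. Conserved operons and regulons
are found by intersecting member ortholog-group sets across genomes.

Distances: ``d(a, b) = 1 - score(a, b) / min(self_score(a), self_score(b))``,
clamped to [0, 1]; identical sequences have distance 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .errors import NotFoundError, ValidationError
from .store import Store

MIN_MAX_N, MAX_MAX_N = 10, 200
DEFAULT_WINDOW_BP = 10_000

# 20-color palette for OG coloring in SVG output (color_index cycles through it)
PALETTE = [
    "#e6194b", "#3cb44b", "#4363d8", "#f58231", "#911eb4", "#46f0f0",
    "#f032e6", "#bcf60c", "#fabebe", "#008080", "#e6beff", "#9a6324",
    "#fffac8", "#800000", "#aaffc3", "#808000", "#ffd8b1", "#000075",
    "#808080", "#ffe119",
]


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


class _ScoreCache:
    """Pairwise alignment scores keyed by protein hash pairs."""

    def __init__(self, store: Store):
        self.store = store
        self.aligner = make_aligner()
        self._seqs: dict[str, str] = {}
        self._scores: dict[tuple[str, str], float] = {}

    def seq(self, phash: str) -> str:
        if phash not in self._seqs:
            self._seqs[phash] = self.store.protein(phash)["sequence"]
        return self._seqs[phash]

    def score(self, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in self._scores:
            self._scores[key] = float(self.aligner.score(self.seq(key[0]), self.seq(key[1])))
        return self._scores[key]

    def distance(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        denom = min(self.score(a, a), self.score(b, b))
        if denom <= 0:
            return 1.0
        return min(1.0, max(0.0, 1.0 - self.score(a, b) / denom))


@dataclass
class SimilarityHit:
    protein_hash: str
    genome_id: str
    gene_id: str
    locus_tag: str
    score: float
    normalized_distance: float

    @property
    def label(self) -> str:
        return f"{self.genome_id}|{self.locus_tag}"


def most_specific_level(store: Store, phash: str) -> str:
    """Pick one taxonomic level for a protein with assignments at several.

    "Most specific" is resolved as the level whose OG has the fewest member
    proteins in the store (a narrower taxonomic level covers fewer
    sequences); ties break by level name for determinism.
    """
    assignments = store.protein_ogs(phash)
    if not assignments:
        raise NotFoundError("no ortholog family")

    def key(item):
        og_id, level = item
        n = store.conn.execute(
            "SELECT COUNT(*) FROM protein_ogs WHERE og_id = ? AND level = ?",
            (og_id, level)).fetchone()[0]
        return (n, level)

    return min(assignments, key=key)[1]


def _og_at_level(store: Store, phash: str | None, level: str) -> str | None:
    if phash is None:
        return None
    for og_id, og_level in store.protein_ogs(phash):
        if og_level == level:
            return og_id
    return None


def similar_proteins(store: Store, genome_id: str, locus_tag: str,
                     max_n: int = 50, og_level: str | None = None,
                     _cache: _ScoreCache | None = None) -> list[SimilarityHit]:
    """Rank the members of the anchor's ortholog group by alignment score.

    Candidates are all CDS genes store-wide whose protein shares the
    anchor's OG at ``og_level`` (default: the anchor's most specific level).
    The anchor itself is always rank 1; remaining hits are ordered by score
    descending with ties broken by (genome_id, locus_tag). The list is
    truncated to ``max_n`` entries, which must lie in [10, 200].
    """
    if not (MIN_MAX_N <= max_n <= MAX_MAX_N):
        raise ValidationError(f"max_n must be in [{MIN_MAX_N}, {MAX_MAX_N}], got {max_n}")
    store.require_genome(genome_id)
    anchor = store.gene_by_locus(genome_id, locus_tag)
    if anchor is None:
        raise NotFoundError(f"gene not found: {genome_id}:{locus_tag}")
    if anchor["feature_type"] != "CDS" or not anchor["protein_hash"]:
        raise ValidationError(f"anchor {locus_tag} is not a protein-coding gene")
    if og_level is None:
        og_level = most_specific_level(store, anchor["protein_hash"])
    og_id = _og_at_level(store, anchor["protein_hash"], og_level)
    if og_id is None:
        raise NotFoundError("no ortholog family")
    cache = _cache or _ScoreCache(store)
    cur = store.conn.execute(
        "SELECT g.gene_id, g.genome_id, g.locus_tag, g.protein_hash FROM genes g "
        "JOIN protein_ogs po ON g.protein_hash = po.protein_hash "
        "WHERE po.og_id = ? AND po.level = ? AND g.feature_type = 'CDS' "
        "ORDER BY g.genome_id, g.locus_tag", (og_id, og_level))
    anchor_hash = anchor["protein_hash"]
    hits = []
    for gene_id, g_genome, g_tag, phash in cur:
        score = cache.score(anchor_hash, phash)
        hits.append(SimilarityHit(
            protein_hash=phash, genome_id=g_genome, gene_id=gene_id,
            locus_tag=g_tag, score=score,
            normalized_distance=cache.distance(anchor_hash, phash)))
    anchor_hit = next(h for h in hits if h.gene_id == anchor["gene_id"])
    rest = [h for h in hits if h.gene_id != anchor["gene_id"]]
    rest.sort(key=lambda h: (-h.score, h.genome_id, h.locus_tag))
    return [anchor_hit] + rest[:max_n - 1]


# ---------------------------------------------------------------------------
# Guide tree


def _ladderize(node: TreeNode) -> None:
    """Deterministic leaf order: smaller subtree first, ties by smallest leaf name."""
    for child in node.children:
        _ladderize(child)

    def key(child):
        tips = [t.name for t in child.tips()] or [child.name]
        return (len(tips), min(tips))
    node.children.sort(key=key)


def guide_tree(labels: list[str], distances: np.ndarray) -> TreeNode:
    """Neighbor-joining tree over a full pairwise distance matrix.

    Negative NJ branch lengths are clamped to zero, the tree is rooted at
    the midpoint, and children are ordered deterministically (smaller
    subtree first, ties by leaf label). Degenerate sizes are handled
    directly: one leaf gives a single-node tree, two leaves split their
    distance evenly.
    """
    n = len(labels)
    if n == 0:
        raise ValidationError("guide_tree needs at least one leaf")
    if n == 1:
        return TreeNode(name=labels[0])
    if n == 2:
        d = float(distances[0][1]) / 2.0
        root = TreeNode()
        root.extend([TreeNode(name=labels[0], length=d),
                     TreeNode(name=labels[1], length=d)])
        return root
    dm = DistanceMatrix(np.asarray(distances, dtype=float), ids=labels)
    tree = nj(dm, neg_as_zero=True)
    try:
        tree = tree.root_at_midpoint()
    except Exception:
        pass  # zero-length star trees cannot be midpoint-rooted; keep as-is
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    _ladderize(tree)
    return tree


def tree_newick(tree: TreeNode) -> str:
    return str(tree).strip()


def guide_tree_for_hits(hits: list[SimilarityHit], cache: _ScoreCache) -> TreeNode:
    labels = [h.label for h in hits]
    n = len(hits)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = cache.distance(hits[i].protein_hash, hits[j].protein_hash)
    return guide_tree(labels, d)


# ---------------------------------------------------------------------------
# Neighborhood assembly


@dataclass
class GeneGlyph:
    locus_tag: str
    start: int   # display coordinates within the window (bp from window left)
    end: int
    strand: int
    og_id: str | None
    color_index: int | None
    cog: str | None  # concatenated COG category letters, or None


@dataclass
class NeighborhoodRow:
    gene_id: str     # the hit gene anchoring this row
    genome_id: str
    locus_tag: str
    genes: list[GeneGlyph]


@dataclass
class NeighborhoodView:
    anchor_gene_id: str
    og_level: str
    window_bp: int
    rows: list[NeighborhoodRow]
    tree_newick: str
    colors: dict[str, int] = field(default_factory=dict)  # og_id -> color_index

    def to_dict(self) -> dict:
        return {
            "anchor_gene_id": self.anchor_gene_id,
            "og_level": self.og_level,
            "window_bp": self.window_bp,
            "colors": self.colors,
            "rows": [{
                "gene_id": r.gene_id, "genome_id": r.genome_id,
                "locus_tag": r.locus_tag,
                "genes": [{
                    "locus_tag": g.locus_tag, "start": g.start, "end": g.end,
                    "strand": g.strand, "og_id": g.og_id,
                    "color_index": g.color_index, "cog": g.cog,
                } for g in r.genes],
            } for r in self.rows],
        }


def build_neighborhood(store: Store, genome_id: str, locus_tag: str,
                       max_n: int = 50, window_bp: int = DEFAULT_WINDOW_BP,
                       og_level: str | None = None) -> NeighborhoodView:
    """Assemble the tree-ordered, OG-colored gene neighborhood of an anchor.

    One row per similarity hit, containing every gene overlapping a
    symmetric ``window_bp`` window around the hit gene's midpoint on its
    contig. Rows whose hit gene lies on the minus strand are mirrored so
    the hit always points rightward. Colors are assigned per OG in order of
    first appearance scanning rows top-down (tree leaf order) and
    left-to-right; the anchor's OG is always color 0; genes without an OG
    at the chosen level carry no color.
    """
    anchor = store.gene_by_locus(genome_id, locus_tag)
    if anchor is None:
        raise NotFoundError(f"gene not found: {genome_id}:{locus_tag}")
    cache = _ScoreCache(store)
    if og_level is None:
        if not anchor["protein_hash"]:
            raise ValidationError(f"anchor {locus_tag} is not a protein-coding gene")
        og_level = most_specific_level(store, anchor["protein_hash"])
    hits = similar_proteins(store, genome_id, locus_tag, max_n=max_n,
                            og_level=og_level, _cache=cache)
    tree = guide_tree_for_hits(hits, cache)
    leaf_order = [t.name for t in tree.tips()] or [tree.name]
    by_label = {h.label: h for h in hits}
    anchor_og = _og_at_level(store, anchor["protein_hash"], og_level)

    rows: list[NeighborhoodRow] = []
    for label in leaf_order:
        hit = by_label[label]
        gene = store.gene(hit.gene_id)
        center = (gene["start"] + gene["end"]) // 2
        w_left = center - window_bp // 2
        w_right = center + window_bp // 2
        cur = store.conn.execute(
            "SELECT * FROM genes WHERE genome_id = ? AND contig_id = ? "
            "AND end > ? AND start < ? ORDER BY start, end, locus_tag",
            (hit.genome_id, gene["contig_id"], w_left, w_right))
        glyphs = []
        for g in cur:
            if gene["strand"] == -1:
                disp_start, disp_end = w_right - g["end"], w_right - g["start"]
                disp_strand = -g["strand"]
            else:
                disp_start, disp_end = g["start"] - w_left, g["end"] - w_left
                disp_strand = g["strand"]
            glyphs.append(GeneGlyph(
                locus_tag=g["locus_tag"], start=disp_start, end=disp_end,
                strand=disp_strand,
                og_id=_og_at_level(store, g["protein_hash"], og_level),
                color_index=None,
                cog="".join(store.protein_label_values(g["protein_hash"], "COG_category"))
                or None if g["protein_hash"] else None))
        glyphs.sort(key=lambda g: (g.start, g.end, g.locus_tag))
        rows.append(NeighborhoodRow(gene_id=hit.gene_id, genome_id=hit.genome_id,
                                    locus_tag=hit.locus_tag, genes=glyphs))

    colors: dict[str, int] = {}
    if anchor_og is not None:
        colors[anchor_og] = 0
    for row in rows:
        for glyph in row.genes:
            if glyph.og_id is not None and glyph.og_id not in colors:
                colors[glyph.og_id] = len(colors)
    for row in rows:
        for glyph in row.genes:
            if glyph.og_id is not None:
                glyph.color_index = colors[glyph.og_id]

    return NeighborhoodView(
        anchor_gene_id=anchor["gene_id"], og_level=og_level, window_bp=window_bp,
        rows=rows, tree_newick=tree_newick(tree), colors=colors)


# ---------------------------------------------------------------------------
# Functional profile


@dataclass
class FunctionalProfile:
    entries: list[tuple[str, int]]
    total: int

    def to_dict(self) -> dict:
        return {"entries": [{"category": c, "count": n} for c, n in self.entries],
                "total": self.total}


def functional_profile(view: NeighborhoodView) -> FunctionalProfile:
    """Count functional-category letters over all genes of the neighborhood.

    Multi-letter COG categories (e.g. "KT") count once per letter; genes
    without any category label count under "unclassified".
    """
    counts: dict[str, int] = {}
    for row in view.rows:
        for glyph in row.genes:
            if glyph.cog:
                for letter in glyph.cog:
                    counts[letter] = counts.get(letter, 0) + 1
            else:
                counts["unclassified"] = counts.get("unclassified", 0) + 1
    entries = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return FunctionalProfile(entries=entries, total=sum(counts.values()))


# ---------------------------------------------------------------------------
# Conserved operons / regulons


def _operon_og_sets(store: Store, level: str) -> dict[str, tuple[str, set[str]]]:
    """operon_id -> (genome_id, set of member OG ids at the level)."""
    out: dict[str, tuple[str, set[str]]] = {}
    cur = store.conn.execute(
        "SELECT o.operon_id, o.genome_id, po.og_id FROM operons o "
        "JOIN operon_genes og ON o.operon_id = og.operon_id "
        "JOIN genes g ON og.gene_id = g.gene_id "
        "LEFT JOIN protein_ogs po ON g.protein_hash = po.protein_hash AND po.level = ?",
        (level,))
    for operon_id, genome_id, og_id in cur:
        entry = out.setdefault(operon_id, (genome_id, set()))
        if og_id is not None:
            entry[1].add(og_id)
    return out


def conserved_operons(store: Store, operon_id: str, min_shared: int = 2,
                      og_level: str | None = None) -> list[tuple[str, int]]:
    """Operons in other genomes sharing at least ``min_shared`` OGs with the query.

    The OG set of an operon is the set of distinct ortholog groups of its
    member proteins at one taxonomic level (default: the most specific
    level among the query members' assignments). Results are ranked by the
    shared-OG count descending, then genome, then operon id.
    """
    row = store.conn.execute(
        "SELECT * FROM operons WHERE operon_id = ?", (operon_id,)).fetchone()
    if row is None:
        raise NotFoundError(f"operon not found: {operon_id}")
    if og_level is None:
        og_level = _default_level_for_genes(
            store, [r[0] for r in store.conn.execute(
                "SELECT gene_id FROM operon_genes WHERE operon_id = ?", (operon_id,))])
    og_sets = _operon_og_sets(store, og_level)
    query_genome, query_ogs = og_sets.get(operon_id, (row["genome_id"], set()))
    results = []
    for other_id, (genome, ogs) in og_sets.items():
        if other_id == operon_id or genome == query_genome:
            continue
        shared = len(query_ogs & ogs)
        if shared >= min_shared:
            results.append((other_id, shared, genome))
    results.sort(key=lambda r: (-r[1], r[2], r[0]))
    return [(oid, n) for oid, n, _ in results]


def _default_level_for_genes(store: Store, gene_ids: list[str]) -> str:
    """Most specific level represented among the genes' OG assignments."""
    best = None
    for gid in gene_ids:
        gene = store.gene(gid)
        if gene and gene["protein_hash"]:
            try:
                level = most_specific_level(store, gene["protein_hash"])
            except NotFoundError:
                continue
            n = store.conn.execute(
                "SELECT COUNT(DISTINCT protein_hash) FROM protein_ogs WHERE level = ?",
                (level,)).fetchone()[0]
            cand = (n, level)
            if best is None or cand < best:
                best = cand
    if best is None:
        raise NotFoundError("no ortholog family among member genes")
    return best[1]


def conserved_regulons(store: Store, regulon_id: str, min_shared: int = 2,
                       og_level: str | None = None) -> list[tuple[str, int]]:
    """Regulons in other genomes whose target-gene OG sets share ``min_shared`` OGs.

    When both the query and a candidate have a regulator gene with an OG at
    the level, the regulators must additionally share an OG; a regulon
    without a regulator imposes no regulator constraint.
    """
    row = store.conn.execute(
        "SELECT * FROM regulons WHERE regulon_id = ?", (regulon_id,)).fetchone()
    if row is None:
        raise NotFoundError(f"regulon not found: {regulon_id}")

    def targets(rid):
        return [r[0] for r in store.conn.execute(
            "SELECT gene_id FROM regulon_targets WHERE regulon_id = ?", (rid,))]

    if og_level is None:
        og_level = _default_level_for_genes(store, targets(regulon_id))

    def og_set(gene_ids):
        ogs = set()
        for gid in gene_ids:
            gene = store.gene(gid)
            if gene and gene["protein_hash"]:
                og = _og_at_level(store, gene["protein_hash"], og_level)
                if og:
                    ogs.add(og)
        return ogs

    def regulator_ogs(reg_row):
        if not reg_row["regulator_gene_id"]:
            return None
        gene = store.gene(reg_row["regulator_gene_id"])
        if not gene or not gene["protein_hash"]:
            return None
        ogs = og_set([reg_row["regulator_gene_id"]])
        return ogs or None

    query_targets = og_set(targets(regulon_id))
    query_reg = regulator_ogs(row)
    results = []
    for other in store.conn.execute("SELECT * FROM regulons"):
        if other["regulon_id"] == regulon_id or other["genome_id"] == row["genome_id"]:
            continue
        shared = len(query_targets & og_set(targets(other["regulon_id"])))
        if shared < min_shared:
            continue
        other_reg = regulator_ogs(other)
        if query_reg is not None and other_reg is not None and not (query_reg & other_reg):
            continue
        results.append((other["regulon_id"], shared, other["genome_id"]))
    results.sort(key=lambda r: (-r[1], r[2], r[0]))
    return [(rid, n) for rid, n, _ in results]


# ---------------------------------------------------------------------------
# SVG rendering


def render_svg(view: NeighborhoodView, row_height: int = 28,
               label_width: int = 220) -> str:
    """Standalone SVG of the neighborhood: one row per hit, arrows per gene."""
    scale = 900.0 / max(view.window_bp, 1)
    width = label_width + 920
    height = row_height * (len(view.rows) + 1)
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'font-family="monospace" font-size="11">',
        f'<text x="4" y="14">{view.anchor_gene_id} neighborhood '
        f'({view.og_level}, window {view.window_bp} bp)</text>',
    ]
    for i, row in enumerate(view.rows):
        y = row_height * (i + 1)
        parts.append(f'<text x="4" y="{y + 16}">{row.genome_id}|{row.locus_tag}</text>')
        for g in row.genes:
            x0 = label_width + max(0.0, g.start * scale)
            x1 = label_width + min(920.0, g.end * scale)
            if x1 <= x0:
                continue
            fill = PALETTE[g.color_index % len(PALETTE)] if g.color_index is not None \
                else "#d9d9d9"
            tip = min(8.0, x1 - x0)
            ymid, ytop, ybot = y + 12, y + 4, y + 20
            if g.strand >= 0:
                pts = f"{x0:.1f},{ytop} {x1 - tip:.1f},{ytop} {x1:.1f},{ymid} " \
                      f"{x1 - tip:.1f},{ybot} {x0:.1f},{ybot}"
            else:
                pts = f"{x1:.1f},{ytop} {x0 + tip:.1f},{ytop} {x0:.1f},{ymid} " \
                      f"{x0 + tip:.1f},{ybot} {x1:.1f},{ybot}"
            parts.append(f'<polygon points="{pts}" fill="{fill}" stroke="#333">'
                         f'<title>{g.locus_tag} {g.og_id or "-"}</title></polygon>')
    parts.append("</svg>")
    return "\n".join(parts)
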