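"""Embedded single-file relational store for a microbial genome collection.

One sqlite file holds every entity of the collection: taxonomy, strains and
samples with metadata triples, genomes with contigs and genes, deduplicated
proteins keyed by MD5, ortholog-group and functional-label assignments,
operons, regulons with binding sites, registered annotation tools, gene
annotations, and pipeline job records. Every mutating operation is wrapped
in a transaction and is all-or-nothing.

Multiple independent store files may coexist on one host; each is a
self-contained collection.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path

from ._tsv import read_tsv
from .errors import NotFoundError, StoreError, ValidationError

SCHEMA_VERSION = 1

_SCHEMA = """
CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT NOT NULL);
CREATE TABLE taxa (
    taxon_id TEXT PRIMARY KEY, name TEXT NOT NULL,
    rank TEXT NOT NULL, parent_id TEXT NOT NULL
);
CREATE TABLE strains (
    strain_id TEXT PRIMARY KEY, name TEXT NOT NULL, taxon_id TEXT
);
CREATE TABLE samples (
    sample_id TEXT PRIMARY KEY, name TEXT NOT NULL, description TEXT
);
CREATE TABLE metadata (
    kind TEXT NOT NULL CHECK (kind IN ('strain', 'sample')),
    entity_id TEXT NOT NULL, key TEXT NOT NULL,
    source TEXT NOT NULL, value TEXT NOT NULL
);
CREATE TABLE genomes (
    genome_id TEXT PRIMARY KEY, strain_id TEXT, sample_id TEXT, taxon_id TEXT
);
CREATE TABLE contigs (
    genome_id TEXT NOT NULL, contig_id TEXT NOT NULL,
    length INTEGER NOT NULL, sequence TEXT NOT NULL,
    PRIMARY KEY (genome_id, contig_id)
);
CREATE TABLE proteins (
    protein_hash TEXT PRIMARY KEY, sequence TEXT NOT NULL,
    length INTEGER NOT NULL
);
CREATE TABLE genes (
    gene_id TEXT PRIMARY KEY, genome_id TEXT NOT NULL,
    locus_tag TEXT NOT NULL, contig_id TEXT NOT NULL,
    start INTEGER NOT NULL, end INTEGER NOT NULL, strand INTEGER NOT NULL,
    feature_type TEXT NOT NULL, name TEXT, function_text TEXT,
    protein_hash TEXT,
    UNIQUE (genome_id, locus_tag)
);
CREATE INDEX idx_genes_genome ON genes (genome_id, contig_id, start);
CREATE INDEX idx_genes_hash ON genes (protein_hash);
CREATE TABLE og_groups (
    og_id TEXT NOT NULL, level TEXT NOT NULL, description TEXT,
    PRIMARY KEY (og_id, level)
);
CREATE TABLE protein_ogs (
    protein_hash TEXT NOT NULL, og_id TEXT NOT NULL, level TEXT NOT NULL,
    PRIMARY KEY (protein_hash, og_id, level)
);
CREATE INDEX idx_pogs_og ON protein_ogs (og_id, level);
CREATE TABLE labels (
    scheme TEXT NOT NULL, value TEXT NOT NULL, description TEXT,
    PRIMARY KEY (scheme, value)
);
CREATE TABLE protein_labels (
    protein_hash TEXT NOT NULL, scheme TEXT NOT NULL, value TEXT NOT NULL,
    PRIMARY KEY (protein_hash, scheme, value)
);
CREATE TABLE protein_map_status (
    protein_hash TEXT PRIMARY KEY,
    status TEXT NOT NULL CHECK (status IN ('assigned', 'unassigned'))
);
CREATE TABLE operons (
    operon_id TEXT PRIMARY KEY, genome_id TEXT NOT NULL,
    contig_id TEXT NOT NULL, start INTEGER NOT NULL, end INTEGER NOT NULL,
    strand INTEGER NOT NULL, source TEXT NOT NULL
);
CREATE TABLE operon_genes (
    operon_id TEXT NOT NULL, gene_id TEXT NOT NULL, pos INTEGER NOT NULL,
    PRIMARY KEY (operon_id, pos)
);
CREATE TABLE regulons (
    regulon_id TEXT PRIMARY KEY, name TEXT NOT NULL,
    genome_id TEXT NOT NULL, regulator_gene_id TEXT,
    UNIQUE (name, genome_id)
);
CREATE TABLE regulon_targets (
    regulon_id TEXT NOT NULL, gene_id TEXT NOT NULL,
    PRIMARY KEY (regulon_id, gene_id)
);
CREATE TABLE sites (
    site_id TEXT PRIMARY KEY, genome_id TEXT NOT NULL,
    contig_id TEXT NOT NULL, start INTEGER NOT NULL, end INTEGER NOT NULL,
    strand INTEGER NOT NULL, sequence TEXT NOT NULL, regulon_id TEXT
);
CREATE TABLE tools (
    name TEXT PRIMARY KEY, env_name TEXT NOT NULL,
    command_template TEXT NOT NULL, params TEXT NOT NULL,
    enabled INTEGER NOT NULL
);
CREATE TABLE annotations (
    ann_id INTEGER PRIMARY KEY,
    gene_id TEXT NOT NULL, genome_id TEXT NOT NULL, source TEXT NOT NULL,
    key TEXT NOT NULL, value TEXT NOT NULL, note TEXT,
    UNIQUE (gene_id, source, key, value)
);
CREATE TABLE jobs (
    job_id INTEGER PRIMARY KEY AUTOINCREMENT,
    tool TEXT NOT NULL, genome_id TEXT NOT NULL,
    status TEXT NOT NULL CHECK (status IN ('queued', 'running', 'done', 'failed')),
    log_path TEXT, n_imported INTEGER
);
"""

ENTITY_TABLES = (
    "taxa", "strains", "samples", "metadata", "genomes", "contigs",
    "proteins", "genes", "og_groups", "protein_ogs", "labels",
    "protein_labels", "operons", "operon_genes", "regulons",
    "regulon_targets", "sites", "tools", "annotations", "jobs",
)

UNCLASSIFIED = "unclassified"


class Store:
    """Handle on an open collection store.

    Use :func:`open_store` to obtain one. The handle owns a sqlite
    connection; mutating helpers run inside ``with self.conn`` blocks so a
    failure rolls the whole call back.
    """

    def __init__(self, path: Path, conn: sqlite3.Connection, schema_version: int):
        self.path = Path(path)
        self.conn = conn
        self.schema_version = schema_version

    def close(self) -> None:
        self.conn.close()

    # -- small query helpers used across modules -------------------------

    def genome_exists(self, genome_id: str) -> bool:
        cur = self.conn.execute(
            "SELECT 1 FROM genomes WHERE genome_id = ?", (genome_id,))
        return cur.fetchone() is not None

    def require_genome(self, genome_id: str) -> None:
        if not self.genome_exists(genome_id):
            raise NotFoundError(f"genome not found: {genome_id}")

    def genome_ids(self) -> list[str]:
        cur = self.conn.execute("SELECT genome_id FROM genomes ORDER BY genome_id")
        return [r[0] for r in cur]

    def gene(self, gene_id: str) -> dict | None:
        cur = self.conn.execute("SELECT * FROM genes WHERE gene_id = ?", (gene_id,))
        row = cur.fetchone()
        return dict(row) if row else None

    def gene_by_locus(self, genome_id: str, locus_tag: str) -> dict | None:
        cur = self.conn.execute(
            "SELECT * FROM genes WHERE genome_id = ? AND locus_tag = ?",
            (genome_id, locus_tag))
        row = cur.fetchone()
        return dict(row) if row else None

    def genes_of_genome(self, genome_id: str) -> list[dict]:
        cur = self.conn.execute(
            "SELECT * FROM genes WHERE genome_id = ? ORDER BY contig_id, start, end, locus_tag",
            (genome_id,))
        return [dict(r) for r in cur]

    def contigs_of_genome(self, genome_id: str) -> list[dict]:
        cur = self.conn.execute(
            "SELECT * FROM contigs WHERE genome_id = ? ORDER BY contig_id",
            (genome_id,))
        return [dict(r) for r in cur]

    def protein(self, protein_hash: str) -> dict | None:
        cur = self.conn.execute(
            "SELECT * FROM proteins WHERE protein_hash = ?", (protein_hash,))
        row = cur.fetchone()
        return dict(row) if row else None

    def protein_ogs(self, protein_hash: str) -> list[tuple[str, str]]:
        cur = self.conn.execute(
            "SELECT og_id, level FROM protein_ogs WHERE protein_hash = ? "
            "ORDER BY level, og_id", (protein_hash,))
        return [(r[0], r[1]) for r in cur]

    def protein_label_values(self, protein_hash: str, scheme: str) -> list[str]:
        cur = self.conn.execute(
            "SELECT value FROM protein_labels WHERE protein_hash = ? AND scheme = ? "
            "ORDER BY value", (protein_hash, scheme))
        return [r[0] for r in cur]

    def entity_counts(self) -> dict[str, int]:
        out = {}
        for t in ENTITY_TABLES:
            out[t] = self.conn.execute(f"SELECT COUNT(*) FROM {t}").fetchone()[0]
        return out

    def protein_hashes(self) -> set[str]:
        return {r[0] for r in self.conn.execute("SELECT protein_hash FROM proteins")}


def open_store(path, create: bool = False) -> Store:
    """Open (or with ``create=True`` initialize) a collection store file.

    Raises :class:`StoreError` with "invalid store" if the file is not a
    store, and "unsupported schema" if it was written by a newer version.
    """
    path = Path(path)
    if not create and not path.exists():
        raise StoreError(f"invalid store: {path} does not exist")
    if create and path.exists():
        raise StoreError(f"refusing to create over existing file: {path}")
    conn = sqlite3.connect(path)
    conn.row_factory = sqlite3.Row
    conn.execute("PRAGMA foreign_keys = ON")
    if create:
        with conn:
            conn.executescript(_SCHEMA)
            conn.execute("INSERT INTO meta (key, value) VALUES ('schema_version', ?)",
                         (str(SCHEMA_VERSION),))
        return Store(path, conn, SCHEMA_VERSION)
    try:
        cur = conn.execute("SELECT value FROM meta WHERE key = 'schema_version'")
        row = cur.fetchone()
    except sqlite3.DatabaseError as exc:
        conn.close()
        raise StoreError(f"invalid store: {path} ({exc})") from exc
    if row is None:
        conn.close()
        raise StoreError(f"invalid store: {path} has no schema_version")
    version = int(row[0])
    if version > SCHEMA_VERSION:
        conn.close()
        raise StoreError(
            f"unsupported schema: store version {version} > supported {SCHEMA_VERSION}")
    return Store(path, conn, version)


# ---------------------------------------------------------------------------
# Taxonomy


def load_taxonomy(store: Store, tsv) -> int:
    """Load (or extend) the taxonomy table from a TSV.

    Columns: taxon_id, name, rank, parent_id. The root node has
    parent_id equal to its own taxon_id or empty. Accepts full NCBI-style
    dumps rewritten to this layout; a packaged mini taxonomy ships with the
    package for desk use.
    """
    rows = list(read_tsv(tsv, required_columns=("taxon_id", "name", "rank", "parent_id")))
    n = 0
    with store.conn:
        for _, row in rows:
            if not row["taxon_id"]:
                continue
            store.conn.execute(
                "INSERT OR REPLACE INTO taxa (taxon_id, name, rank, parent_id) "
                "VALUES (?, ?, ?, ?)",
                (row["taxon_id"], row["name"], row["rank"], row["parent_id"]))
            n += 1
    return n


def taxon_lineage(store: Store, taxon_id: str) -> list[dict]:
    """Root-to-taxon chain of taxa; empty if the taxon is unknown."""
    chain = []
    seen = set()
    current = taxon_id
    while current and current not in seen:
        seen.add(current)
        cur = store.conn.execute("SELECT * FROM taxa WHERE taxon_id = ?", (current,))
        row = cur.fetchone()
        if row is None:
            return []
        node = dict(row)
        chain.append(node)
        if node["parent_id"] in ("", node["taxon_id"]):
            break
        current = node["parent_id"]
    chain.reverse()
    return chain


def resolve_taxon(store: Store, taxon_id: str | None, name: str | None) -> str | None:
    """Resolve a taxonomy hint to a known taxon_id: by id first, then by exact name."""
    if taxon_id:
        cur = store.conn.execute("SELECT taxon_id FROM taxa WHERE taxon_id = ?", (taxon_id,))
        row = cur.fetchone()
        if row:
            return row[0]
    if name:
        cur = store.conn.execute(
            "SELECT taxon_id FROM taxa WHERE name = ? ORDER BY taxon_id", (name,))
        row = cur.fetchone()
        if row:
            return row[0]
    return None


# ---------------------------------------------------------------------------
# Strains / samples and metadata bulk import


def add_strain(store: Store, strain_id: str, name: str | None = None,
               taxon_id: str | None = None) -> None:
    with store.conn:
        store.conn.execute(
            "INSERT OR IGNORE INTO strains (strain_id, name, taxon_id) VALUES (?, ?, ?)",
            (strain_id, name or strain_id, taxon_id))


def add_sample(store: Store, sample_id: str, name: str | None = None,
               description: str = "") -> None:
    with store.conn:
        store.conn.execute(
            "INSERT OR IGNORE INTO samples (sample_id, name, description) VALUES (?, ?, ?)",
            (sample_id, name or sample_id, description))


@dataclass
class BulkImportReport:
    """Outcome of a bulk TSV import: rows imported, skipped names, row errors."""
    n_imported: int = 0
    skipped: list[str] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)


def bulk_import_metadata(store: Store, kind: str, tsv) -> BulkImportReport:
    """Attach (key, source, value) metadata triples to strains or samples.

    TSV columns: entity_name, key, source, value. Rows naming unknown
    entities are reported in ``skipped`` and not imported; malformed rows are
    collected in ``errors`` while valid rows proceed. If every data row is
    bad the import fails.
    """
    if kind not in ("strain", "sample"):
        raise ValidationError(f"metadata kind must be strain or sample, got {kind!r}")
    table, id_col = ("strains", "strain_id") if kind == "strain" else ("samples", "sample_id")
    report = BulkImportReport()
    rows = list(read_tsv(tsv, required_columns=("entity_name", "key", "source", "value")))
    to_insert = []
    for lineno, row in rows:
        if not row["entity_name"] or not row["key"]:
            report.errors.append(f"row {lineno}: empty entity_name or key")
            continue
        cur = store.conn.execute(
            f"SELECT 1 FROM {table} WHERE {id_col} = ? OR name = ?",
            (row["entity_name"], row["entity_name"]))
        hit = cur.fetchone()
        if hit is None:
            report.skipped.append(row["entity_name"])
            continue
        cur = store.conn.execute(
            f"SELECT {id_col} FROM {table} WHERE {id_col} = ? OR name = ?",
            (row["entity_name"], row["entity_name"]))
        entity_id = cur.fetchone()[0]
        to_insert.append((kind, entity_id, row["key"], row["source"], row["value"]))
    if rows and not to_insert and not report.skipped:
        raise ValidationError(
            "metadata import failed: every row malformed: " + "; ".join(report.errors))
    with store.conn:
        for rec in to_insert:
            store.conn.execute(
                "INSERT INTO metadata (kind, entity_id, key, source, value) "
                "VALUES (?, ?, ?, ?, ?)", rec)
    report.n_imported = len(to_insert)
    return report


# ---------------------------------------------------------------------------
# Regulons and sites


def bulk_import_regulons(store: Store, tsv) -> BulkImportReport:
    """Bulk-import regulons (regulator, targets, optional binding sites).

    TSV columns: regulon_name, genome, regulator_locus_tag,
    target_locus_tag, site_contig, site_start, site_end, site_strand,
    site_sequence (site columns optional per row). Rows naming the same
    (regulon_name, genome) accumulate targets and sites on one regulon.
    """
    report = BulkImportReport()
    rows = list(read_tsv(tsv, required_columns=(
        "regulon_name", "genome", "regulator_locus_tag", "target_locus_tag")))
    ops = []  # (regulon_id, name, genome, regulator_gene_id, target_gene_id, site or None)
    for lineno, row in rows:
        genome = row["genome"]
        if not store.genome_exists(genome):
            report.errors.append(f"row {lineno}: unknown genome {genome!r}")
            report.skipped.append(row["regulon_name"])
            continue
        regulator_gene_id = None
        if row["regulator_locus_tag"]:
            g = store.gene_by_locus(genome, row["regulator_locus_tag"])
            if g is None:
                report.errors.append(
                    f"row {lineno}: unknown regulator locus_tag {row['regulator_locus_tag']!r}")
                report.skipped.append(row["regulon_name"])
                continue
            regulator_gene_id = g["gene_id"]
        target = store.gene_by_locus(genome, row["target_locus_tag"])
        if target is None:
            report.errors.append(
                f"row {lineno}: unknown target locus_tag {row['target_locus_tag']!r}")
            report.skipped.append(row["regulon_name"])
            continue
        site = None
        if row.get("site_contig"):
            try:
                start = int(row["site_start"]); end = int(row["site_end"])
                strand = int(row.get("site_strand") or 0)
            except ValueError:
                report.errors.append(f"row {lineno}: bad site coordinates")
                report.skipped.append(row["regulon_name"])
                continue
            seq = row.get("site_sequence", "")
            cur = store.conn.execute(
                "SELECT length FROM contigs WHERE genome_id = ? AND contig_id = ?",
                (genome, row["site_contig"]))
            crow = cur.fetchone()
            if crow is None:
                report.errors.append(f"row {lineno}: unknown contig {row['site_contig']!r}")
                report.skipped.append(row["regulon_name"])
                continue
            if not (0 <= start < end <= crow[0]) or (seq and len(seq) != end - start):
                report.errors.append(f"row {lineno}: site violates coordinate invariants")
                report.skipped.append(row["regulon_name"])
                continue
            site = (row["site_contig"], start, end, strand, seq)
        regulon_id = f"{row['regulon_name']}@{genome}"
        ops.append((regulon_id, row["regulon_name"], genome, regulator_gene_id,
                    target["gene_id"], site))
    with store.conn:
        for regulon_id, name, genome, regulator, target_gene, site in ops:
            store.conn.execute(
                "INSERT OR IGNORE INTO regulons (regulon_id, name, genome_id, regulator_gene_id) "
                "VALUES (?, ?, ?, ?)", (regulon_id, name, genome, regulator))
            store.conn.execute(
                "INSERT OR IGNORE INTO regulon_targets (regulon_id, gene_id) VALUES (?, ?)",
                (regulon_id, target_gene))
            if site is not None:
                contig, start, end, strand, seq = site
                site_id = f"{regulon_id}:{contig}:{start}-{end}"
                store.conn.execute(
                    "INSERT OR REPLACE INTO sites "
                    "(site_id, genome_id, contig_id, start, end, strand, sequence, regulon_id) "
                    "VALUES (?, ?, ?, ?, ?, ?, ?, ?)",
                    (site_id, genome, contig, start, end, strand, seq, regulon_id))
    report.n_imported = len(ops)
    return report


# ---------------------------------------------------------------------------
# Taxonomy sunburst


def taxonomy_sunburst(store: Store) -> dict:
    """Hierarchical taxonomy overview with per-node genome counts.

    Returns a nested node dict ``{name, rank, taxon_id, count, children}``.
    Each genome contributes a leaf node (rank "genome") under its assigned
    taxon, so every internal node's count is exactly the sum of its
    children's counts and the root count is the total number of genomes.
    Genomes without a resolvable taxon are grouped under "unclassified".
    """
    root = {"name": "root", "rank": "root", "taxon_id": None, "count": 0, "children": []}
    index = {}  # path tuple -> node

    def child(parent, parent_path, name, rank, taxon_id):
        path = parent_path + (name,)
        node = index.get(path)
        if node is None:
            node = {"name": name, "rank": rank, "taxon_id": taxon_id,
                    "count": 0, "children": []}
            index[path] = node
            parent["children"].append(node)
        return node, path

    cur = store.conn.execute("SELECT genome_id, taxon_id FROM genomes ORDER BY genome_id")
    for genome_id, taxon_id in cur:
        lineage = taxon_lineage(store, taxon_id) if taxon_id else []
        node, path = root, ()
        if not lineage:
            node, path = child(node, path, UNCLASSIFIED, "no rank", None)
            node["count"] += 1
            root["count"] += 1
        else:
            root["count"] += 1
            for taxon in lineage:
                node, path = child(node, path, taxon["name"], taxon["rank"],
                                   taxon["taxon_id"])
                node["count"] += 1
        leaf, _ = child(node, path, genome_id, "genome", None)
        leaf["count"] += 1

    def sort_rec(node):
        node["children"].sort(key=lambda n: n["name"])
        for c in node["children"]:
            sort_rec(c)
    sort_rec(root)
    return root


# ---------------------------------------------------------------------------
# Deletion


def delete_genome(store: Store, genome_id: str) -> dict[str, int]:
    """Remove a genome and everything hanging off it; returns per-class counts.

    Proteins still referenced by genes of other genomes are kept; proteins
    that become orphaned are removed together with their ortholog/label
    assignments and mapping status.
    """
    store.require_genome(genome_id)
    conn = store.conn
    report = {}
    with conn:
        hashes = {r[0] for r in conn.execute(
            "SELECT DISTINCT protein_hash FROM genes WHERE genome_id = ? "
            "AND protein_hash IS NOT NULL", (genome_id,))}
        report["genes"] = conn.execute(
            "SELECT COUNT(*) FROM genes WHERE genome_id = ?", (genome_id,)).fetchone()[0]
        report["contigs"] = conn.execute(
            "SELECT COUNT(*) FROM contigs WHERE genome_id = ?", (genome_id,)).fetchone()[0]
        report["operons"] = conn.execute(
            "SELECT COUNT(*) FROM operons WHERE genome_id = ?", (genome_id,)).fetchone()[0]
        report["regulons"] = conn.execute(
            "SELECT COUNT(*) FROM regulons WHERE genome_id = ?", (genome_id,)).fetchone()[0]
        report["sites"] = conn.execute(
            "SELECT COUNT(*) FROM sites WHERE genome_id = ?", (genome_id,)).fetchone()[0]
        report["annotations"] = conn.execute(
            "SELECT COUNT(*) FROM annotations WHERE genome_id = ?", (genome_id,)).fetchone()[0]
        conn.execute(
            "DELETE FROM operon_genes WHERE operon_id IN "
            "(SELECT operon_id FROM operons WHERE genome_id = ?)", (genome_id,))
        conn.execute("DELETE FROM operons WHERE genome_id = ?", (genome_id,))
        conn.execute(
            "DELETE FROM regulon_targets WHERE regulon_id IN "
            "(SELECT regulon_id FROM regulons WHERE genome_id = ?)", (genome_id,))
        conn.execute("DELETE FROM regulons WHERE genome_id = ?", (genome_id,))
        conn.execute("DELETE FROM sites WHERE genome_id = ?", (genome_id,))
        conn.execute("DELETE FROM annotations WHERE genome_id = ?", (genome_id,))
        conn.execute("DELETE FROM jobs WHERE genome_id = ?", (genome_id,))
        conn.execute("DELETE FROM genes WHERE genome_id = ?", (genome_id,))
        conn.execute("DELETE FROM contigs WHERE genome_id = ?", (genome_id,))
        conn.execute("DELETE FROM genomes WHERE genome_id = ?", (genome_id,))
        orphans = [h for h in sorted(hashes) if conn.execute(
            "SELECT 1 FROM genes WHERE protein_hash = ? LIMIT 1", (h,)).fetchone() is None]
        for h in orphans:
            conn.execute("DELETE FROM proteins WHERE protein_hash = ?", (h,))
            conn.execute("DELETE FROM protein_ogs WHERE protein_hash = ?", (h,))
            conn.execute("DELETE FROM protein_labels WHERE protein_hash = ?", (h,))
            conn.execute("DELETE FROM protein_map_status WHERE protein_hash = ?", (h,))
        report["proteins"] = len(orphans)
    return report


# ---------------------------------------------------------------------------
# Audit


def audit_store(store: Store) -> list[str]:
    """Referential-integrity audit; returns a list of problems (empty = clean)."""
    conn = store.conn
    problems = []
    q = conn.execute(
        "SELECT g.gene_id FROM genes g LEFT JOIN contigs c "
        "ON g.genome_id = c.genome_id AND g.contig_id = c.contig_id "
        "WHERE c.contig_id IS NULL")
    problems += [f"gene {r[0]}: contig missing" for r in q]
    q = conn.execute(
        "SELECT g.gene_id FROM genes g LEFT JOIN contigs c "
        "ON g.genome_id = c.genome_id AND g.contig_id = c.contig_id "
        "WHERE c.contig_id IS NOT NULL AND NOT "
        "(g.start >= 0 AND g.start < g.end AND g.end <= c.length)")
    problems += [f"gene {r[0]}: coordinates out of contig bounds" for r in q]
    q = conn.execute(
        "SELECT g.gene_id FROM genes g WHERE g.protein_hash IS NOT NULL AND "
        "g.protein_hash NOT IN (SELECT protein_hash FROM proteins)")
    problems += [f"gene {r[0]}: protein record missing" for r in q]
    q = conn.execute(
        "SELECT og.operon_id FROM operon_genes og "
        "LEFT JOIN genes g ON og.gene_id = g.gene_id WHERE g.gene_id IS NULL")
    problems += [f"operon {r[0]}: member gene missing" for r in q]
    for op in conn.execute("SELECT * FROM operons"):
        members = [dict(r) for r in conn.execute(
            "SELECT g.* FROM operon_genes og JOIN genes g ON og.gene_id = g.gene_id "
            "WHERE og.operon_id = ? ORDER BY og.pos", (op["operon_id"],))]
        if len(members) < 2:
            problems.append(f"operon {op['operon_id']}: fewer than 2 members")
            continue
        if any(m["contig_id"] != op["contig_id"] or m["strand"] != op["strand"]
               or m["genome_id"] != op["genome_id"] for m in members):
            problems.append(f"operon {op['operon_id']}: member contig/strand mismatch")
        if op["start"] != min(m["start"] for m in members) or \
                op["end"] != max(m["end"] for m in members):
            problems.append(f"operon {op['operon_id']}: span != member span")
    q = conn.execute(
        "SELECT rt.regulon_id FROM regulon_targets rt "
        "LEFT JOIN genes g ON rt.gene_id = g.gene_id WHERE g.gene_id IS NULL")
    problems += [f"regulon {r[0]}: target gene missing" for r in q]
    q = conn.execute(
        "SELECT r.regulon_id FROM regulons r JOIN regulon_targets rt "
        "ON r.regulon_id = rt.regulon_id JOIN genes g ON rt.gene_id = g.gene_id "
        "WHERE g.genome_id != r.genome_id")
    problems += [f"regulon {r[0]}: target outside genome" for r in q]
    for s in conn.execute("SELECT * FROM sites"):
        cur = conn.execute(
            "SELECT length FROM contigs WHERE genome_id = ? AND contig_id = ?",
            (s["genome_id"], s["contig_id"]))
        row = cur.fetchone()
        if row is None:
            problems.append(f"site {s['site_id']}: contig missing")
        elif not (0 <= s["start"] < s["end"] <= row[0]):
            problems.append(f"site {s['site_id']}: out of bounds")
        elif s["sequence"] and len(s["sequence"]) != s["end"] - s["start"]:
            problems.append(f"site {s['site_id']}: sequence length != end - start")
    q = conn.execute(
        "SELECT po.protein_hash, po.og_id, po.level FROM protein_ogs po "
        "LEFT JOIN og_groups og ON po.og_id = og.og_id AND po.level = og.level "
        "WHERE og.og_id IS NULL")
    problems += [f"protein {r[0]}: og {r[1]}@{r[2]} not in og_groups" for r in q]
    q = conn.execute(
        "SELECT pl.protein_hash, pl.scheme, pl.value FROM protein_labels pl "
        "LEFT JOIN labels l ON pl.scheme = l.scheme AND pl.value = l.value "
        "WHERE l.value IS NULL")
    problems += [f"protein {r[0]}: label {r[1]}:{r[2]} not in labels" for r in q]
    q = conn.execute(
        "SELECT p.protein_hash FROM proteins p "
        "LEFT JOIN genes g ON p.protein_hash = g.protein_hash WHERE g.gene_id IS NULL")
    problems += [f"protein {r[0]}: orphaned (no referencing gene)" for r in q]
    q = conn.execute(
        "SELECT a.ann_id, a.gene_id FROM annotations a "
        "LEFT JOIN genes g ON a.gene_id = g.gene_id WHERE g.gene_id IS NULL")
    problems += [f"annotation {r[0]}: gene {r[1]} missing" for r in q]
    return problems


def tool_params(raw: str) -> list[tuple[str, str]]:
    return [tuple(p) for p in json.loads(raw)]
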