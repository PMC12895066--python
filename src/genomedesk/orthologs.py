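"""Ortholog-group assignment against a precomputed reference.

De-novo orthology inference is quadratic in collection size because of the
all-against-all stage; this module instead assigns proteins to precomputed
ortholog groups (OGs) by exact hash lookup in a fixed reference table, and
only for protein hashes the store has never seen. Updates therefore cost
one lookup per *novel* protein, independent of how large the store already
is. An external mapper producing the same TSV dialect can be plugged in via
:func:`run_mapper_plugin`.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass, field
from pathlib import Path

from ._tsv import read_tsv
from .errors import NotFoundError, ValidationError
from .genbank import protein_hash
from .store import Store

LABEL_SCHEMES = {
    "kegg_ko": "KEGG_ortholog",
    "kegg_pathway": "KEGG_pathway",
    "ec": "EC",
    "go": "GO",
    "cog_category": "COG_category",
}

REFERENCE_COLUMNS = ("og_id", "level", "kegg_ko", "kegg_pathway", "ec", "go",
                     "cog_category")


@dataclass
class RefEntry:
    """Assignments for one protein: OGs per taxonomic level plus labels."""
    ogs: list[tuple[str, str]] = field(default_factory=list)   # (og_id, level)
    labels: list[tuple[str, str]] = field(default_factory=list)  # (scheme, value)


@dataclass
class ReferenceIndex:
    by_hash: dict[str, RefEntry] = field(default_factory=dict)
    n_entries: int = 0
    n_lookups: int = 0  # instrumentation: how many hash lookups were performed

    def lookup(self, phash: str) -> RefEntry | None:
        self.n_lookups += 1
        return self.by_hash.get(phash)


@dataclass
class MappingReport:
    genome_id: str
    n_proteins_considered: int = 0
    n_skipped_known: int = 0
    n_assigned: int = 0
    n_unassigned: int = 0


def load_reference(tsv) -> ReferenceIndex:
    """Build a :class:`ReferenceIndex` from a reference TSV.

    Columns: protein_md5 or protein_seq (at least one per row), og_id,
    level, kegg_ko, kegg_pathway, ec, go, cog_category. Multi-valued label
    cells are comma-separated; empty cells are allowed. Rows keyed by
    sequence have their MD5 computed on load. A protein may appear on
    several rows (one per taxonomic level); two rows giving *different*
    OGs at the same level for the same protein are a load error.
    """
    index = ReferenceIndex()
    rows = list(read_tsv(tsv, required_columns=("og_id", "level")))
    header_has_key = False
    for lineno, row in rows:
        phash = row.get("protein_md5", "")
        pseq = row.get("protein_seq", "")
        if not phash and not pseq:
            raise ValidationError(
                f"invalid reference: row {lineno} has neither protein_md5 nor protein_seq")
        header_has_key = True
        if not phash:
            phash = protein_hash(pseq.upper().rstrip("*"))
        phash = phash.lower()
        entry = index.by_hash.setdefault(phash, RefEntry())
        og_id, level = row["og_id"], row["level"]
        if og_id and level:
            for existing_og, existing_level in entry.ogs:
                if existing_level == level and existing_og != og_id:
                    raise ValidationError(
                        f"invalid reference: row {lineno}: protein {phash} already "
                        f"assigned to {existing_og} at level {level}, conflicting {og_id}")
            if (og_id, level) not in entry.ogs:
                entry.ogs.append((og_id, level))
        for col, scheme in LABEL_SCHEMES.items():
            for value in filter(None, (v.strip() for v in row.get(col, "").split(","))):
                if (scheme, value) not in entry.labels:
                    entry.labels.append((scheme, value))
        index.n_entries += 1
    if rows and not header_has_key:
        raise ValidationError("invalid reference: no key column")
    return index


def _persist_entry(store: Store, phash: str, entry: RefEntry) -> None:
    conn = store.conn
    for og_id, level in entry.ogs:
        conn.execute(
            "INSERT OR IGNORE INTO og_groups (og_id, level, description) VALUES (?, ?, NULL)",
            (og_id, level))
        conn.execute(
            "INSERT OR IGNORE INTO protein_ogs (protein_hash, og_id, level) VALUES (?, ?, ?)",
            (phash, og_id, level))
    for scheme, value in entry.labels:
        conn.execute(
            "INSERT OR IGNORE INTO labels (scheme, value, description) VALUES (?, ?, NULL)",
            (scheme, value))
        conn.execute(
            "INSERT OR IGNORE INTO protein_labels (protein_hash, scheme, value) "
            "VALUES (?, ?, ?)", (phash, scheme, value))


def assign_orthologs(store: Store, ref: ReferenceIndex, genome_id: str,
                     retry_unassigned: bool = False) -> MappingReport:
    """Assign OGs and labels to the genome's proteins, touching only novel hashes.

    A hash with a recorded mapping status (assigned, or previously looked up
    and found absent) is skipped without consulting the reference, so the
    number of reference lookups equals the number of novel hashes regardless
    of store size. Assignments are store-wide per hash and thus shared by
    every genome carrying the protein. ``retry_unassigned`` re-queries
    hashes recorded as absent (e.g. after swapping in a larger reference).
    """
    store.require_genome(genome_id)
    report = MappingReport(genome_id=genome_id)
    cur = store.conn.execute(
        "SELECT DISTINCT protein_hash FROM genes "
        "WHERE genome_id = ? AND protein_hash IS NOT NULL ORDER BY protein_hash",
        (genome_id,))
    hashes = [r[0] for r in cur]
    report.n_proteins_considered = len(hashes)
    with store.conn:
        for phash in hashes:
            row = store.conn.execute(
                "SELECT status FROM protein_map_status WHERE protein_hash = ?",
                (phash,)).fetchone()
            if row is not None and not (retry_unassigned and row[0] == "unassigned"):
                report.n_skipped_known += 1
                continue
            entry = ref.lookup(phash)
            if entry is None:
                store.conn.execute(
                    "INSERT OR REPLACE INTO protein_map_status (protein_hash, status) "
                    "VALUES (?, 'unassigned')", (phash,))
                report.n_unassigned += 1
            else:
                _persist_entry(store, phash, entry)
                store.conn.execute(
                    "INSERT OR REPLACE INTO protein_map_status (protein_hash, status) "
                    "VALUES (?, 'assigned')", (phash,))
                report.n_assigned += 1
    return report


def novel_proteins(store: Store, genome_id: str) -> list[tuple[str, str]]:
    """(hash, sequence) of the genome's proteins with no recorded mapping status."""
    store.require_genome(genome_id)
    cur = store.conn.execute(
        "SELECT DISTINCT p.protein_hash, p.sequence FROM genes g "
        "JOIN proteins p ON g.protein_hash = p.protein_hash "
        "WHERE g.genome_id = ? AND g.protein_hash NOT IN "
        "(SELECT protein_hash FROM protein_map_status) ORDER BY p.protein_hash",
        (genome_id,))
    return [(r[0], r[1]) for r in cur]


def run_mapper_plugin(store: Store, tool, genome_id: str, workdir=None) -> MappingReport:
    """Run an external mapper tool on the genome's novel proteins.

    The tool (a registered :class:`~genomedesk.annotate.ToolConfig`)
    receives a protein FASTA containing only novel hashes via the
    ``{input_faa}`` placeholder and must write the reference TSV dialect to
    ``{output_tsv}``. On success the emitted rows are applied exactly as
    :func:`assign_orthologs` would; on tool failure or unparseable output
    the store is left untouched.
    """
    from .annotate import render_command  # local import to avoid a cycle
    store.require_genome(genome_id)
    novel = novel_proteins(store, genome_id)
    workdir = Path(workdir) if workdir else Path(store.path).parent / "mapper_work"
    workdir.mkdir(parents=True, exist_ok=True)
    faa = workdir / f"{genome_id}.novel.faa"
    with faa.open("w", encoding="utf-8") as fh:
        for phash, seq in novel:
            fh.write(f">{phash}\n{seq}\n")
    out_tsv = workdir / f"{genome_id}.mapper.tsv"
    cmd = render_command(tool, input_faa=faa, output_tsv=out_tsv, workdir=workdir)
    proc = subprocess.run(cmd, shell=True, cwd=workdir, capture_output=True, text=True)
    report = MappingReport(genome_id=genome_id)
    report.n_proteins_considered = len(novel) + (
        store.conn.execute(
            "SELECT COUNT(DISTINCT protein_hash) FROM genes WHERE genome_id = ? "
            "AND protein_hash IN (SELECT protein_hash FROM protein_map_status)",
            (genome_id,)).fetchone()[0])
    report.n_skipped_known = report.n_proteins_considered - len(novel)
    if proc.returncode != 0 or not out_tsv.exists():
        raise ValidationError(
            f"mapper tool {tool.name} failed (exit {proc.returncode}); store unchanged")
    ref = load_reference(out_tsv)  # raises on unparseable output, store untouched
    with store.conn:
        for phash, _seq in novel:
            entry = ref.lookup(phash)
            if entry is None:
                store.conn.execute(
                    "INSERT OR REPLACE INTO protein_map_status (protein_hash, status) "
                    "VALUES (?, 'unassigned')", (phash,))
                report.n_unassigned += 1
            else:
                _persist_entry(store, phash, entry)
                store.conn.execute(
                    "INSERT OR REPLACE INTO protein_map_status (protein_hash, status) "
                    "VALUES (?, 'assigned')", (phash,))
                report.n_assigned += 1
    return report
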