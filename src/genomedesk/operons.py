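"""Operon prediction.

Built-in baseline: maximal runs of two or more consecutive same-strand CDS
whose intergenic gaps do not exceed ``max_gap`` base pairs become operons.
This is a transparent, documented stand-in for heavier external predictors,
which can be attached through the plugin contract (:func:`run_operon_plugin`)
and whose TSV output replaces the built-in calls for a genome.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass, field
from pathlib import Path

from ._tsv import read_tsv
from .errors import NotFoundError, ValidationError
from .store import Store

DEFAULT_MAX_GAP = 150


@dataclass
class Operon:
    operon_id: str
    genome_id: str
    contig_id: str
    gene_ids: list[str]  # ordered by start
    start: int
    end: int
    strand: int


def call_operons(genes: list[dict], max_gap: int = DEFAULT_MAX_GAP,
                 genome_id: str = "genome", contig_id: str | None = None) -> list[Operon]:
    """Group sorted CDS genes of one contig into operons.

    ``genes`` are dicts with gene_id, start, end, strand (CDS only, sorted
    by start). Two consecutive same-strand genes belong to the same operon
    when ``next.start - prev.end <= max_gap``; overlapping genes (negative
    gap) count as gap 0 and are joined. Singleton runs are not operons.
    Operon ids are deterministic: ``genome:contig:index`` with a 1-based
    index in start order.
    """
    starts = [g["start"] for g in genes]
    if starts != sorted(starts):
        raise ValidationError("input not sorted")
    if contig_id is None:
        contig_id = genes[0]["contig_id"] if genes else "contig"
    runs: list[list[dict]] = []
    current: list[dict] = []
    for g in genes:
        if current and g["strand"] == current[-1]["strand"] and \
                max(0, g["start"] - current[-1]["end"]) <= max_gap:
            current.append(g)
        else:
            if len(current) >= 2:
                runs.append(current)
            current = [g]
    if len(current) >= 2:
        runs.append(current)
    operons = []
    for i, run in enumerate(runs, start=1):
        operons.append(Operon(
            operon_id=f"{genome_id}:{contig_id}:{i}",
            genome_id=genome_id,
            contig_id=contig_id,
            gene_ids=[g["gene_id"] for g in run],
            start=min(g["start"] for g in run),
            end=max(g["end"] for g in run),
            strand=run[0]["strand"],
        ))
    return operons


def _replace_operons(store: Store, genome_id: str, operons: list[Operon],
                     source: str) -> None:
    conn = store.conn
    conn.execute(
        "DELETE FROM operon_genes WHERE operon_id IN "
        "(SELECT operon_id FROM operons WHERE genome_id = ?)", (genome_id,))
    conn.execute("DELETE FROM operons WHERE genome_id = ?", (genome_id,))
    for op in operons:
        conn.execute(
            "INSERT INTO operons (operon_id, genome_id, contig_id, start, end, strand, source) "
            "VALUES (?, ?, ?, ?, ?, ?, ?)",
            (op.operon_id, op.genome_id, op.contig_id, op.start, op.end, op.strand, source))
        for pos, gid in enumerate(op.gene_ids):
            conn.execute(
                "INSERT INTO operon_genes (operon_id, gene_id, pos) VALUES (?, ?, ?)",
                (op.operon_id, gid, pos))


def predict_operons(store: Store, genome_id: str,
                    max_gap: int = DEFAULT_MAX_GAP) -> list[Operon]:
    """Run the built-in caller on every contig of a genome and persist the result.

    Existing operons of the genome (from any source) are replaced, never
    merged, so repeated prediction is idempotent.
    """
    store.require_genome(genome_id)
    all_ops: list[Operon] = []
    for contig in store.contigs_of_genome(genome_id):
        cur = store.conn.execute(
            "SELECT gene_id, start, end, strand, contig_id FROM genes "
            "WHERE genome_id = ? AND contig_id = ? AND feature_type = 'CDS' "
            "ORDER BY start, end, gene_id", (genome_id, contig["contig_id"]))
        genes = [dict(r) for r in cur]
        all_ops.extend(call_operons(genes, max_gap=max_gap, genome_id=genome_id,
                                    contig_id=contig["contig_id"]))
    with store.conn:
        _replace_operons(store, genome_id, all_ops, source="builtin")
    return all_ops


def run_operon_plugin(store: Store, tool, genome_id: str, workdir=None) -> int:
    """Run an external operon predictor and import its operon TSV.

    The tool must write rows (operon_name, genome, contig, locus_tags) with
    locus_tags comma-separated. Rows with unknown locus tags, fewer than two
    members, or mixed strands are skipped with a report entry. The tool's
    operons *replace* all stored operons for the genome. On tool failure the
    store is unchanged.
    """
    from .annotate import render_command, write_job_inputs
    store.require_genome(genome_id)
    workdir = Path(workdir) if workdir else Path(store.path).parent / "operon_work"
    workdir.mkdir(parents=True, exist_ok=True)
    inputs = write_job_inputs(store, genome_id, workdir)
    out_tsv = workdir / f"{genome_id}.operons.tsv"
    cmd = render_command(tool, output_tsv=out_tsv, workdir=workdir, **inputs)
    proc = subprocess.run(cmd, shell=True, cwd=workdir, capture_output=True, text=True)
    if proc.returncode != 0 or not out_tsv.exists():
        raise ValidationError(
            f"operon tool {tool.name} failed (exit {proc.returncode}); store unchanged")
    operons: list[Operon] = []
    skipped: list[str] = []
    for lineno, row in read_tsv(out_tsv, required_columns=(
            "operon_name", "genome", "contig", "locus_tags")):
        if row["genome"] != genome_id:
            skipped.append(f"row {lineno}: genome mismatch")
            continue
        tags = [t for t in (s.strip() for s in row["locus_tags"].split(",")) if t]
        members = []
        ok = True
        for tag in tags:
            g = store.gene_by_locus(genome_id, tag)
            if g is None or g["contig_id"] != row["contig"]:
                skipped.append(f"row {lineno}: unknown locus_tag {tag!r} on {row['contig']!r}")
                ok = False
                break
            members.append(g)
        if not ok:
            continue
        if len(members) < 2:
            skipped.append(f"row {lineno}: fewer than 2 members")
            continue
        if len({m["strand"] for m in members}) != 1:
            skipped.append(f"row {lineno}: mixed strands")
            continue
        members.sort(key=lambda m: m["start"])
        operons.append(Operon(
            operon_id=f"{genome_id}:{row['contig']}:{row['operon_name']}",
            genome_id=genome_id,
            contig_id=row["contig"],
            gene_ids=[m["gene_id"] for m in members],
            start=min(m["start"] for m in members),
            end=max(m["end"] for m in members),
            strand=members[0]["strand"],
        ))
    with store.conn:
        _replace_operons(store, genome_id, operons, source=tool.name)
    return len(operons)
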