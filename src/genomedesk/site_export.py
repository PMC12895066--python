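"""Static-site export.

Writes a browsable, serveable snapshot of a collection: a genome listing
with strain/taxonomy/counts, per-genome track bundles (FASTA/GFF3/protein
FASTA) plus gene/operon/regulon JSON, the taxonomy sunburst JSON, and a
minimal static index page linking them. Output is deterministic so
repeated exports of an unchanged store are byte-identical.

JSON schemas are documented in docs/site_schema.md.
"""

from __future__ import annotations

import json
from pathlib import Path

from .errors import NotFoundError
from .genbank import export_tracks
from .store import Store, taxonomy_sunburst


def _dump(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n", encoding="utf-8")


def export_site(store: Store, outdir) -> dict:
    """Export the whole collection as static JSON + HTML; returns a manifest."""
    genome_ids = store.genome_ids()
    if not genome_ids:
        raise NotFoundError("nothing to export: store holds no genomes")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genomes_listing = []
    for gid in genome_ids:
        row = store.conn.execute(
            "SELECT * FROM genomes WHERE genome_id = ?", (gid,)).fetchone()
        taxon_name = None
        if row["taxon_id"]:
            trow = store.conn.execute(
                "SELECT name FROM taxa WHERE taxon_id = ?", (row["taxon_id"],)).fetchone()
            taxon_name = trow[0] if trow else None
        counts = {
            "contigs": store.conn.execute(
                "SELECT COUNT(*) FROM contigs WHERE genome_id = ?", (gid,)).fetchone()[0],
            "genes": store.conn.execute(
                "SELECT COUNT(*) FROM genes WHERE genome_id = ?", (gid,)).fetchone()[0],
            "operons": store.conn.execute(
                "SELECT COUNT(*) FROM operons WHERE genome_id = ?", (gid,)).fetchone()[0],
            "regulons": store.conn.execute(
                "SELECT COUNT(*) FROM regulons WHERE genome_id = ?", (gid,)).fetchone()[0],
        }
        genomes_listing.append({
            "genome_id": gid, "strain_id": row["strain_id"],
            "sample_id": row["sample_id"], "taxon_id": row["taxon_id"],
            "taxon_name": taxon_name, "counts": counts,
        })
    _dump(outdir / "genomes.json", genomes_listing)
    _dump(outdir / "sunburst.json", taxonomy_sunburst(store))

    files = ["genomes.json", "sunburst.json", "index.html"]
    for gid in genome_ids:
        gdir = outdir / gid
        gdir.mkdir(exist_ok=True)
        export_tracks(store, gid, gdir)
        genes = [{k: g[k] for k in ("gene_id", "locus_tag", "contig_id", "start",
                                    "end", "strand", "feature_type", "name",
                                    "function_text", "protein_hash")}
                 for g in store.genes_of_genome(gid)]
        _dump(gdir / "genes.json", genes)
        operons = []
        for op in store.conn.execute(
                "SELECT * FROM operons WHERE genome_id = ? ORDER BY operon_id", (gid,)):
            members = [r[0] for r in store.conn.execute(
                "SELECT gene_id FROM operon_genes WHERE operon_id = ? ORDER BY pos",
                (op["operon_id"],))]
            operons.append({"operon_id": op["operon_id"], "contig_id": op["contig_id"],
                            "start": op["start"], "end": op["end"],
                            "strand": op["strand"], "source": op["source"],
                            "gene_ids": members})
        _dump(gdir / "operons.json", operons)
        regulons = []
        for reg in store.conn.execute(
                "SELECT * FROM regulons WHERE genome_id = ? ORDER BY regulon_id", (gid,)):
            targets = sorted(r[0] for r in store.conn.execute(
                "SELECT gene_id FROM regulon_targets WHERE regulon_id = ?",
                (reg["regulon_id"],)))
            sites = [dict(s) for s in store.conn.execute(
                "SELECT site_id, contig_id, start, end, strand, sequence FROM sites "
                "WHERE regulon_id = ? ORDER BY site_id", (reg["regulon_id"],))]
            regulons.append({"regulon_id": reg["regulon_id"], "name": reg["name"],
                             "regulator_gene_id": reg["regulator_gene_id"],
                             "target_gene_ids": targets, "sites": sites})
        _dump(gdir / "regulons.json", regulons)
        files += [f"{gid}/{n}" for n in ("genome.fna", "genome.gff3", "proteins.faa",
                                         "genes.json", "operons.json", "regulons.json")]

    items = "\n".join(
        f'<li><a href="{gid}/genes.json">{gid}</a></li>' for gid in genome_ids)
    (outdir / "index.html").write_text(
        "<!DOCTYPE html>\n<html><head><title>genome collection</title></head>\n"
        "<body>\n<h1>Genome collection</h1>\n"
        '<p><a href="genomes.json">genomes.json</a> | '
        '<a href="sunburst.json">sunburst.json</a></p>\n'
        f"<ul>\n{items}\n</ul>\n</body></html>\n", encoding="utf-8")
    manifest = {"outdir": str(outdir), "n_genomes": len(genome_ids), "files": sorted(files)}
    return manifest


def audit_site(outdir) -> list[str]:
    """Cross-file consistency audit of an exported site (empty list = clean)."""
    outdir = Path(outdir)
    problems = []
    try:
        genomes = json.loads((outdir / "genomes.json").read_text(encoding="utf-8"))
        sunburst = json.loads((outdir / "sunburst.json").read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        return [f"unreadable site: {exc}"]
    if sunburst["count"] != len(genomes):
        problems.append(
            f"sunburst root count {sunburst['count']} != {len(genomes)} genomes")

    def check_counts(node):
        if node["children"]:
            total = sum(c["count"] for c in node["children"])
            if total != node["count"]:
                problems.append(
                    f"sunburst node {node['name']}: children sum {total} != {node['count']}")
            for c in node["children"]:
                check_counts(c)
    check_counts(sunburst)

    for entry in genomes:
        gid = entry["genome_id"]
        gdir = outdir / gid
        try:
            genes = json.loads((gdir / "genes.json").read_text(encoding="utf-8"))
            operons = json.loads((gdir / "operons.json").read_text(encoding="utf-8"))
            regulons = json.loads((gdir / "regulons.json").read_text(encoding="utf-8"))
        except (OSError, json.JSONDecodeError) as exc:
            problems.append(f"{gid}: unreadable bundle: {exc}")
            continue
        gene_ids = {g["gene_id"] for g in genes}
        for op in operons:
            for gene_id in op["gene_ids"]:
                if gene_id not in gene_ids:
                    problems.append(f"{gid}: operon {op['operon_id']} references "
                                    f"unknown gene {gene_id}")
        for reg in regulons:
            for gene_id in reg["target_gene_ids"]:
                if gene_id not in gene_ids:
                    problems.append(f"{gid}: regulon {reg['regulon_id']} references "
                                    f"unknown gene {gene_id}")
        if entry["counts"]["genes"] != len(genes):
            problems.append(f"{gid}: genomes.json gene count != genes.json length")
    return problems
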