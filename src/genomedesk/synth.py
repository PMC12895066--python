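"""Deterministic synthetic genome-collection generator.

Emulates a desk-scale collection of annotated bacterial genomes: each
genome is one contig of protein-coding genes drawn from planted ortholog
families. Family members are derived from a family ancestor by per-residue
substitution at ``mutation_rate`` and back-translated with seeded uniform
codon choice (bacterial code), so every GenBank /translation is consistent
with its spliced nucleotide sequence and every member's percent identity
to the ancestor is known exactly.

Planted structure, identical across genomes:
  * a conserved 4-gene neighborhood block (the first four shared families,
    conserved order/orientation, intergenic gaps above the operon cutoff);
  * operons per ``operon_spec``: same-strand runs with small internal gaps;
  * further shared families, then genome-private families, then "orphan"
    genes whose proteins are absent from the ortholog reference.

Alongside the GenBank files the generator writes a mini taxonomy TSV, an
ortholog-reference TSV covering the planted families with KEGG/EC/GO/COG
labels, and ground-truth tables (gene-to-family, operon membership,
identity percentages) for verification. Same seed, same bytes: generation
uses only Python's ``random`` module and pins the GenBank LOCUS date.

What this does not emulate: rearrangements, horizontal transfer, paralogs,
pseudogenes, intergenic features — real-genome structure beyond what the
importer, mapper and comparative modules need for exact verification.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError
from .genbank import protein_hash

AA20 = "ACDEFGHIKLMNPQRSTVWY"
OG_LEVEL = "Bacteria"
NEIGHBORHOOD_BLOCK = 4
_GENBANK_DATE = "01-JAN-1980"

# distinctive names/products for the conserved block, for text-search fixtures
_BLOCK_NAMES = ["dnaE", "rplA", "abcT", "regX"]
_BLOCK_PRODUCTS = [
    "DNA polymerase III subunit alpha",
    "50S ribosomal protein L1",
    "ABC transporter permease",
    "transcriptional regulator",
]
_PRODUCT_POOL = [
    "oxidoreductase", "aminotransferase", "membrane protein",
    "efflux pump component", "two-component sensor kinase",
    "glycosyl transferase", "acyl carrier protein", "peptidase",
]


@dataclass
class CollectionSpec:
    """Parameters of one synthetic collection (the study conditions)."""
    n_genomes: int = 10
    genes_per_genome: int = 200
    og_pool_size: int = 1200
    shared_og_fraction: float = 0.5
    operon_spec: list[tuple[int, int]] = field(
        default_factory=lambda: [(3, 150), (4, 120), (2, 100)])
    mutation_rate: float = 0.05
    seed: int = 1


def _codon_table_11() -> dict[str, list[str]]:
    table = CodonTable.unambiguous_dna_by_id[11]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in sorted(table.forward_table.items()):
        by_aa.setdefault(aa, []).append(codon)
    return by_aa

_CODONS = _codon_table_11()
_STOPS = ("TAA", "TAG", "TGA")


def _mutate(rng: random.Random, seq: str, rate: float) -> tuple[str, int]:
    """Substitute residues (never the leading M) at ``rate``; returns (seq, n_sub)."""
    out = [seq[0]]
    n = 0
    for aa in seq[1:]:
        if rng.random() < rate:
            choices = AA20.replace(aa, "")
            out.append(rng.choice(choices))
            n += 1
        else:
            out.append(aa)
    return "".join(out), n


def _backtranslate(rng: random.Random, protein: str) -> str:
    codons = [rng.choice(_CODONS[aa]) for aa in protein]
    codons.append(rng.choice(_STOPS))
    return "".join(codons)


def _og_labels(j: int) -> dict[str, str]:
    labels = {"kegg_ko": f"K{10000 + j:05d}",
              "cog_category": "JKLMEGHIPQCOT"[j % 13] + ("T" if j % 10 == 9 else "")}
    if j % 3 == 0:
        labels["kegg_pathway"] = f"map{(j % 10) + 1:05d}"
    if j % 4 == 0:
        labels["ec"] = f"{1 + j % 6}.1.1.{j + 1}"
    if j % 2 == 0:
        labels["go"] = f"GO:{7000000 + j:07d}"
    return labels


def _validate(spec: CollectionSpec) -> dict:
    if spec.n_genomes < 1 or spec.genes_per_genome < 1:
        raise ValidationError("spec rejected: need at least one genome and one gene")
    if not (0.0 <= spec.shared_og_fraction <= 1.0):
        raise ValidationError("spec rejected: shared_og_fraction must be in [0, 1]")
    if not (0.0 <= spec.mutation_rate <= 1.0):
        raise ValidationError("spec rejected: mutation_rate must be in [0, 1]")
    s = round(spec.shared_og_fraction * spec.genes_per_genome)
    operon_genes = sum(size for size, _ in spec.operon_spec)
    block = min(NEIGHBORHOOD_BLOCK, s)
    if block + operon_genes > s:
        raise ValidationError(
            f"spec rejected: conserved block ({block}) + operon genes ({operon_genes}) "
            f"exceed shared gene count ({s})")
    if any(size < 2 for size, _ in spec.operon_spec):
        raise ValidationError("spec rejected: operons need at least 2 genes")
    remaining = spec.genes_per_genome - s
    orphan_n = min(remaining, spec.genes_per_genome // 10)
    private_n = remaining - orphan_n
    n_ogs_needed = s + spec.n_genomes * private_n
    if n_ogs_needed > spec.og_pool_size:
        raise ValidationError(
            f"spec rejected: needs {n_ogs_needed} ortholog families "
            f"but og_pool_size is {spec.og_pool_size}")
    return {"shared": s, "block": block, "operon_genes": operon_genes,
            "orphan_n": orphan_n, "private_n": private_n}


def synth_collection(spec: CollectionSpec, outdir) -> dict:
    """Generate a collection into ``outdir``; returns (and writes) the manifest."""
    layout = _validate(spec)
    rng = random.Random(spec.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    s, block = layout["shared"], layout["block"]
    orphan_n, private_n = layout["orphan_n"], layout["private_n"]

    # --- taxonomy: root -> Bacteria -> 2 genera -> one species per genome
    genera = [("10", "Synthetica", "genus"), ("20", "Artificiella", "genus")]
    taxonomy_rows = [("1", "root", "no rank", "1"),
                     ("2", "Bacteria", "superkingdom", "1")]
    taxonomy_rows += [(tid, name, rank, "2") for tid, name, rank in genera]
    genome_ids = [f"genome{i:02d}" for i in range(spec.n_genomes)]
    species = {}
    for i, gid in enumerate(genome_ids):
        genus = genera[i % 2]
        tid = str(100 + i)
        name = f"{genus[1]} specimen{i:02d}"
        taxonomy_rows.append((tid, name, "species", genus[0]))
        species[gid] = (tid, name)
    tax_path = outdir / "taxonomy.tsv"
    with tax_path.open("w", encoding="utf-8") as fh:
        fh.write("taxon_id\tname\trank\tparent_id\n")
        for row in taxonomy_rows:
            fh.write("\t".join(row) + "\n")

    # --- ortholog family ancestors (shared pool first, then private partitions)
    n_families = s + spec.n_genomes * private_n
    ancestors = []
    for j in range(n_families):
        length = rng.randint(50, 150)
        seq = "M" + "".join(rng.choice(AA20) for _ in range(length - 1))
        ancestors.append(seq)
    family_strand = [rng.choice((1, -1)) for _ in range(n_families)]

    # --- per-slot layout shared by all genomes
    # slot: (kind, og_index or None, strand or None, gap_before, operon_tag)
    slots = []
    for b in range(block):
        slots.append(("shared", b, family_strand[b], rng.randint(200, 400), None))
    og_cursor = block
    for op_i, (size, max_gap) in enumerate(spec.operon_spec):
        strand = family_strand[og_cursor]
        for k in range(size):
            gap = rng.randint(200, 400) if k == 0 else rng.randint(5, min(max_gap, 150))
            slots.append(("shared", og_cursor, strand, gap, op_i))
            og_cursor += 1
    while og_cursor < s:
        slots.append(("shared", og_cursor, family_strand[og_cursor],
                      rng.randint(200, 500), None))
        og_cursor += 1
    for _ in range(private_n):
        slots.append(("private", None, None, rng.randint(200, 500), None))
    for _ in range(orphan_n):
        slots.append(("orphan", None, None, rng.randint(200, 500), None))

    reference_rows: dict[str, tuple] = {}  # hash -> (og_id, labels dict)
    truth_genes = []   # (genome, locus_tag, og_id, level, md5, identity_pct, product)
    truth_operons: dict[tuple, list[str]] = {}
    all_translations = set()
    genbank_paths = []

    for i, gid in enumerate(genome_ids):
        contig_id = f"{gid}_c1"
        parts = []
        features = []
        cursor = 0
        taxon_id, organism = species[gid]
        for idx, (kind, og_index, strand, gap, operon_tag) in enumerate(slots):
            locus_tag = f"{gid}_{idx + 1:04d}"
            if kind == "shared":
                j = og_index
            elif kind == "private":
                j = s + i * private_n + (idx - (len(slots) - private_n - orphan_n))
            else:
                j = None
            if j is not None:
                protein, n_sub = _mutate(rng, ancestors[j], spec.mutation_rate)
                identity = 100.0 * (len(protein) - n_sub) / len(protein)
                og_id = f"OG{j:05d}"
                g_strand = strand if strand is not None else rng.choice((1, -1))
                if j < block:
                    name, product = _BLOCK_NAMES[j], _BLOCK_PRODUCTS[j]
                else:
                    name, product = None, _PRODUCT_POOL[j % len(_PRODUCT_POOL)]
                reference_rows.setdefault(
                    protein_hash(protein), (og_id, _og_labels(j)))
            else:
                length = rng.randint(60, 100)
                protein = "M" + "".join(rng.choice(AA20) for _ in range(length - 1))
                identity = 100.0
                og_id, name = "", None
                product = "hypothetical protein"
                g_strand = rng.choice((1, -1))
            nt = _backtranslate(rng, protein)
            cursor += gap
            parts.append("".join(rng.choice("ACGT") for _ in range(gap)))
            start, end = cursor, cursor + len(nt)
            parts.append(nt if g_strand == 1 else str(Seq(nt).reverse_complement()))
            cursor = end
            quals = {"locus_tag": [locus_tag], "product": [product],
                     "transl_table": ["11"], "translation": [protein]}
            if name:
                quals["gene"] = [name]
            features.append(SeqFeature(
                SimpleLocation(start, end, strand=g_strand), type="CDS",
                qualifiers=quals))
            truth_genes.append((gid, locus_tag, og_id, OG_LEVEL if og_id else "",
                                protein_hash(protein), f"{identity:.2f}", product))
            all_translations.add(protein)
            if operon_tag is not None:
                truth_operons.setdefault((gid, contig_id, operon_tag), []).append(locus_tag)
        tail = rng.randint(100, 300)
        parts.append("".join(rng.choice("ACGT") for _ in range(tail)))
        contig_seq = "".join(parts)

        rec = SeqRecord(Seq(contig_seq), id=contig_id, name=contig_id[:16],
                        description=f"synthetic contig of {gid}")
        rec.annotations.update(molecule_type="DNA", topology="linear",
                               data_file_division="BCT", date=_GENBANK_DATE,
                               organism=organism, source=organism)
        source = SeqFeature(SimpleLocation(0, len(contig_seq), strand=1), type="source",
                            qualifiers={"organism": [organism],
                                        "db_xref": [f"taxon:{taxon_id}"]})
        rec.features = [source] + features
        gb_path = outdir / f"{gid}.gbk"
        with gb_path.open("w", encoding="utf-8") as fh:
            SeqIO.write([rec], fh, "genbank")
        genbank_paths.append(gb_path)

    # --- ortholog reference TSV
    ref_path = outdir / "reference.tsv"
    with ref_path.open("w", encoding="utf-8") as fh:
        fh.write("protein_md5\tog_id\tlevel\tkegg_ko\tkegg_pathway\tec\tgo\tcog_category\n")
        for phash in sorted(reference_rows):
            og_id, labels = reference_rows[phash]
            fh.write("\t".join([
                phash, og_id, OG_LEVEL,
                labels.get("kegg_ko", ""), labels.get("kegg_pathway", ""),
                labels.get("ec", ""), labels.get("go", ""),
                labels.get("cog_category", "")]) + "\n")

    truth_gene_path = outdir / "truth_gene_og.tsv"
    with truth_gene_path.open("w", encoding="utf-8") as fh:
        fh.write("genome\tlocus_tag\tog_id\tlevel\tprotein_md5\tidentity_pct\tproduct\n")
        for row in truth_genes:
            fh.write("\t".join(row) + "\n")

    truth_operon_path = outdir / "truth_operons.tsv"
    with truth_operon_path.open("w", encoding="utf-8") as fh:
        fh.write("genome\tcontig\toperon_index\tlocus_tags\n")
        for (gid, contig_id, tag), tags in sorted(truth_operons.items()):
            fh.write(f"{gid}\t{contig_id}\t{tag}\t{','.join(tags)}\n")

    manifest = {
        "spec": {
            "n_genomes": spec.n_genomes,
            "genes_per_genome": spec.genes_per_genome,
            "og_pool_size": spec.og_pool_size,
            "shared_og_fraction": spec.shared_og_fraction,
            "operon_spec": [list(x) for x in spec.operon_spec],
            "mutation_rate": spec.mutation_rate,
            "seed": spec.seed,
        },
        "genomes": genome_ids,
        "genbank_files": [p.name for p in genbank_paths],
        "taxonomy": tax_path.name,
        "reference": ref_path.name,
        "truth_gene_og": truth_gene_path.name,
        "truth_operons": truth_operon_path.name,
        "n_distinct_proteins": len(all_translations),
        "neighborhood_block_ogs": [f"OG{j:05d}" for j in range(block)],
        "layout": layout,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return manifest
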