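"""GenBank import and track export.

Parses GenBank flat files (as produced by Prokka, Bakta or NCBI-style
exports) into genome records, deduplicates protein sequences by MD5 content
hash, attaches taxonomy, and exports per-genome FASTA/GFF3 track files.

Coordinate convention: internally everything is 0-based half-open on the
forward strand; GenBank and GFF3 1-based inclusive boundaries are converted
exactly once, at I/O.
"""

from __future__ import annotations

import hashlib
import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation

from .errors import NotFoundError, ParseError, ValidationError
from .store import Store, UNCLASSIFIED, resolve_taxon

_GENE_FEATURES = {"CDS", "tRNA", "rRNA", "tmRNA", "ncRNA", "misc_RNA"}


@dataclass
class Contig:
    contig_id: str
    sequence: str  # uppercase ACGTN

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Gene:
    gene_id: str
    locus_tag: str
    contig_id: str
    start: int  # 0-based inclusive
    end: int    # exclusive
    strand: int  # +1 / -1
    feature_type: str  # CDS, tRNA, rRNA, other
    name: str | None = None
    function_text: str | None = None
    protein_sequence: str | None = None  # CDS only; hashed at import
    fuzzy: bool = False


@dataclass
class GenomeRecord:
    genome_id: str
    contigs: list[Contig] = field(default_factory=list)
    genes: list[Gene] = field(default_factory=list)
    strain_ref: str | None = None
    sample_ref: str | None = None
    source_taxon_hint: tuple[str | None, str | None] = (None, None)  # (name, taxon_id)
    warnings: list[str] = field(default_factory=list)


@dataclass
class ImportReport:
    genome_id: str
    n_contigs: int = 0
    n_genes: int = 0
    n_cds: int = 0
    n_new_proteins: int = 0
    n_reused_proteins: int = 0
    warnings: list[str] = field(default_factory=list)


def protein_hash(sequence: str) -> str:
    """Lowercase hex MD5 digest of the UTF-8 bytes of an amino-acid sequence.

    The hash is the store-wide deduplication key: identical protein
    sequences collapse onto one record no matter how many genomes carry
    them.
    """
    if not sequence:
        raise ValidationError("empty protein")
    return hashlib.md5(sequence.encode("utf-8")).hexdigest()


def _is_fuzzy(location) -> bool:
    parts = location.parts if isinstance(location, CompoundLocation) else [location]
    for part in parts:
        for pos in (part.start, part.end):
            if type(pos).__name__ not in ("ExactPosition", "int"):
                return True
    return False


def parse_genbank(path, genome_id: str | None = None) -> GenomeRecord:
    """Parse a GenBank flat file into a :class:`GenomeRecord`.

    Multiple LOCUS records become multiple contigs. CDS features take their
    protein from the /translation qualifier when present; otherwise the
    spliced nucleotide sequence is translated with the bacterial code
    (table 11, or /transl_table when given) and the trailing stop is
    stripped. Features with fuzzy (< or >) endpoints are imported with a
    warning and no translation re-derivation.
    """
    path = Path(path)
    if genome_id is None:
        genome_id = path.stem
    try:
        seq_records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:
        raise ParseError(f"parse failure: {path}: {exc}") from exc
    if not seq_records:
        raise ParseError(f"parse failure: {path}: no GenBank records")
    record = GenomeRecord(genome_id=genome_id)
    taxon_name, taxon_id = None, None
    for rec in seq_records:
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"parse failure: {path}: contig {rec.id} has no sequence")
        contig = Contig(contig_id=rec.id, sequence=seq)
        record.contigs.append(contig)
        if taxon_name is None:
            taxon_name = rec.annotations.get("organism") or None
        counter = 0
        for feat in rec.features:
            if feat.type == "source":
                if taxon_name is None:
                    taxon_name = (feat.qualifiers.get("organism", [None]) or [None])[0]
                for xref in feat.qualifiers.get("db_xref", []):
                    if xref.startswith("taxon:"):
                        taxon_id = xref.split(":", 1)[1]
                continue
            if feat.type not in _GENE_FEATURES:
                continue
            counter += 1
            start = int(feat.location.start)
            end = int(feat.location.end)
            strand = -1 if feat.location.strand == -1 else 1
            locus_tag = (feat.qualifiers.get("locus_tag", [None]) or [None])[0]
            if not locus_tag:
                locus_tag = f"{rec.id}_{counter:04d}"
            ftype = feat.type if feat.type in ("CDS", "tRNA", "rRNA") else "other"
            gene = Gene(
                gene_id=f"{genome_id}:{locus_tag}",
                locus_tag=locus_tag,
                contig_id=rec.id,
                start=start,
                end=end,
                strand=strand,
                feature_type=ftype,
                name=(feat.qualifiers.get("gene", [None]) or [None])[0],
                function_text=(feat.qualifiers.get("product", [None]) or [None])[0],
                fuzzy=_is_fuzzy(feat.location),
            )
            if ftype == "CDS":
                translation = (feat.qualifiers.get("translation", [None]) or [None])[0]
                if translation:
                    gene.protein_sequence = translation.upper().rstrip("*")
                elif gene.fuzzy:
                    record.warnings.append(
                        f"{locus_tag}: fuzzy location and no /translation; protein omitted")
                else:
                    table = int((feat.qualifiers.get("transl_table", ["11"]) or ["11"])[0])
                    try:
                        nt = feat.extract(rec.seq)
                        aa = str(Seq(nt).translate(table=table)).rstrip("*")
                    except Exception:
                        aa = ""
                    if aa and "*" not in aa:
                        gene.protein_sequence = aa
                    else:
                        record.warnings.append(
                            f"{locus_tag}: translation could not be derived; protein omitted")
                if gene.fuzzy:
                    record.warnings.append(f"{locus_tag}: fuzzy feature endpoints")
            record.genes.append(gene)
    record.source_taxon_hint = (taxon_name, taxon_id)
    return record


def import_genome(store: Store, record: GenomeRecord,
                  strain: str | None = None, sample: str | None = None) -> ImportReport:
    """Persist a parsed genome atomically, deduplicating proteins by hash.

    For each CDS protein the MD5 hash is compared against the store: an
    existing record is reused (``n_reused_proteins``), a novel sequence
    creates one (``n_new_proteins``). The taxonomy hint is resolved against
    the taxonomy table by taxon_id first, then exact organism name;
    unresolved genomes are attached to "unclassified" with a warning.
    """
    if store.genome_exists(record.genome_id):
        raise ValidationError(f"duplicate genome_id: {record.genome_id}")
    if not record.contigs:
        raise ValidationError("genome has no contigs")
    report = ImportReport(genome_id=record.genome_id, warnings=list(record.warnings))
    name, taxon_id_hint = record.source_taxon_hint
    taxon_id = resolve_taxon(store, taxon_id_hint, name)
    if taxon_id is None:
        report.warnings.append(
            f"taxonomy hint {record.source_taxon_hint!r} unresolved; "
            f"genome attached to {UNCLASSIFIED!r}")
    strain_id = strain or record.strain_ref
    sample_id = sample or record.sample_ref
    conn = store.conn
    with conn:
        if strain_id:
            conn.execute(
                "INSERT OR IGNORE INTO strains (strain_id, name, taxon_id) VALUES (?, ?, ?)",
                (strain_id, strain_id, taxon_id))
        if sample_id:
            conn.execute(
                "INSERT OR IGNORE INTO samples (sample_id, name, description) VALUES (?, ?, '')",
                (sample_id, sample_id, ""))
        conn.execute(
            "INSERT INTO genomes (genome_id, strain_id, sample_id, taxon_id) "
            "VALUES (?, ?, ?, ?)",
            (record.genome_id, strain_id, sample_id, taxon_id))
        for contig in record.contigs:
            conn.execute(
                "INSERT INTO contigs (genome_id, contig_id, length, sequence) "
                "VALUES (?, ?, ?, ?)",
                (record.genome_id, contig.contig_id, contig.length, contig.sequence))
        report.n_contigs = len(record.contigs)
        for gene in record.genes:
            phash = None
            if gene.feature_type == "CDS":
                report.n_cds += 1
                if gene.protein_sequence:
                    phash = protein_hash(gene.protein_sequence)
                    cur = conn.execute(
                        "SELECT 1 FROM proteins WHERE protein_hash = ?", (phash,))
                    if cur.fetchone() is None:
                        conn.execute(
                            "INSERT INTO proteins (protein_hash, sequence, length) "
                            "VALUES (?, ?, ?)",
                            (phash, gene.protein_sequence, len(gene.protein_sequence)))
                        report.n_new_proteins += 1
                    else:
                        report.n_reused_proteins += 1
            conn.execute(
                "INSERT INTO genes (gene_id, genome_id, locus_tag, contig_id, start, end, "
                "strand, feature_type, name, function_text, protein_hash) "
                "VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?)",
                (gene.gene_id, record.genome_id, gene.locus_tag, gene.contig_id,
                 gene.start, gene.end, gene.strand, gene.feature_type,
                 gene.name, gene.function_text, phash))
            report.n_genes += 1
    return report


def import_genbank_file(store: Store, path, genome_id: str | None = None,
                        strain: str | None = None, sample: str | None = None) -> ImportReport:
    """Convenience: parse a GenBank file and import it in one call."""
    record = parse_genbank(path, genome_id=genome_id)
    return import_genome(store, record, strain=strain, sample=sample)


# ---------------------------------------------------------------------------
# Track export


def _gff_escape(value: str) -> str:
    return urllib.parse.quote(value, safe=" .:^*$@!+_?-|")


def _wrap_fasta(seq: str, width: int = 70) -> str:
    return "\n".join(seq[i:i + width] for i in range(0, len(seq), width))


def export_tracks(store: Store, genome_id: str, outdir) -> dict[str, Path]:
    """Write genome.fna, genome.gff3, proteins.faa for one genome.

    Output is deterministic (contigs by id, genes by start) so repeated
    exports are byte-identical. GFF3 rows use 1-based inclusive coordinates;
    protein FASTA headers are ``genome_id|locus_tag|protein_hash``.
    """
    store.require_genome(genome_id)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contigs = store.contigs_of_genome(genome_id)
    genes = store.genes_of_genome(genome_id)

    fna = outdir / "genome.fna"
    with fna.open("w", encoding="utf-8") as fh:
        for c in contigs:
            fh.write(f">{c['contig_id']}\n{_wrap_fasta(c['sequence'])}\n")

    gff = outdir / "genome.gff3"
    with gff.open("w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for c in contigs:
            fh.write(f"##sequence-region {c['contig_id']} 1 {c['length']}\n")
        for g in genes:
            attrs = [f"ID={_gff_escape(g['locus_tag'])}",
                     f"locus_tag={_gff_escape(g['locus_tag'])}"]
            if g["name"]:
                attrs.append(f"Name={_gff_escape(g['name'])}")
            if g["function_text"]:
                attrs.append(f"product={_gff_escape(g['function_text'])}")
            if g["protein_hash"]:
                attrs.append(f"protein_hash={g['protein_hash']}")
            ftype = g["feature_type"] if g["feature_type"] != "other" else "misc_feature"
            phase = "0" if g["feature_type"] == "CDS" else "."
            fh.write("\t".join([
                g["contig_id"], "genomedesk", ftype,
                str(g["start"] + 1), str(g["end"]),
                ".", "+" if g["strand"] > 0 else "-", phase,
                ";".join(attrs)]) + "\n")

    faa = outdir / "proteins.faa"
    with faa.open("w", encoding="utf-8") as fh:
        for g in genes:
            if g["protein_hash"]:
                prot = store.protein(g["protein_hash"])
                fh.write(f">{genome_id}|{g['locus_tag']}|{g['protein_hash']}\n"
                         f"{_wrap_fasta(prot['sequence'])}\n")
    return {"fna": fna, "gff3": gff, "faa": faa}


def parse_gff3_coordinates(path) -> list[tuple[str, int, int, int, str]]:
    """Read (contig, start, end, strand, locus_tag) tuples back from a GFF3 file.

    Coordinates are converted back to the internal 0-based half-open
    convention; used for round-trip verification of exports.
    """
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ParseError(f"bad GFF3 row: {line!r}")
        attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
        locus_tag = urllib.parse.unquote(attrs.get("locus_tag", attrs.get("ID", "")))
        out.append((cols[0], int(cols[3]) - 1, int(cols[4]),
                    1 if cols[6] != "-" else -1, locus_tag))
    return out
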