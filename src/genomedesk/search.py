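"""Annotation, genome and sequence search.

Text search runs case-insensitive substring queries over gene names and
function text (classification identifiers like "K00001" match exactly),
and over genome names, strain names, taxonomy, and strain metadata.

Sequence search is an internal seed-and-extend scan over the stored contig
and protein sequences: exact k-mer seeds (nucleotide k=11 on both strands,
protein k=4) are extended without gaps in both directions until the running
score drops 20 below its maximum; overlapping hits on the same diagonal
are merged, hits below the identity threshold are dropped, and results are
ranked by raw score. There are no E-values: score and percent identity
only.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import NotFoundError, ValidationError
from .store import Store, taxon_lineage

NT_SEED = 11
PROT_SEED = 4
XDROP = 20
NT_MATCH, NT_MISMATCH = 1, -2

_NT_ALPHABET = set("ACGTN")
_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYXBZU")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

CLASSIFICATION_FIELDS = {
    "KEGG_ortholog": "KEGG_ortholog",
    "KEGG_pathway": "KEGG_pathway",
    "GO": "GO",
    "EC": "EC",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Text search


def search_genes(store: Store, query: str, scope: str | None = None,
                 field: str = "any") -> list[dict]:
    """Find genes by name, function text, or classification identifier.

    ``field`` is one of name, function, KEGG_ortholog, KEGG_pathway, GO,
    EC, or any (the union). Name/function use case-insensitive substring
    match; classification identifiers match exactly. ``scope`` restricts to
    one genome. Results are sorted by (genome, contig, start).
    """
    if not query:
        raise ValidationError("empty query")
    if scope is not None:
        store.require_genome(scope)
    valid = {"name", "function", "any", *CLASSIFICATION_FIELDS}
    if field not in valid:
        raise ValidationError(f"unknown search field: {field}")
    found: dict[str, dict] = {}

    def add(rows, matched_field):
        for r in rows:
            d = dict(r)
            if d["gene_id"] not in found:
                d["matched_field"] = matched_field
                found[d["gene_id"]] = d

    like = f"%{query.lower()}%"
    scope_sql = " AND genome_id = ?" if scope else ""
    scope_arg = (scope,) if scope else ()
    if field in ("name", "any"):
        add(store.conn.execute(
            f"SELECT * FROM genes WHERE LOWER(IFNULL(name, '')) LIKE ?{scope_sql}",
            (like, *scope_arg)), "name")
    if field in ("function", "any"):
        add(store.conn.execute(
            f"SELECT * FROM genes WHERE LOWER(IFNULL(function_text, '')) LIKE ?{scope_sql}",
            (like, *scope_arg)), "function")
    schemes = [field] if field in CLASSIFICATION_FIELDS else \
        (list(CLASSIFICATION_FIELDS) if field == "any" else [])
    for scheme in schemes:
        add(store.conn.execute(
            f"SELECT g.* FROM genes g JOIN protein_labels pl "
            f"ON g.protein_hash = pl.protein_hash "
            f"WHERE pl.scheme = ? AND pl.value = ?{scope_sql.replace('genome_id', 'g.genome_id')}",
            (scheme, query, *scope_arg)), scheme)
    out = list(found.values())
    out.sort(key=lambda g: (g["genome_id"], g["contig_id"], g["start"], g["locus_tag"]))
    return out


def search_genomes(store: Store, query: str) -> list[dict]:
    """Find genomes by genome name, strain name, taxonomy, or strain metadata.

    Case-insensitive substring match; each result records which field
    matched (genome_name, strain_name, taxonomy, metadata).
    """
    if not query:
        raise ValidationError("empty query")
    q = query.lower()
    results: dict[str, dict] = {}

    def add(genome_id, matched_field, matched_value):
        if genome_id not in results:
            results[genome_id] = {"genome_id": genome_id,
                                  "matched_field": matched_field,
                                  "matched_value": matched_value}

    for row in store.conn.execute(
            "SELECT genome_id, strain_id, taxon_id FROM genomes ORDER BY genome_id"):
        genome_id, strain_id, taxon_id = row
        if q in genome_id.lower():
            add(genome_id, "genome_name", genome_id)
        if strain_id:
            srow = store.conn.execute(
                "SELECT name FROM strains WHERE strain_id = ?", (strain_id,)).fetchone()
            if srow and (q in strain_id.lower() or q in srow[0].lower()):
                add(genome_id, "strain_name", srow[0])
            for mrow in store.conn.execute(
                    "SELECT key, value FROM metadata WHERE kind = 'strain' AND entity_id = ?",
                    (strain_id,)):
                if q in mrow[0].lower() or q in mrow[1].lower():
                    add(genome_id, "metadata", f"{mrow[0]}={mrow[1]}")
        if taxon_id:
            for taxon in taxon_lineage(store, taxon_id):
                if q in taxon["name"].lower():
                    add(genome_id, "taxonomy", taxon["name"])
                    break
    return sorted(results.values(), key=lambda r: r["genome_id"])


def list_pathway_genes(store: Store, genome_id: str, pathway_id: str
                       ) -> list[tuple[str, list[dict]]]:
    """KEGG orthology groups of a genome's genes mapped to one pathway.

    Returns (KEGG_ortholog, genes) pairs; genes labeled with the pathway
    but lacking a KEGG ortholog are grouped under the empty string so the
    union over pathways covers every pathway-labeled gene.
    """
    store.require_genome(genome_id)
    groups: dict[str, list[dict]] = {}
    cur = store.conn.execute(
        "SELECT g.* FROM genes g JOIN protein_labels pl "
        "ON g.protein_hash = pl.protein_hash "
        "WHERE g.genome_id = ? AND pl.scheme = 'KEGG_pathway' AND pl.value = ? "
        "ORDER BY g.contig_id, g.start", (genome_id, pathway_id))
    for row in cur:
        gene = dict(row)
        kos = store.protein_label_values(gene["protein_hash"], "KEGG_ortholog") or [""]
        for ko in kos:
            groups.setdefault(ko, []).append(gene)
    return sorted(groups.items(), key=lambda kv: kv[0])


def genome_pathways(store: Store, genome_id: str) -> list[str]:
    """Distinct KEGG pathways with at least one labeled gene in the genome."""
    store.require_genome(genome_id)
    cur = store.conn.execute(
        "SELECT DISTINCT pl.value FROM genes g JOIN protein_labels pl "
        "ON g.protein_hash = pl.protein_hash "
        "WHERE g.genome_id = ? AND pl.scheme = 'KEGG_pathway' ORDER BY pl.value",
        (genome_id,))
    return [r[0] for r in cur]


# ---------------------------------------------------------------------------
# Seed-and-extend sequence search


@dataclass
class SeqHit:
    subject_id: str
    subject_start: int  # 0-based half-open, forward strand of the subject
    subject_end: int
    query_start: int
    query_end: int
    strand: int         # +1 / -1 (nucleotide mode; +1 for protein)
    matches: int
    length: int
    score: int

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.matches / self.length


def _blosum62():
    from Bio.Align import substitution_matrices
    m = substitution_matrices.load("BLOSUM62")
    table = {}
    for a in m.alphabet:
        for b in m.alphabet:
            table[(a, b)] = int(m[a, b])
    return table

_BLOSUM = None


def _pair_score(a: str, b: str, mode: str) -> int:
    global _BLOSUM
    if mode == "nucleotide":
        return NT_MATCH if (a == b and a != "N") else NT_MISMATCH
    if _BLOSUM is None:
        _BLOSUM = _blosum62()
    return _BLOSUM.get((a, b), -4)


def _extend(query: str, subject: str, qpos: int, spos: int, k: int, mode: str):
    """Ungapped X-drop extension of a seed; returns (qs, qe, ss, se, score, matches)."""
    score = sum(_pair_score(query[qpos + i], subject[spos + i], mode) for i in range(k))
    best = score
    qs, ss = qpos, spos
    qe, se = qpos + k, spos + k
    # right
    run, best_run = 0, 0
    i = 0
    cur = score
    best_i = 0
    while qpos + k + i < len(query) and spos + k + i < len(subject):
        cur += _pair_score(query[qpos + k + i], subject[spos + k + i], mode)
        i += 1
        if cur > best:
            best, best_i = cur, i
        elif best - cur > XDROP:
            break
    qe, se = qpos + k + best_i, spos + k + best_i
    score = best
    # left
    cur = best
    i = 0
    best_i = 0
    while qpos - 1 - i >= 0 and spos - 1 - i >= 0:
        cur += _pair_score(query[qpos - 1 - i], subject[spos - 1 - i], mode)
        i += 1
        if cur > best:
            best, best_i = cur, i
        elif best - cur > XDROP:
            break
    qs, ss = qpos - best_i, spos - best_i
    score = best
    matches = sum(1 for a, b in zip(query[qs:qe], subject[ss:se]) if a == b)
    return qs, qe, ss, se, score, matches


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _search_one_subject(query: str, subject: str, k: int, mode: str,
                        index: dict[str, list[int]]) -> list[tuple]:
    """Best hit per diagonal after seed extension; list of extension tuples."""
    best_by_diag: dict[int, tuple] = {}
    seen_spans: set[tuple[int, int]] = set()
    for qpos in range(len(query) - k + 1):
        for spos in index.get(query[qpos:qpos + k], ()):
            diag = qpos - spos
            prev = best_by_diag.get(diag)
            if prev is not None and prev[0] <= qpos < prev[1]:
                continue  # seed inside an already-extended alignment on this diagonal
            ext = _extend(query, subject, qpos, spos, k, mode)
            qs, qe, ss, se, score, matches = ext
            key = (qs, qe)
            if prev is None or score > prev[4]:
                best_by_diag[diag] = ext
    return list(best_by_diag.values())


def _validate_query(query: str, mode: str) -> str:
    query = query.strip().upper()
    if mode == "nucleotide":
        if not query or set(query) - _NT_ALPHABET:
            raise ValidationError("query is not a nucleotide sequence (ACGTN)")
        if len(query) < NT_SEED:
            raise ValidationError(f"query shorter than seed length {NT_SEED}")
    elif mode == "protein":
        if not query or set(query) - _AA_ALPHABET:
            raise ValidationError("query is not a protein sequence")
        if len(query) < PROT_SEED:
            raise ValidationError(f"query shorter than seed length {PROT_SEED}")
    else:
        raise ValidationError(f"mode must be nucleotide or protein, got {mode!r}")
    return query


def seq_search(store: Store, query: str, mode: str,
               min_identity_pct: float = 80.0, max_hits: int = 50) -> list[SeqHit]:
    """Seed-and-extend search of a query against all stored sequences.

    Nucleotide mode scans every contig on both strands (reverse-strand hits
    report forward-strand subject coordinates with strand −1); protein mode
    scans every gene's protein. Hits below ``min_identity_pct`` are
    dropped; the rest are ranked by score descending, ties by subject_id,
    truncated to ``max_hits``.
    """
    query = _validate_query(query, mode)
    hits: list[SeqHit] = []
    if mode == "nucleotide":
        k = NT_SEED
        rc = revcomp(query)
        cur = store.conn.execute(
            "SELECT genome_id, contig_id, sequence FROM contigs "
            "ORDER BY genome_id, contig_id")
        for genome_id, contig_id, seq in cur:
            subject_id = f"{genome_id}|{contig_id}"
            index = _kmer_index(seq, k)
            for strand, q in ((1, query), (-1, rc)):
                for qs, qe, ss, se, score, matches in _search_one_subject(
                        q, seq, k, mode, index):
                    if strand == -1:
                        # report query coordinates on the original query
                        qs, qe = len(query) - qe, len(query) - qs
                    hits.append(SeqHit(
                        subject_id=subject_id, subject_start=ss, subject_end=se,
                        query_start=qs, query_end=qe, strand=strand,
                        matches=matches, length=se - ss, score=score))
    else:
        k = PROT_SEED
        cur = store.conn.execute(
            "SELECT p.protein_hash, p.sequence FROM proteins p ORDER BY p.protein_hash")
        gene_map: dict[str, list[str]] = {}
        for gene_row in store.conn.execute(
                "SELECT genome_id, locus_tag, protein_hash FROM genes "
                "WHERE protein_hash IS NOT NULL ORDER BY genome_id, locus_tag"):
            gene_map.setdefault(gene_row[2], []).append(f"{gene_row[0]}|{gene_row[1]}")
        for phash, seq in cur:
            index = _kmer_index(seq, k)
            for qs, qe, ss, se, score, matches in _search_one_subject(
                    query, seq, k, mode, index):
                for subject_id in gene_map.get(phash, []):
                    hits.append(SeqHit(
                        subject_id=subject_id, subject_start=ss, subject_end=se,
                        query_start=qs, query_end=qe, strand=1,
                        matches=matches, length=se - ss, score=score))
    hits = [h for h in hits if h.identity_pct >= min_identity_pct]
    hits.sort(key=lambda h: (-h.score, h.subject_id, h.subject_start, h.strand))
    return hits[:max_hits]
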