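# Methods

This note documents the models, algorithms and parameter choices behind
genomedesk, the assumptions they make, and what the synthetic test data
does and does not establish about real genomes.

## Data model and store

A collection lives in one sqlite file (schema version 1). Entities:
taxonomy nodes, strains and samples with `(key, source, value)` metadata
triples, genomes → contigs → genes, content-addressed proteins, ortholog
groups and functional labels attached *per protein hash* (so assignments
are shared by every genome carrying a protein), operons, regulons with
binding sites, registered tool configurations, gene annotations, and job
records. Every mutating library call runs in a single transaction;
`audit_store` checks referential integrity, coordinate bounds, operon
invariants and orphaned proteins, and the test suite asserts it stays
clean across operation sequences.

Coordinates are 0-based half-open on the forward strand everywhere inside
the store. GenBank and GFF3 use 1-based inclusive coordinates; conversion
happens exactly once at I/O (`start+1` on export, `start-1` on GFF
re-parse), which keeps interval arithmetic free of off-by-one cases.

Metadata triples carry a `source` field because strain metadata
accumulates from mixed origins (field notes, assays, submitters) and
search results should say where a value came from. Keys are free-form;
no controlled vocabulary is enforced.

## Protein deduplication and incremental ortholog mapping

Proteins are keyed by the lowercase hex MD5 of the amino-acid sequence
(stop stripped, uppercase). Hashing the protein rather than the CDS makes
deduplication robust to synonymous nucleotide differences. MD5 is used as
a content key, not for security; at desk scale accidental collisions are
negligible (and a collision would only merge two protein records, which
`audit_store` would surface via sequence-length mismatch in search).

Ortholog-group assignment deliberately avoids de-novo inference, whose
all-against-all stage is quadratic in collection size. Instead a fixed
reference table maps protein MD5s to precomputed ortholog groups at one
or more taxonomic levels, plus KEGG ortholog/reaction/pathway, EC, GO and
COG-category labels. `assign_orthologs` consults the reference **only for
hashes with no recorded mapping status**; previously assigned *and*
previously-missing hashes are skipped without a lookup, so the work per
update is proportional to the number of novel proteins, not to the store
size. The reference index carries an instrumented lookup counter and the
suite asserts `lookups == novel hashes` for every genome. Hashes absent
from the reference are recorded as `unassigned` so repeated runs do not
retry them; `--retry-unassigned` re-queries them (e.g. after swapping in
a larger reference). A consequence of the three-bucket report
(`skipped_known / assigned / unassigned`) is that previously-missing
hashes count as `skipped_known` on later runs.

An external mapper can replace the packaged table: it receives a FASTA of
novel proteins (headers are the MD5s) and must emit the same reference
TSV dialect. A failing or unparseable tool leaves the store untouched.

When a protein is assigned at several taxonomic levels, operations that
need a single level (neighborhoods, conserved-operon/regulon counting)
default to the *most specific* one, resolved as the level whose OG has
the fewest member proteins in the store, ties broken by level name. This
is a heuristic proxy — a narrower clade covers fewer sequences — chosen
because the reference dialect does not encode the taxonomy of levels;
pass `og_level=` explicitly to override.

## Operon baseline

`call_operons` groups sorted same-strand CDS runs whose intergenic gaps
(`next.start − prev.end`, negative overlaps clamped to 0 and therefore
joined) are at most `max_gap`, default **150 bp**; runs of length ≥ 2
become operons with deterministic ids `genome:contig:index`. 150 bp is a
conventional prokaryotic intergenic cutoff: most within-operon gaps are
below it, most transcription-unit boundaries above. The rule is
transparent and exactly testable (the suite checks it against an
independently coded scan on randomized layouts, plus monotonicity of gene
coverage in `max_gap`); it ignores promoter/terminator signals and
conditional transcription, which a dedicated external predictor can
supply through the plugin contract. Plugin (and built-in) predictions
*replace* a genome's stored operons rather than merging, so re-annotation
is idempotent; rows with unknown locus tags, fewer than two members or
mixed strands are skipped with a report.

## Annotation pipeline

Tools run sequentially per (genome, tool) pair: the runner exports the
genome's protein FASTA, nucleotide FASTA and GFF3 into a job directory,
renders the registered command template by pure placeholder substitution
(no shell interpolation of any imported value), optionally prefixes an
environment-activation line (`conda run -n {env_name}` by default,
suppressible for plain scripts), executes it, validates the produced
6-column TSV (`locus_tag, genome, source, key, value, note`) and imports
it in one transaction. Annotations are unique on
`(gene, source, key, value)`; re-importing a file adds zero rows. One
failed job is recorded with its log and leaves both the store and the
remaining jobs untouched. The sequential in-process runner replaces an
asynchronous task queue on purpose: scheduling is deployment machinery,
and determinism matters more at desk scale. The 6-column TSV schema is
this package's fixed contract — anyone exchanging annotation files with
other systems should map columns explicitly (see `tools/examples/`).

## Neighborhood comparison

* **Similarity.** Candidates are all CDS store-wide sharing the anchor's
  OG at the chosen level (OG-restricted search keeps cost linear in
  family size). Scores are global pairwise alignments, BLOSUM62, affine
  gaps: a gap of length L costs 11 + (L−1)·1. Ranking is by score
  descending, ties by `(genome_id, locus_tag)`; the anchor is always rank
  1; `max_n` is bounded to [10, 200].
* **Distances.** `d(a,b) = 1 − S(a,b)/min(S(a,a), S(b,b))`, clamped to
  [0, 1]. Identical sequences get 0; the min-self-score normalization
  keeps d symmetric and length-aware.
* **Guide tree.** Neighbor joining on the full pairwise matrix, negative
  branch lengths clamped to 0, midpoint rooting, children ordered
  deterministically (smaller subtree first, ties by leaf label). One- and
  two-leaf cases are built directly; a zero-distance star tree that
  cannot be midpoint-rooted is kept unrooted. The suite verifies exact
  recovery of additive 4- and 5-leaf trees against a four-point-condition
  oracle.
* **Rows.** One row per hit: all genes overlapping a symmetric window
  (default 10 kb) around the hit gene's midpoint on its contig, in tree
  leaf order. The window is in base pairs, not gene counts, so gene
  density differences are visible. Rows with a minus-strand hit are
  mirrored (coordinates reflected, strands flipped) so the anchor family
  always points rightward — the standard synteny-view convention.
* **Colors.** OG → color index is a bijection assigned in order of first
  appearance scanning rows top-down, left-to-right, with the anchor's OG
  pinned to 0; genes without an OG at the level get the null color. The
  SVG renderer cycles a 20-color palette.
* **Functional profile.** Per-letter counts of COG-category labels over
  all genes of the view ("KT" increments K and T); unlabeled genes count
  under `unclassified`.
* **Conserved operons/regulons.** The OG set of an operon (or of a
  regulon's targets) is the set of distinct OG ids of its members at one
  level (default: most specific among the query's members). Candidates in
  *other* genomes sharing ≥ `min_shared` (default 2) OGs are ranked by
  shared count. Regulons additionally require the regulator genes to
  share an OG when both sides have one with an assignment; an absent
  regulator imposes no constraint.

## Sequence search

A self-contained seed-and-extend scan over stored sequences with fixed,
documented parameters: exact seeds of k = 11 (nucleotide, both strands)
or k = 4 (protein); ungapped extension in both directions until the
running score drops 20 below its maximum (X-drop); nucleotide scoring
+1/−2, protein BLOSUM62; one best alignment per (subject, strand,
diagonal); hits below `min_identity_pct` (default 80) dropped; ranking by
raw score, ties by subject id. Reverse-strand hits report forward-strand
subject coordinates with strand −1. There are deliberately no E-values
and no gapped extension: results are exact, deterministic, and sufficient
for locating planted or near-identical sequences at desk scale; for
sensitive homology search use a dedicated aligner on the exported FASTA
tracks. Seeds containing N are skipped, so poly-N regions cannot match.

Classification text search matches identifiers exactly (so "K1" does not
match "K12345"); names and function text match by case-insensitive
substring.

## Taxonomy sunburst

Each genome contributes a leaf node (rank "genome", count 1) under its
resolved taxon; internal node counts are subtree genome totals, so every
node's count equals the sum of its children's and the root equals the
collection size — the additivity a sunburst chart needs. Genomes whose
GenBank taxonomy hint (db_xref `taxon:` first, then exact organism name)
does not resolve against the loaded taxonomy are grouped under an
`unclassified` node. A packaged mini taxonomy ships for convenience; full
NCBI dumps rewritten to the 4-column TSV are accepted but never required.

## Synthetic collections: what they do and do not show

The generator plants, identically across genomes: a conserved 4-gene
block (gaps above the operon cutoff, conserved orientation), same-strand
operons per `operon_spec` with internal gaps ≤ min(spec gap, 150) bp,
further shared families, genome-private families, and "orphan" genes
absent from the reference (≈10 % of genes, or fewer if the shared
fraction leaves less room). Family members derive from a family ancestor
by per-residue substitution at `mutation_rate` (default 0.05 — typical
within-genus protein divergence) and are back-translated with uniform
seeded codon choice under the bacterial code, so every `/translation` is
consistent with its spliced CDS and every member's identity to the
ancestor is exact ground truth. Defaults: 10 genomes × 200 genes,
ortholog pool 1200, shared fraction 0.5, operons of sizes 3/4/2. All
randomness flows through one `random.Random(seed)`; the GenBank LOCUS
date is pinned, so equal seeds give byte-identical output on any
platform.

Passing tests on these collections establish the *bookkeeping*
guarantees — exact dedup, lookup counts, coordinate round-trips, operon
rule equivalence, color/tree consistency, planted-match retrieval. They
do not establish robustness to real-genome phenomena the generator omits:
rearrangements and horizontal transfer, paralogs inside one genome,
pseudogenes and frameshifts, fuzzy or compound gene models (parsed, but
not generated), biased codon usage, or taxonomies deeper than four ranks.

## Numerical and degenerate-input choices

* Alignment scores are floats from the alignment backend; ties in ranking
  are broken lexicographically so orderings are total and reproducible.
* `normalized_distance` is clamped into [0, 1]; a non-positive self-score
  (impossible for BLOSUM62 on non-empty sequences) would map to 1.
* Fuzzy-endpoint CDS are imported with a warning and no translation
  re-derivation — truncated proteins are never guessed. CDS translation
  honors `/transl_table`, defaulting to the bacterial code (table 11).
* Empty stores: sunburst returns a root with count 0; site export of an
  empty store is refused ("nothing to export").
* Operon calling on unsorted input fails loudly rather than sorting
  silently, because caller order is part of the contract.
* Store files are opened defensively: non-sqlite bytes → "invalid
  store"; a schema version newer than supported → "unsupported schema".

## Known limitations

* Exact-hash ortholog lookup cannot assign novel (unseen) proteins; that
  is the external mapper plugin's job.
* Sequence search is ungapped; indel-containing homologs fragment into
  separate diagonals and may fall below the identity threshold.
* The similarity measure and tree method behind neighborhoods are this
  package's documented reference behavior (global affine BLOSUM62 + NJ);
  other systems may rank by bit score or precomputed family similarity
  and will order rows differently.
* Regulon conservation compares target/regulator OG sets only; binding
  sites are stored and exported but not compared.
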