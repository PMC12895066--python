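# Static-site export schemas

`export_site(store, outdir)` writes a deterministic tree of JSON files
plus a minimal `index.html`. All JSON is UTF-8, keys sorted, one-space
indent.

```
outdir/
  index.html
  genomes.json
  sunburst.json
  <genome_id>/
    genome.fna       # contig FASTA
    genome.gff3      # GFF3, 1-based inclusive coordinates
    proteins.faa     # headers genome_id|locus_tag|protein_hash
    genes.json
    operons.json
    regulons.json
```

## genomes.json

List of objects:

| field | type | meaning |
|---|---|---|
| genome_id | str | collection-unique genome id |
| strain_id / sample_id | str or null | linked strain / sample |
| taxon_id / taxon_name | str or null | resolved taxonomy node |
| counts | object | contigs, genes, operons, regulons |

## sunburst.json

Recursive node: `{name, rank, taxon_id, count, children}`. Each genome is
a leaf node of rank `"genome"` with count 1, so every node's `count`
equals the sum of its children's counts and the root count equals the
number of genomes. Unresolved genomes sit under an `unclassified` node.

## genes.json

List of gene objects: `gene_id` (`genome_id:locus_tag`), `locus_tag`,
`contig_id`, `start`/`end` (0-based half-open), `strand` (+1/−1),
`feature_type` (CDS/tRNA/rRNA/other), `name`, `function_text`,
`protein_hash` (null for non-CDS).

## operons.json

List of `{operon_id, contig_id, start, end, strand, source, gene_ids}`;
`gene_ids` are ordered by position and always reference `genes.json`
entries of the same genome (checked by `audit_site`).

## regulons.json

List of `{regulon_id, name, regulator_gene_id, target_gene_ids, sites}`
with `sites` entries `{site_id, contig_id, start, end, strand, sequence}`.

`audit_site(outdir)` verifies: sunburst root count == genomes.json
length, per-node count additivity, every operon/regulon gene reference
resolvable, and listing gene counts == genes.json lengths.
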