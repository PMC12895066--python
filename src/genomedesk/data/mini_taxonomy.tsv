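# Mini taxonomy in the package's TSV layout (NCBI-style numeric ids as text).
# Full dumps rewritten to these four columns are accepted by load_taxonomy.
taxon_id	name	rank	parent_id
1	root	no rank	1
2	Bacteria	superkingdom	1
1224	Pseudomonadota	phylum	2
1236	Gammaproteobacteria	class	1224
91347	Enterobacterales	order	1236
543	Enterobacteriaceae	family	91347
561	Escherichia	genus	543
562	Escherichia coli	species	561
590	Salmonella	genus	543
28901	Salmonella enterica	species	590
1239	Bacillota	phylum	2
91061	Bacilli	class	1239
1385	Bacillales	order	91061
186817	Bacillaceae	family	1385
1386	Bacillus	genus	186817
1423	Bacillus subtilis	species	1386
10	Synthetica	genus	2
20	Artificiella	genus	2
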