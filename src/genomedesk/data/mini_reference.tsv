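# Mini ortholog-group reference (synthetic sequences) in the reference TSV
# dialect: keyed by protein_seq here, so MD5 keys are computed on load.
# Multi-valued label cells are comma-separated; empty cells allowed.
protein_seq	og_id	level	kegg_ko	kegg_pathway	ec	go	cog_category
MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ	OG00001	Bacteria	K00001	map00010	1.1.1.1	GO:0008270	C
MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ	2ABCD	Gammaproteobacteria	K00001	map00010	1.1.1.1	GO:0008270	C
MSKGEELFTGVVPILVELDGDVNGHKFSVSGEG	OG00002	Bacteria	K00002	map00010		GO:0005515	E
MVLSPADKTNVKAAWGKVGAHAGEYGAEALERM	OG00003	Bacteria	K00003	map00020	2.7.1.1		KT
MNIFEMLRIDEGLRLKIYKDTEGYYTIGIGHLL	OG00004	Bacteria	K00004	map00020	3.2.1.17	GO:0003796	M
MAHHHHHHVGTGSNITGRGSNSGSSGSEFELRR	OG00005	Bacteria	K00005			GO:0046872	J
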