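# Diagnostic-site definitions for a stylised subset of the mitochondrial
# haplogroup tree: the lineage path to haplogroup U6 and its immediate
# derived branches, plus the U5 sister clade.  One row per diagnostic site;
# the parent column links each clade to the tree (root = REF, the reference
# node, which has no diagnostics).  Alleles at sites whose defining allele
# is not fixed by convention default to the transition of the packaged
# reference base (alt_rule=transition); alt_rule=explicit marks sites with
# an explicitly stated allele.
haplogroup	parent	position	ref	alt	alt_rule
N	REF	8701	G	A	transition
N	REF	9540	A	G	transition
N	REF	10398	A	G	transition
R	N	12705	T	C	transition
R	N	16223	G	A	transition
U	R	11467	G	A	transition
U	R	12308	A	G	transition
U	R	12372	T	C	transition
U5	U	3197	C	T	transition
U5	U	16270	T	C	transition
U6	U	3348	T	C	transition
U6	U	16172	T	C	transition
U6a'b'd	U6	16219	C	T	transition
U6c	U6	150	C	T	transition
U6c	U6	437	C	T	transition
U6c	U6	793	C	T	transition
U6c	U6	3688	T	C	transition
U6c	U6	4965	T	C	transition
U6c	U6	5081	T	C	transition
U6c	U6	11013	C	T	transition
U6c	U6	13879	A	G	transition
U6c	U6	15244	G	A	transition
U6c	U6	16169	A	G	transition
U6c	U6	16189	A	G	transition
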