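# Synthetic stand-in for the 15-substitution haplotype of the Pestera
# Muierii 1 (PM1) basal-U6 mitogenome, expressed against the packaged
# synthetic reference.  Only three sites of the real haplotype are public
# (the U6 diagnostics 3348 and 16172, and the private mutation T10517A);
# those rows are marked source=stated.  The remaining twelve substitutions
# are inferred placeholders chosen so the haplotype carries the full
# diagnostic path N -> R -> U -> U6 plus four non-diagnostic changes,
# totalling 15 substitutions; they are marked source=inferred.
position	ref	alt	source
73	G	A	inferred
263	G	A	inferred
750	G	A	inferred
1438	A	G	inferred
3348	T	C	stated
8701	G	A	inferred
9540	A	G	inferred
10398	A	G	inferred
10517	T	A	stated
11467	G	A	inferred
12308	A	G	inferred
12372	T	C	inferred
12705	T	C	inferred
16172	T	C	stated
16223	G	A	inferred
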