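chrom	pos	ref	alt	variant_class	tumor_depth	tumor_alt	normal_depth	normal_alt	caller	downstream_20nt	exonic	trinuc_context
chr1	100	C	T	SNV	25	4	12	0	fixture	.	1	ACA
chr1	200	C	T	SNV	20	5	12	0	fixture	.	1	ACA
chr1	300	C	T	SNV	21	5	10	0	fixture	.	1	ACA
chr1	400	C	T	SNV	1000	99	12	0	fixture	.	1	ACA
chr1	500	C	T	SNV	1000	100	12	0	fixture	.	1	ACA
chr1	600	C	T	SNV	21	3	11	0	fixture	.	1	ACA
chr2	100	C	T	SNV	10	5	100	6	fixture	.	1	ACA
chr2	200	C	T	SNV	9	5	100	0	fixture	.	1	ACA
chr2	300	C	T	SNV	100	4	100	0	fixture	.	1	ACA
chr2	400	C	T	SNV	100	5	100	0	fixture	.	1	ACA
chr2	500	C	T	SNV	100	5	100	7	fixture	.	1	ACA
chr2	600	C	T	SNV	200	9	100	0	fixture	.	1	ACA
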