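sample	gene	outcome	chrom	pos	ref	alt
3CC-a	BRCA1	negative_full_screen	.	.	.	.
3CC-a	BRCA2	negative_full_screen	.	.	.	.
4CA-a	BRCA1	negative_full_screen	.	.	.	.
4CA-a	BRCA2	negative_full_screen	.	.	.	.
1EA-a	BRCA1	negative_full_screen	.	.	.	.
1EA-a	BRCA2	negative_full_screen	.	.	.	.
1EAC-a	BRCA1	negative_full_screen	.	.	.	.
1EAC-a	BRCA2	negative_full_screen	.	.	.	.
1CE-a	BRCA1	negative_full_screen	.	.	.	.
1CE-a	BRCA2	negative_full_screen	.	.	.	.
1CD-a	BRCA1	negative_full_screen	.	.	.	.
1CD-a	BRCA2	negative_full_screen	.	.	.	.
1CB-a	BRCA2	positive	chr13	32339966	AGTAA	-
1CAD-a	BRCA1	positive	chr17	43051071	A	C
1CAD-f	BRCA1	negative_targeted	chr17	43051071	A	C
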