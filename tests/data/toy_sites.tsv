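site_id	chrom	pos	strand	kind	annotated	cryptic
s1	chr1	100	+	donor	1	0
s2	chr1	120	+	donor	0	0
s3	chr1	145	+	donor	1	0
s4	chr1	300	+	donor	0	1
s5	chr1	500	+	donor	1	0
s6	chr1	525	+	donor	1	0
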