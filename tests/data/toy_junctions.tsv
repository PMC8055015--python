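site_id	sample_id	tissue	reads	entropy
s1	A	liver	50	2.0
s1	B	lung	40	2.0
s2	A	liver	3	2.0
s2	B	lung	4	2.0
s3	A	liver	10	2.0
s3	D	lung	4	1.0
s4	A	liver	3	2.0
s4	C	liver	5	2.0
s5	A	liver	30	2.0
s5	B	lung	25	2.0
s6	A	liver	5	2.0
s6	B	lung	6	2.0
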