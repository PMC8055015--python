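site_id	expressed	kept_after_artifact_filter	cluster_id	cluster_passes	rank
s1	1	1	c1	1	1
s2	1	1	c1	1	3
s3	0	0	c1	1	2
s4	0	0	standalone	0	0
s5	1	1	c2	1	1
s6	1	0	c2	1	2
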