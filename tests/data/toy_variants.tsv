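site_id	carrier_samples
s6	A,B
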