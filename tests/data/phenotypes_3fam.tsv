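individual_id	phenotype_id	status
f1_f	asthma	1
f1_m	asthma	0
f1_c1	asthma	1
f1_c2	asthma	0
f2_f	asthma	0
f2_m	asthma	1
f2_c1	asthma	0
f2_c2	asthma	0
f2_c3	asthma	1
f3_f	asthma	0
f3_c1	asthma	0
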