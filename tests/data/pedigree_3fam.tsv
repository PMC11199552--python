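individual_id	family_id	role	sex	birth_year	months_enrolled	location_id
f1_f	f1	father	M	1962	96	A
f1_m	f1	mother	F	1964	96	A
f1_c1	f1	child	F	1992	96	A
f1_c2	f1	child	M	1995	96	A
f2_f	f2	father	M	1958	84	B
f2_m	f2	mother	F	1960	84	B
f2_c1	f2	child	M	1988	84	B
f2_c2	f2	child	F	1990	84	B
f2_c3	f2	child	M	1993	84	B
f3_f	f3	father	M	1970	72	C
f3_c1	f3	child	F	2000	72	C
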