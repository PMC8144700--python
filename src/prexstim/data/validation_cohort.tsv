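subject_id	sex	epilepsy_type	age_onset	age_implant	epilepsy_duration	vns_duration	treatment	responder
1	M	Extra-TLE	20	22	2	5	VPA,TPM	yes
2	M	Extra-TLE	7	22	15	3	ZNS,CBZ,LCM,CLZ	yes
3	M	Extra-TLE	23	39	16	4	LCM,GBP	yes
4	F	Extra-TLE	8	28	20	3	LTG,VPA	yes
5	F	TLE	30	53	23	3	ZNS,CLZ,VPA	yes
6	F	TLE	60	71	11	4	CBZ,ZNS,PGB	yes
7	M	Extra-TLE	11	25	14	4	ESL,LTG,VPA,PHT,CLZ	no
8	M	TLE	12	42	30	4	CBZ,VPA,LTG	no
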