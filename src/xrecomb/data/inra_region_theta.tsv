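# Per-F1-female recombination fractions over broad SSC-X intervals (>10 cM),
# INRA Large White x Meishan pedigree.  n_offspring: genotyped F2 per female.
# Empty theta: female uninformative for that interval (double heterozygosity
# absent or markers not scoreable).
subfamily	female	n_offspring	interval	theta
1	910002	76	SW980-SW1903	
1	910009	72	SW980-SW1903	
1	910010	96	SW980-SW1903	
1	910013	55	SW980-SW1903	
2	910014	83	SW980-SW1903	0.228
2	910016	38	SW980-SW1903	0.184
2	910020	69	SW980-SW1903	0.206
3	910018	45	SW980-SW1903	0.231
4	910069	62	SW980-SW1903	0.213
4	910071	68	SW980-SW1903	0.246
4	910072	63	SW980-SW1903	0.206
4	910074	83	SW980-SW1903	0.241
5	910084	50	SW980-SW1903	0.190
5	910086	27	SW980-SW1903	0.222
6	910095	62	SW980-SW1903	0.177
6	910096	42	SW980-SW1903	0.171
6	910097	37	SW980-SW1903	0.243
1	910002	76	SW1903-SW2456	
1	910009	72	SW1903-SW2456	
1	910010	96	SW1903-SW2456	
1	910013	55	SW1903-SW2456	
2	910014	83	SW1903-SW2456	0.316
2	910016	38	SW1903-SW2456	0.342
2	910020	69	SW1903-SW2456	0.232
3	910018	45	SW1903-SW2456	0.154
4	910069	62	SW1903-SW2456	0.295
4	910071	68	SW1903-SW2456	0.123
4	910072	63	SW1903-SW2456	0.111
4	910074	83	SW1903-SW2456	0.190
5	910084	50	SW1903-SW2456	0.190
5	910086	27	SW1903-SW2456	0.231
6	910095	62	SW1903-SW2456	0.113
6	910096	42	SW1903-SW2456	0.250
6	910097	37	SW1903-SW2456	0.081
1	910002	76	SW2456-SW259	0.184
1	910009	72	SW2456-SW259	0.127
1	910010	96	SW2456-SW259	0.106
1	910013	55	SW2456-SW259	0.109
2	910014	83	SW2456-SW259	0.241
2	910016	38	SW2456-SW259	0.132
2	910020	69	SW2456-SW259	0.159
3	910018	45	SW2456-SW259	0.077
4	910069	62	SW2456-SW259	0.161
4	910071	68	SW2456-SW259	0.154
4	910072	63	SW2456-SW259	0.175
4	910074	83	SW2456-SW259	0.177
5	910084	50	SW2456-SW259	0.190
5	910086	27	SW2456-SW259	0.269
6	910095	62	SW2456-SW259	0.210
6	910096	42	SW2456-SW259	0.175
6	910097	37	SW2456-SW259	0.027
1	910002	76	UMNP71-SW1943	0.303
1	910009	72	UMNP71-SW1943	0.417
1	910010	96	UMNP71-SW1943	0.271
1	910013	55	UMNP71-SW1943	0.091
2	910014	83	UMNP71-SW1943	0.253
2	910016	38	UMNP71-SW1943	0.211
2	910020	69	UMNP71-SW1943	0.159
3	910018	45	UMNP71-SW1943	0.222
4	910069	62	UMNP71-SW1943	0.145
4	910071	68	UMNP71-SW1943	0.206
4	910072	63	UMNP71-SW1943	0.206
4	910074	83	UMNP71-SW1943	0.120
5	910084	50	UMNP71-SW1943	0.280
5	910086	27	UMNP71-SW1943	0.148
6	910095	62	UMNP71-SW1943	0.242
6	910096	42	UMNP71-SW1943	0.262
6	910097	37	UMNP71-SW1943	0.189
1	910002	76	SW1943-SW1608	0.105
1	910009	72	SW1943-SW1608	0.085
1	910010	96	SW1943-SW1608	0.137
1	910013	55	SW1943-SW1608	0.164
2	910014	83	SW1943-SW1608	0.146
2	910016	38	SW1943-SW1608	0.132
2	910020	69	SW1943-SW1608	0.159
3	910018	45	SW1943-SW1608	0.133
4	910069	62	SW1943-SW1608	0.097
4	910071	68	SW1943-SW1608	0.132
4	910072	63	SW1943-SW1608	0.143
4	910074	83	SW1943-SW1608	0.181
5	910084	50	SW1943-SW1608	
5	910086	27	SW1943-SW1608	
6	910095	62	SW1943-SW1608	0.081
6	910096	42	SW1943-SW1608	0.024
6	910097	37	SW1943-SW1608	0.189
1	910002	76	SW1608-S0218	0.158
1	910009	72	SW1608-S0218	0.086
1	910010	96	SW1608-S0218	0.108
1	910013	55	SW1608-S0218	0.127
2	910014	83	SW1608-S0218	0.064
2	910016	38	SW1608-S0218	0.184
2	910020	69	SW1608-S0218	0.059
3	910018	45	SW1608-S0218	0.308
4	910069	62	SW1608-S0218	0.210
4	910071	68	SW1608-S0218	0.091
4	910072	63	SW1608-S0218	0.143
4	910074	83	SW1608-S0218	0.157
5	910084	50	SW1608-S0218	
5	910086	27	SW1608-S0218	
6	910095	62	SW1608-S0218	0.161
6	910096	42	SW1608-S0218	0.073
6	910097	37	SW1608-S0218	0.054
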