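# Per-F1-female recombination fractions over the fine interval UMNP891-UMNP93,
# INRA Large White x Meishan pedigree, with each female's paternal (Large
# White) and maternal (Meishan) four-marker haplotype label over the interval.
subfamily	female	paternal_hap	maternal_hap	n	theta
1	910002	2413	1122	76	0.053
1	910009	2413	1122	72	0.139
1	910010	2413	1122	95	0.116
1	910013	2413	4311	55	0
2	910014	5113	1222	83	0.096
2	910016	5113	3221	38	0.105
2	910020	5113	1222	68	0.015
3	910018	5113	4311	46	0
4	910069	2413	1222	62	0.032
4	910071	2413	1222	68	0.044
4	910072	2413	1222	63	0.048
4	910074	2413	5221	83	0.012
5	910084	6323	1222	51	0.118
5	910086	6323	1222	27	0.037
6	910095	5413	1222	62	0.048
6	910096	5413	1222	42	0.048
6	910097	5413	4311	37	0.027
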