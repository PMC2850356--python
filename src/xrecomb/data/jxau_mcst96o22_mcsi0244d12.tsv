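# Recombination fractions over the interval MCST96O22-MCSI0244D12 in the JXAU
# White Duroc x Erhualian pedigree.  level "family": the two paternal half-sib
# families of F1 females (one per F0 boar, haplotype in `hap`); level
# "maternal_0F11"/"maternal_0F21": F1 females within that family grouped by
# the maternal (Erhualian) haplotype they carry.  `dam`/`suffix` keep groups
# with identical haplotype labels distinct, as reported.
level	dam	hap	suffix	n	theta
family	0F11	5414	12	518	0.071
family	0F21	2514	12	775	0.084
maternal_0F11	0F11_7	5325	17	95	0.042
maternal_0F11	0F11_1	5122	35	12	0.083
maternal_0F11	0F11_1	5321	13	64	0.047
maternal_0F11	0F11_5	1321	14	79	0.076
maternal_0F11	0F11_5	1321	17	137	0.095
maternal_0F11	0F11_5	1325	17	18	0.056
maternal_0F11	0F11_5	5321	14	56	0.107
maternal_0F11	0F11_5	5325	17	20	0.150
maternal_0F11	0F11_9	5121	16	37	0.000
maternal_0F21	0F21_1	1116	17	35	0.000
maternal_0F21	0F21_1	1321	17	60	0.167
maternal_0F21	0F21_7	5325	17	72	0.056
maternal_0F21	0F21_7	5621	14	24	0.042
maternal_0F21	0F21_1	5121	13	23	0.000
maternal_0F21	0F21_1	5122	35	156	0.051
maternal_0F21	0F21_1	5225	11	12	0.083
maternal_0F21	0F21_1	5321	13	133	0.120
maternal_0F21	0F21_1	5341	38	22	0.227
maternal_0F21	0F21_5	1125	49	28	0.036
maternal_0F21	0F21_5	1321	14	153	0.065
maternal_0F21	0F21_5	5121	14	50	0.140
maternal_0F21	0F21_9	5121	16	7	0.286
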