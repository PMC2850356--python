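# Consensus marker order on the pig X chromosome (SSC-X).
# cM: female linkage map of the INRA (Large White x Meishan) pedigree, Kosambi.
# Mb: pig BAC clone map position.  alt_Mb: homologous human X (HSA-X) position.
# jxau_cM: female linkage map of the JXAU (White Duroc x Erhualian) pedigree.
# Empty fields: marker not placed on that map.  par=1: pseudoautosomal.
name	order	cM	Mb	alt_Mb	par	jxau_cM
SW949	1		0		1	0
SW980	2	0	7.65	11.38	0	16
SW1903	3	23.7	21.28	25.47	0	46.6
SW2456	4	46	38.46	42.14	0	65.5
UMNP1174	5	56.5	42.25	47.22	0	76.1
SW2476	6		42.70	48.32	0	
SWR1861	7	59.5			0	78.7
UMNP448	8		43.78	50.42	0	
BE102J23.0003R1	9		44.30	50.94	0	
SW259	10	62.7	54.21	63.35	0	79.9
MCSE3F14	11		55.27	65.30	0	
BE145J20.0597R1	12		58.94	69.06	0	
MCST2J13	13		63.85	74.74	0	
SW1994	14	62.8	67.72	79.92	0	80.1
MCSE58H4	15		70.38	83.46	0	
BE8B11.0679Y1	16		77.85	97.31	0	
MCSE65L7	17		82.80	91.66	0	
UMNP71	18	62.8	84.83	93.18	0	80.2
UMNP374	19		77.38	97.00	0	
UMNP1218	20	62.8	80.02	99.84	0	80.4
BE497I6FB48R	21		88.52	103.76	0	
BE218F2FB67K	22	63.2	89.33	104.46	0	
SERPINA7E2B114M	23		89.90	105.02	0	80.9
BE151D17.0014Y1	24		90.42	105.88	0	
SW1426	25	65.7	91.73	107.08	0	83.5
BE32D24.0584R1	26		91.73	107.03	0	
BE276J1FB107R	27		91.87	107.20	0	
BE206D8.0949R1	28		92.18	107.47	0	
BE386O15.1136R1	29		92.27	107.86	0	
IRS4.Y1	30		93.33	107.86	0	85.9
MCSE313H19.0244	31	67.5	93.72	108.38	0	
ACSL4I3B259R	32		93.87	108.58	0	
ACSL4I3B359M	33	67.9	93.87	108.58	0	87
MCSE231M24	34	69.8	92.48	109.41	0	88.1
MCSE12P4.1041	35	70.1	92.78	109.65	0	
MCSE12P4.0112	36	71.2			0	
MCST96O22	37	72.8	92.99	110.22	0	90.5
UMNP891	38	73.4			0	90.9
BE95P6.0900R1	39		94.38	110.48	0	
MCSE347J6	40	74.5	94.52	110.63	0	92.3
BE412O5B120R	41		95.59	111.90	0	
BE80C18FB136W	42	77	95.76		0	
BE504J7.0664Y1	43		97.03		0	
SW1522	44	77.5	97.35	113.73	0	95.2
HTR2CI3B151R	45		97.56	113.90	0	95
BE371L5.0001Y1	46		97.88	114.30	0	
BE185O8FB63S	47	78.3	98.02	114.48	0	
BE219E21.0003M1	48		98.16	114.79	0	
UMNP93	49	79.1			0	96.5
BE28B16.0529Y1	50		99.34		0	
UMNP870	51		102.50	117.67	0	
MCSI0244D12	52	81.6		118.15	0	98.8
SLC25A5I2B103DE	53	82.5	102.00	118.36	0	99.5
UMNP1008	54		101.68	118.75	0	
SW1943	55	85	107.17	126.14	0	101.5
SW1608	56	98.4	112.30	132.31	0	114.1
SW707	57				0	120.8
SW2137	58				0	
S0218	59	111.4	117.02		0	
SW2588	60		125.93	150.01	0	159.7
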