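case_id	disease	age	genotype	filament_types	other_filaments
1	AD	79	SS	I-s:21;I-d:5	Abeta:37;tau:37
2	FAD	67	TT	I-s:16;I-d:1	Abeta:27;tau:56
3	EOAD	58	TT	I-s:31;I-d:<1	Abeta:15;tau:54
4	PA	59	TS	I-s:23;I-d:1	Abeta:76
5	CBD	74	TS	I-s:6;I-d:1	tau:93
6	CBD	79	TS	I-s:11;I-d:1	tau:88
7	FTDP-17T	55	TT	I-s:23;I-d:3	tau:74
8	AGD	85	TS	III-s:8	tau:92
9	AGD	90	TT	I-s:29;I-d:3	tau:68
10	LNT	66	TT	I-s:17;I-d:2	tau:81
11	ARTAG	85	SS	III-s:67	tau:11;Abeta:22
12	PD	87	SS	III-s:13	unknown:45;tau:42
13	PDD	64	TT	I-s:50;I-d:6	Abeta:28;unknown:16
14	FPD	67	SS	III-s:4	unknown:96
15	DLB	74	SS	III-s:36	unknown:64
16	DLB	73	TS	I-s:30;I-d:1	Abeta:62;unknown:7
17	MSA	85	SS	III-s:27;III-d:<1	alphaS:73
18	MSA	70	TS	I-s:13;I-d:5	alphaS:82
19	MSA	68	TT	IIa-s:11;IIb-s:4;II-d:<1	alphaS:85
20	FTLD-TDP-A	66	TS	I-s:21;I-d:30	Abeta:46;unknown:3
21	FTLD-TDP-C	65	SS	III-s:77	unknown:23
22	ALS-TDP-B	63	SS	III-s:46;III-d:10	unknown:24;Abeta:19
23	Control	75	TS	I-s:83;I-d:17	undefined:<1
24	Control	84	TS	I-s:67;I-d:33	undefined:<1
25	Control	101	TT	I-s:92;I-d:8	undefined:<1
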