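index	abbreviation	description	lobe	hemisphere	pair_id
1	PreCG.L	Precentral gyrus	Frontal	L	1
2	PreCG.R	Precentral gyrus	Frontal	R	1
3	SFGdor.L	Superior frontal gyrus, dorsolateral	Frontal	L	2
4	SFGdor.R	Superior frontal gyrus, dorsolateral	Frontal	R	2
5	ORBsup.L	Superior frontal gyrus, orbital part	Frontal	L	3
6	ORBsup.R	Superior frontal gyrus, orbital part	Frontal	R	3
7	MFG.L	Middle frontal gyrus, lateral part	Frontal	L	4
8	MFG.R	Middle frontal gyrus, lateral part	Frontal	R	4
9	ORBmid.L	Middle frontal gyrus, orbital part	Frontal	L	5
10	ORBmid.R	Middle frontal gyrus, orbital part	Frontal	R	5
11	IFGoperc.L	Opercular part of inferior frontal gyrus	Frontal	L	6
12	IFGoperc.R	Opercular part of inferior frontal gyrus	Frontal	R	6
13	IFGtriang.L	Area triangularis	Frontal	L	7
14	IFGtriang.R	Area triangularis	Frontal	R	7
15	ORBinf.L	Orbital part of inferior frontal gyrus	Frontal	L	8
16	ORBinf.R	Orbital part of inferior frontal gyrus	Frontal	R	8
17	ROL.L	Rolandic operculum	Frontal	L	9
18	ROL.R	Rolandic operculum	Frontal	R	9
19	SMA.L	Supplementary motor area	Frontal	L	10
20	SMA.R	Supplementary motor area	Frontal	R	10
21	OLF.L	Olfactory cortex	Frontal	L	11
22	OLF.R	Olfactory cortex	Frontal	R	11
23	SFGmed.L	Superior frontal gyrus, medial part	Frontal	L	12
24	SFGmed.R	Superior frontal gyrus, medial part	Frontal	R	12
25	ORBsupmed.L	Superior frontal gyrus, medial orbital part	Frontal	L	13
26	ORBsupmed.R	Superior frontal gyrus, medial orbital part	Frontal	R	13
27	REC.L	Gyrus rectus	Frontal	L	14
28	REC.R	Gyrus rectus	Frontal	R	14
29	INS.L	Insula	Insular	L	15
30	INS.R	Insula	Insular	R	15
31	ACG.L	Anterior cingulate gyrus	Limbic	L	16
32	ACG.R	Anterior cingulate gyrus	Limbic	R	16
33	DCG.L	Middle cingulate	Limbic	L	17
34	DCG.R	Middle cingulate	Limbic	R	17
35	PCG.L	Posterior cingulate gyrus	Limbic	L	18
36	PCG.R	Posterior cingulate gyrus	Limbic	R	18
37	HIP.L	Hippocampus	Limbic	L	19
38	HIP.R	Hippocampus	Limbic	R	19
39	PHG.L	Parahippocampal gyrus	Limbic	L	20
40	PHG.R	Parahippocampal gyrus	Limbic	R	20
41	AMYG.L	Amygdala	Limbic	L	21
42	AMYG.R	Amygdala	Limbic	R	21
43	CAL.L	Calcarine sulcus	Occipital	L	22
44	CAL.R	Calcarine sulcus	Occipital	R	22
45	CUN.L	Cuneus	Occipital	L	23
46	CUN.R	Cuneus	Occipital	R	23
47	LING.L	Lingual gyrus	Occipital	L	24
48	LING.R	Lingual gyrus	Occipital	R	24
49	SOG.L	Superior occipital	Occipital	L	25
50	SOG.R	Superior occipital	Occipital	R	25
51	MOG.L	Middle occipital	Occipital	L	26
52	MOG.R	Middle occipital	Occipital	R	26
53	IOG.L	Inferior occipital	Occipital	L	27
54	IOG.R	Inferior occipital	Occipital	R	27
55	FFG.L	Fusiform gyrus	Temporal	L	28
56	FFG.R	Fusiform gyrus	Temporal	R	28
57	PoCG.L	Postcentral gyrus	Parietal	L	29
58	PoCG.R	Postcentral gyrus	Parietal	R	29
59	SPG.L	Superior parietal lobule	Parietal	L	30
60	SPG.R	Superior parietal lobule	Parietal	R	30
61	IPL.L	Inferior parietal lobule	Parietal	L	31
62	IPL.R	Inferior parietal lobule	Parietal	R	31
63	SMG.L	Supramarginal gyrus	Parietal	L	32
64	SMG.R	Supramarginal gyrus	Parietal	R	32
65	ANG.L	Angular gyrus	Parietal	L	33
66	ANG.R	Angular gyrus	Parietal	R	33
67	PCUN.L	Precuneus	Parietal	L	34
68	PCUN.R	Precuneus	Parietal	R	34
69	PCL.L	Paracentral lobule	Parietal	L	35
70	PCL.R	Paracentral lobule	Parietal	R	35
71	CAU.L	Caudate nucleus	Basal ganglia	L	36
72	CAU.R	Caudate nucleus	Basal ganglia	R	36
73	PUT.L	Putamen	Basal ganglia	L	37
74	PUT.R	Putamen	Basal ganglia	R	37
75	PAL.L	Globus pallidus	Basal ganglia	L	38
76	PAL.R	Globus pallidus	Basal ganglia	R	38
77	STN.L	Subthalamic nucleus	Basal ganglia	L	39
78	STN.R	Subthalamic nucleus	Basal ganglia	R	39
79	THA.L	Thalamus	Basal ganglia	L	40
80	THA.R	Thalamus	Basal ganglia	R	40
81	HES.L	Transverse temporal gyri	Temporal	L	41
82	HES.R	Transverse temporal gyri	Temporal	R	41
83	STG.L	Superior temporal gyrus	Temporal	L	42
84	STG.R	Superior temporal gyrus	Temporal	R	42
85	TPOsup.L	Superior temporal pole	Temporal	L	43
86	TPOsup.R	Superior temporal pole	Temporal	R	43
87	MTG.L	Middle temporal gyrus	Temporal	L	44
88	MTG.R	Middle temporal gyrus	Temporal	R	44
89	TPOmid.L	Middle temporal pole	Temporal	L	45
90	TPOmid.R	Middle temporal pole	Temporal	R	45
91	ITG.L	Inferior temporal gyrus	Temporal	L	46
92	ITG.R	Inferior temporal gyrus	Temporal	R	46
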