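index	name	hemisphere	affiliation	kind
0	L_bankssts	left	Frontotemporal	cortical
1	L_caudalanteriorcingulate	left	Frontotemporal	cortical
2	L_caudalmiddlefrontal	left	Premotor	cortical
3	L_cuneus	left	Sensory	cortical
4	L_entorhinal	left	Frontotemporal	cortical
5	L_frontalpole	left	Frontotemporal	cortical
6	L_fusiform	left	Frontotemporal	cortical
7	L_inferiorparietal	left	Frontotemporal	cortical
8	L_inferiortemporal	left	Frontotemporal	cortical
9	L_insula	left	Frontotemporal	cortical
10	L_isthmuscingulate	left	Frontotemporal	cortical
11	L_lateraloccipital	left	Sensory	cortical
12	L_lateralorbitofrontal	left	Frontotemporal	cortical
13	L_lingual	left	Sensory	cortical
14	L_medialorbitofrontal	left	Frontotemporal	cortical
15	L_middletemporal	left	Frontotemporal	cortical
16	L_paracentral	left	Motor	cortical
17	L_parahippocampal	left	Frontotemporal	cortical
18	L_parsopercularis	left	Frontotemporal	cortical
19	L_parsorbitalis	left	Frontotemporal	cortical
20	L_parstriangularis	left	Frontotemporal	cortical
21	L_pericalcarine	left	Sensory	cortical
22	L_postcentral	left	Sensory	cortical
23	L_posteriorcingulate	left	Frontotemporal	cortical
24	L_precentral	left	Motor	cortical
25	L_precuneus	left	Frontotemporal	cortical
26	L_rostralanteriorcingulate	left	Frontotemporal	cortical
27	L_rostralmiddlefrontal	left	Frontotemporal	cortical
28	L_superiorfrontal	left	Premotor	cortical
29	L_superiorparietal	left	Sensory	cortical
30	L_superiortemporal	left	Frontotemporal	cortical
31	L_supramarginal	left	Sensory	cortical
32	L_temporalpole	left	Frontotemporal	cortical
33	L_transversetemporal	left	Sensory	cortical
34	R_bankssts	right	Frontotemporal	cortical
35	R_caudalanteriorcingulate	right	Frontotemporal	cortical
36	R_caudalmiddlefrontal	right	Premotor	cortical
37	R_cuneus	right	Sensory	cortical
38	R_entorhinal	right	Frontotemporal	cortical
39	R_frontalpole	right	Frontotemporal	cortical
40	R_fusiform	right	Frontotemporal	cortical
41	R_inferiorparietal	right	Frontotemporal	cortical
42	R_inferiortemporal	right	Frontotemporal	cortical
43	R_insula	right	Frontotemporal	cortical
44	R_isthmuscingulate	right	Frontotemporal	cortical
45	R_lateraloccipital	right	Sensory	cortical
46	R_lateralorbitofrontal	right	Frontotemporal	cortical
47	R_lingual	right	Sensory	cortical
48	R_medialorbitofrontal	right	Frontotemporal	cortical
49	R_middletemporal	right	Frontotemporal	cortical
50	R_paracentral	right	Motor	cortical
51	R_parahippocampal	right	Frontotemporal	cortical
52	R_parsopercularis	right	Frontotemporal	cortical
53	R_parsorbitalis	right	Frontotemporal	cortical
54	R_parstriangularis	right	Frontotemporal	cortical
55	R_pericalcarine	right	Sensory	cortical
56	R_postcentral	right	Sensory	cortical
57	R_posteriorcingulate	right	Frontotemporal	cortical
58	R_precentral	right	Motor	cortical
59	R_precuneus	right	Frontotemporal	cortical
60	R_rostralanteriorcingulate	right	Frontotemporal	cortical
61	R_rostralmiddlefrontal	right	Frontotemporal	cortical
62	R_superiorfrontal	right	Premotor	cortical
63	R_superiorparietal	right	Sensory	cortical
64	R_superiortemporal	right	Frontotemporal	cortical
65	R_supramarginal	right	Sensory	cortical
66	R_temporalpole	right	Frontotemporal	cortical
67	R_transversetemporal	right	Sensory	cortical
68	L_thalamus	left	Subcortical/Cerebellar	subcortical
69	L_caudate	left	Subcortical/Cerebellar	subcortical
70	L_putamen	left	Subcortical/Cerebellar	subcortical
71	L_pallidum	left	Subcortical/Cerebellar	subcortical
72	L_hippocampus	left	Subcortical/Cerebellar	subcortical
73	L_amygdala	left	Subcortical/Cerebellar	subcortical
74	L_accumbens	left	Subcortical/Cerebellar	subcortical
75	L_ventraldc	left	Subcortical/Cerebellar	subcortical
76	R_thalamus	right	Subcortical/Cerebellar	subcortical
77	R_caudate	right	Subcortical/Cerebellar	subcortical
78	R_putamen	right	Subcortical/Cerebellar	subcortical
79	R_pallidum	right	Subcortical/Cerebellar	subcortical
80	R_hippocampus	right	Subcortical/Cerebellar	subcortical
81	R_amygdala	right	Subcortical/Cerebellar	subcortical
82	R_accumbens	right	Subcortical/Cerebellar	subcortical
83	R_ventraldc	right	Subcortical/Cerebellar	subcortical
84	L_cerebellum_I_IV	left	Subcortical/Cerebellar	cerebellar
85	L_cerebellum_V	left	Subcortical/Cerebellar	cerebellar
86	L_cerebellum_VI	left	Subcortical/Cerebellar	cerebellar
87	L_cerebellum_crusI	left	Subcortical/Cerebellar	cerebellar
88	L_cerebellum_crusII	left	Subcortical/Cerebellar	cerebellar
89	L_cerebellum_VIIb	left	Subcortical/Cerebellar	cerebellar
90	L_cerebellum_VIIIa	left	Subcortical/Cerebellar	cerebellar
91	L_cerebellum_VIIIb	left	Subcortical/Cerebellar	cerebellar
92	L_cerebellum_IX	left	Subcortical/Cerebellar	cerebellar
93	L_cerebellum_X	left	Subcortical/Cerebellar	cerebellar
94	R_cerebellum_I_IV	right	Subcortical/Cerebellar	cerebellar
95	R_cerebellum_V	right	Subcortical/Cerebellar	cerebellar
96	R_cerebellum_VI	right	Subcortical/Cerebellar	cerebellar
97	R_cerebellum_crusI	right	Subcortical/Cerebellar	cerebellar
98	R_cerebellum_crusII	right	Subcortical/Cerebellar	cerebellar
99	R_cerebellum_VIIb	right	Subcortical/Cerebellar	cerebellar
100	R_cerebellum_VIIIa	right	Subcortical/Cerebellar	cerebellar
101	R_cerebellum_VIIIb	right	Subcortical/Cerebellar	cerebellar
102	R_cerebellum_IX	right	Subcortical/Cerebellar	cerebellar
103	R_cerebellum_X	right	Subcortical/Cerebellar	cerebellar
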