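patient_id	family_id	variant_ids	enrollment_status	platelet_count	thrombocytopenia	macrothrombocytes	dohle_bodies	dohle_method	hearing_impairment	nephropathy	liver_enzyme_elevation	family_history_myh9rd	phenotype_specific	contribution_printed
1	F01	V01	unclassified_platelet_disorder		1	1	reported	immunofluorescence				0	1	Full
2	F02	V02	known_MYH9RD_unconfirmed		1	1	reported	MGG				0	1	Full
3	F03	V03	unclassified_platelet_disorder		1	1	reported	MGG				0	1	Full
4	F04	V13	known_MYH9RD_unconfirmed		1	1	unknown					1	1	Full
5	F05	V14	known_MYH9RD_unconfirmed		1	1	unknown					0	1	Full
6	F06	V15	suspected_MYH9RD		1	1	unknown					0	0	Full
7	F07	V16	unclassified_platelet_disorder		1	1	unknown					0	1	Full
8	F08	V16	suspected_MYH9RD		1	1	unknown		1	1		0	1	Full
9	F09	V16	unclassified_platelet_disorder		1	1	unknown					0	1	Full
10	F10	V16	known_MYH9RD_unconfirmed		1	1	unknown					0	1	Full
11	F11	V17	suspected_MYH9RD		1	1	unknown					0	1	Full
12	F12	V18	known_MYH9RD_unconfirmed		1	1	unknown		1			0	1	Full
13	F13	V18	suspected_MYH9RD		1	1	unknown					0	1	Full
14	F14	V19	unclassified_platelet_disorder		1	1	unknown					1	1	Full
15	F14	V19	unclassified_platelet_disorder		1	1	unknown					1	1	Full
16	F14	V19	unclassified_platelet_disorder		1	1	unknown					1	1	Full
17	F14	V19	unclassified_platelet_disorder	187	0	1	unknown			1		1	1	Full
18	F15	V20	suspected_MYH9RD		1	1	unknown					0	1	Full
19	F16	V20	unclassified_platelet_disorder		1	1	unknown					0	1	Full
20	F17	V04	unclassified_platelet_disorder	88	1	1	reported	immunofluorescence				0	1	Full
21	F18	V06	known_MYH9RD_unconfirmed	70	1	1	reported	MGG				1	1	Full
22	F19	V21	known_MYH9RD_unconfirmed		1	1	unknown					1	1	Full
23	F20	V21	suspected_MYH9RD		1	1	unknown					1	1	Full
24	F19	V21	known_MYH9RD_unconfirmed		1	1	unknown					1	1	Full
25	F21	V21	suspected_MYH9RD		1	1	unknown					0	1	Full
26	F22	V21	unclassified_platelet_disorder		1	1	unknown					0	1	Full
27	F23	V21	unclassified_platelet_disorder		1	1	unknown					0	1	Full
28	F24	V07	unclassified_platelet_disorder		1	1	reported	immunofluorescence				0	0	Full
29	F25	V08	unclassified_platelet_disorder		1	1	reported	immunofluorescence				0	0	Full
30	F26	V22	unclassified_platelet_disorder		1	1	unknown					0	1	Full
31	F27	V22	suspected_MYH9RD		1	1	unknown					0	1	Full
32	F28	V22	suspected_MYH9RD		1	1	unknown					0	1	Full
33	F29	V22	suspected_MYH9RD		1	1	unknown					0	1	Full
34	F30	V23	known_MYH9RD_unconfirmed		1	1	unknown					1	1	Full
35	F30	V23	known_MYH9RD_unconfirmed		1	1	unknown					1	1	Full
36	F31	V23	suspected_MYH9RD		1	1	unknown					0	1	Full
37	F32	V09	unclassified_platelet_disorder		1	1	unknown					0	0	Full
38	F33	V24	known_MYH9RD_unconfirmed		1	1	unknown					1	1	Full
39	F34	V05;V10	unclassified_platelet_disorder		1	1	unknown					1	0	Full
40	F35	V11	unclassified_platelet_disorder	220	0	1	reported	immunofluorescence				0	0	Uncertain
41	F36	V25	known_MYH9RD_unconfirmed		1	1	unknown					0	1	Full
42	F37	V25	known_MYH9RD_unconfirmed		1	1	unknown					0	1	Full
43	F38	V25	known_MYH9RD_unconfirmed		1	1	unknown					1	1	Full
44	F38	V25	known_MYH9RD_unconfirmed		1	1	unknown					1	1	Full
45	F39	V26	unclassified_platelet_disorder		1	1	unknown					0	1	Full
46	F40	V27	known_MYH9RD_unconfirmed		1	1	unknown					0	1	Full
47	F41	V27	known_MYH9RD_unconfirmed		1	1	unknown					1	1	Full
48	F42	V27	known_MYH9RD_unconfirmed		1	1	unknown					0	1	Full
49	F43	V28	known_MYH9RD_unconfirmed		1	1	unknown					0	1	Full
50	F44	V12	known_MYH9RD_unconfirmed	16	1	1	reported	MGG				0	1	Full
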