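drb1	dqa1	dqb1	breed	frequency	count
10301	00101	00802	NF	0.28	37
00101	00101	00201	AH1	0.15	12
00101	00101	00201	CB1	0.24	24
00101	00101	00201	CB2	0.22	51
00101	00101	00201	ISD	0.08	2
00101	00101	00201	KL	0.30	83
00101	00101	00201	NF	0.02	3
00101	00101	00201	RRB	0.35	36
00101	00101	03601	ECS	0.12	2
00101	00101	03601	RRB	0.02	2
00101	00101	03603	ISD	0.12	3
00103	00101	00201	ECS	0.06	1
00201	00901	00101	RRB	0.25	26
00201	00901	00101	SA	0.17	28
00601	005011	00701	AH2	0.17	2
00601	005011	00701	CB1	0.25	24
00601	005011	00701	CB2	0.01	2
00601	005011	00701	GR	1.00	26
00601	005011	00701	KL	0.08	22
00601	005011	00701	LW	0.18	6
00601	005011	00701	RRB	0.05	5
00601	005011	02001	ECS	0.12	2
00601	005011	02001	SA	0.33	55
00901	00101	008011	AH1	0.32	25
00901	00101	008011	AH2	0.42	5
00901	00101	008011	CB1	0.03	3
00901	00101	008011	KKH	0.47	35
00901	00101	008011	KL	0.02	6
010011	00201	01501	ECS	0.06	1
01101	00201	01303	SBT	0.04	1
01102	00201	01303	SBT	0.08	2
01201	00401	013017	AH2	0.33	4
01201	00401	013017	NF	0.51	67
01201	00401	013017	RRB	0.19	20
01201	00401	013017	SA	0.01	2
01201	00401	01303	SBT	0.42	11
01301	00101	00201	CB1	0.19	19
01301	00101	00201	CB2	0.04	9
01301	00101	00201	ECS	0.25	4
01301	00101	00201	ISD	0.46	12
01301	00601	02002	CB1	0.07	7
01501	00901	00101	ECS	0.19	3
01501	00601	02301	AH1	0.24	19
01501	00601	02301	CB2	0.31	72
01501	00601	02301	ECS	0.19	3
01501	00601	02301	ISD	0.23	6
01501	00601	02301	KL	0.03	8
01501	00601	02301	SBT	0.04	1
01501	00601	05701	KL	0.03	8
01501	00601	00301	LW	0.12	4
01501	00601	02201	KKH	0.30	22
01501	00601	02002	RRB	0.07	7
01501	00401	013017	KKH	0.03	2
01501	012011	03501	SA	0.01	2
01501	00601	01101	CB1	0.18	18
01501	00601	01101	KL	0.09	25
01502	00601	02301	KL	0.22	61
01502	00601	02301	NF	0.03	4
01503	00601	00301	AH2	0.08	1
01503	00601	02304	SA	0.07	12
01801	00101	00802	CB1	0.03	3
01801	00101	00802	LW	0.24	8
01801	00101	00802	NF	0.14	18
01801	00101	00802	SA	0.07	12
02001	00401	01303	AH1	0.27	21
02001	00401	01303	CB2	0.09	21
02001	00401	01303	ISD	0.04	1
02001	00401	01303	SA	0.01	2
02001	00401	01303	SBT	0.42	11
02301	00301	00501	KL	0.23	63
02301	00301	00501	LW	0.18	6
03001	00601	00301	CB2	0.03	7
04001	01001	01901	SA	0.17	28
07001	01801	05001	SA	0.06	10
07401	005011	00701	KKH	0.16	12
07401	005011	00701	NF	0.02	3
07401	00101	00201	SA	0.01	2
07601	00601	02301	CB2	0.25	58
07801	00401	01303	SA	0.08	13
08001	00402	01303	CB2	0.01	2
09401	00101	008011	LW	0.18	6
09501	00301	05401	RRB	0.05	5
09501	00101	008011	RRB	0.02	2
09501	00901	00101	CB2	0.02	5
09701	00601	02002	KKH	0.04	3
09801	00402	02301	AH1	0.01	1
NA	NA	NA	CB2	0.02	5
NA	NA	NA	ISD	0.08	2
NA	NA	NA	LW	0.12	4
NA	NA	NA	RRB	0.01	1
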