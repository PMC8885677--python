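rank	sequence	length	seed	score	log_score	step_probs
1	ESS	3	E	0.71967	-0.328963	0.978109;0.735776
2	ESSE	4	E	0.61563	-0.485108	0.978109;0.735776;0.855435
3	ESSES	5	E	0.602858	-0.506073	0.978109;0.735776;0.855435;0.979253
4	SES	3	S	0.584974	-0.536188	0.588502;0.994006
5	DES	3	D	0.401255	-0.913159	0.409611;0.979599
6	IES	3	I	0.364071	-1.01041	0.371264;0.980625
7	LES	3	L	0.354811	-1.03617	0.364501;0.973414
8	DESS	4	D	0.312777	-1.16226	0.409611;0.979599;0.779498
9	LESS	4	L	0.285679	-1.25288	0.364501;0.973414;0.80516
10	IESS	4	I	0.282362	-1.26457	0.371264;0.980625;0.775568
11	DESSE	5	D	0.267561	-1.31841	0.409611;0.979599;0.779498;0.855435
12	DESSES	6	D	0.26201	-1.33937	0.409611;0.979599;0.779498;0.855435;0.979253
13	PES	3	P	0.259057	-1.35071	0.264337;0.980027
14	GES	3	G	0.247129	-1.39785	0.254064;0.972703
15	LESSE	5	L	0.24438	-1.40903	0.364501;0.973414;0.80516;0.855435
16	IESSE	5	I	0.241542	-1.42071	0.371264;0.980625;0.775568;0.855435
17	ESSESS	6	E	0.239386	-1.42968	0.978109;0.735776;0.855435;0.979253;0.397085
18	LESSES	6	L	0.23931	-1.43	0.364501;0.973414;0.80516;0.855435;0.979253
19	IESSES	6	I	0.236531	-1.44168	0.371264;0.980625;0.775568;0.855435;0.979253
20	SESS	4	S	0.232284	-1.45979	0.588502;0.994006;0.397085
21	QES	3	Q	0.222544	-1.50263	0.230028;0.967464
22	AES	3	A	0.216324	-1.53098	0.222636;0.971651
23	ESSESSE	7	E	0.204779	-1.58582	0.978109;0.735776;0.855435;0.979253;0.397085;0.855435
24	ESSESSES	8	E	0.20053	-1.60679	0.978109;0.735776;0.855435;0.979253;0.397085;0.855435;0.979253
25	SESSE	5	S	0.198704	-1.61594	0.588502;0.994006;0.397085;0.855435
26	GESS	4	G	0.194677	-1.63642	0.254064;0.972703;0.787754
27	SESSES	6	S	0.194582	-1.6369	0.588502;0.994006;0.397085;0.855435;0.979253
28	QESS	4	Q	0.192814	-1.64603	0.230028;0.967464;0.86641
29	PESS	4	P	0.189153	-1.6652	0.264337;0.980027;0.730158
30	AESS	4	A	0.17614	-1.73648	0.222636;0.971651;0.814238
31	GESSE	5	G	0.166533	-1.79256	0.254064;0.972703;0.787754;0.855435
32	QESSE	5	Q	0.16494	-1.80217	0.230028;0.967464;0.86641;0.855435
33	GESSES	6	G	0.163078	-1.81353	0.254064;0.972703;0.787754;0.855435;0.979253
34	PESSE	5	P	0.161808	-1.82134	0.264337;0.980027;0.730158;0.855435
35	QESSES	6	Q	0.161518	-1.82314	0.230028;0.967464;0.86641;0.855435;0.979253
36	PESSES	6	P	0.158451	-1.84231	0.264337;0.980027;0.730158;0.855435;0.979253
37	AESSE	5	A	0.150676	-1.89262	0.222636;0.971651;0.814238;0.855435
38	AESSES	6	A	0.14755	-1.91359	0.222636;0.971651;0.814238;0.855435;0.979253
39	ESSESE	6	E	0.144658	-1.93338	0.978109;0.735776;0.855435;0.979253;0.239954
40	SESE	4	S	0.140367	-1.9635	0.588502;0.994006;0.239954
41	ESSESES	7	E	0.130544	-2.03605	0.978109;0.735776;0.855435;0.979253;0.239954;0.902428
42	SESES	5	S	0.126671	-2.06616	0.588502;0.994006;0.239954;0.902428
43	MES	3	M	0.123194	-2.094	0.127698;0.964729
44	SSS	3	S	0.109976	-2.20749	0.210265;0.523035
45	DESSESS	7	D	0.10404	-2.26298	0.409611;0.979599;0.779498;0.855435;0.979253;0.397085
46	LESSESS	7	L	0.0950264	-2.3536	0.364501;0.973414;0.80516;0.855435;0.979253;0.397085
47	ESE	3	E	0.0947005	-2.35704	0.978109;0.0968199
48	IESSESS	7	I	0.0939228	-2.36528	0.371264;0.980625;0.775568;0.855435;0.979253;0.397085
49	MESS	4	M	0.0923193	-2.3825	0.127698;0.964729;0.749384
50	DESSESSE	8	D	0.0889995	-2.41913	0.409611;0.979599;0.779498;0.855435;0.979253;0.397085;0.855435
51	DESSESSES	9	D	0.087153	-2.44009	0.409611;0.979599;0.779498;0.855435;0.979253;0.397085;0.855435;0.979253
52	ESES	4	E	0.0854603	-2.4597	0.978109;0.0968199;0.902428
53	LESSESSE	8	L	0.0812889	-2.50975	0.364501;0.973414;0.80516;0.855435;0.979253;0.397085;0.855435
54	SSE	3	S	0.0810674	-2.51247	0.210265;0.385549
55	IESSESSE	8	I	0.0803448	-2.52143	0.371264;0.980625;0.775568;0.855435;0.979253;0.397085;0.855435
56	ESSESSESS	9	E	0.0796276	-2.53039	0.978109;0.735776;0.855435;0.979253;0.397085;0.855435;0.979253;0.397085
57	LESSESSES	9	L	0.0796024	-2.53071	0.364501;0.973414;0.80516;0.855435;0.979253;0.397085;0.855435;0.979253
58	SSES	4	S	0.0793855	-2.53344	0.210265;0.385549;0.979253
59	MESSE	5	M	0.0789731	-2.53865	0.127698;0.964729;0.749384;0.855435
60	IESSESSES	9	I	0.0786779	-2.54239	0.371264;0.980625;0.775568;0.855435;0.979253;0.397085;0.855435;0.979253
61	MESSES	6	M	0.0773347	-2.55961	0.127698;0.964729;0.749384;0.855435;0.979253
62	SESSESS	7	S	0.0772654	-2.56051	0.588502;0.994006;0.397085;0.855435;0.979253;0.397085
63	SSSE	4	S	0.0731817	-2.61481	0.210265;0.523035;0.665434
64	SSSES	5	S	0.0716634	-2.63578	0.210265;0.523035;0.665434;0.979253
65	ESSESSESSE	10	E	0.0681162	-2.68654	0.978109;0.735776;0.855435;0.979253;0.397085;0.855435;0.979253;0.397085;0.855435
66	SESSESSE	8	S	0.0660955	-2.71665	0.588502;0.994006;0.397085;0.855435;0.979253;0.397085;0.855435
67	GESSESS	7	G	0.0647558	-2.73713	0.254064;0.972703;0.787754;0.855435;0.979253;0.397085
68	SESSESSES	9	S	0.0647242	-2.73762	0.588502;0.994006;0.397085;0.855435;0.979253;0.397085;0.855435;0.979253
69	QESSESS	7	Q	0.0641363	-2.74674	0.230028;0.967464;0.86641;0.855435;0.979253;0.397085
70	PESSESS	7	P	0.0629185	-2.76591	0.264337;0.980027;0.730158;0.855435;0.979253;0.397085
71	DESSESE	7	D	0.0628703	-2.76668	0.409611;0.979599;0.779498;0.855435;0.979253;0.239954
72	AESSESS	7	A	0.0585898	-2.83719	0.222636;0.971651;0.814238;0.855435;0.979253;0.397085
73	LESSESE	7	L	0.0574234	-2.8573	0.364501;0.973414;0.80516;0.855435;0.979253;0.239954
74	IESSESE	7	I	0.0567565	-2.86898	0.371264;0.980625;0.775568;0.855435;0.979253;0.239954
75	DESSESES	8	D	0.0567359	-2.86935	0.409611;0.979599;0.779498;0.855435;0.979253;0.239954;0.902428
76	GESSESSE	8	G	0.0553944	-2.89328	0.254064;0.972703;0.787754;0.855435;0.979253;0.397085;0.855435
77	QESSESSE	8	Q	0.0548644	-2.90289	0.230028;0.967464;0.86641;0.855435;0.979253;0.397085;0.855435
78	GESSESSES	9	G	0.0542451	-2.91424	0.254064;0.972703;0.787754;0.855435;0.979253;0.397085;0.855435;0.979253
79	PESSESSE	8	P	0.0538227	-2.92206	0.264337;0.980027;0.730158;0.855435;0.979253;0.397085;0.855435
80	QESSESSES	9	Q	0.0537262	-2.92386	0.230028;0.967464;0.86641;0.855435;0.979253;0.397085;0.855435;0.979253
81	PESSESSES	9	P	0.052706	-2.94303	0.264337;0.980027;0.730158;0.855435;0.979253;0.397085;0.855435;0.979253
82	ESSESESS	8	E	0.0518369	-2.95965	0.978109;0.735776;0.855435;0.979253;0.239954;0.902428;0.397085
83	LESSESES	8	L	0.0518205	-2.95997	0.364501;0.973414;0.80516;0.855435;0.979253;0.239954;0.902428
84	IESSESES	8	I	0.0512187	-2.97165	0.371264;0.980625;0.775568;0.855435;0.979253;0.239954;0.902428
85	SESESS	6	S	0.0502991	-2.98977	0.588502;0.994006;0.239954;0.902428;0.397085
86	AESSESSE	8	A	0.0501197	-2.99334	0.222636;0.971651;0.814238;0.855435;0.979253;0.397085;0.855435
87	AESSESSES	9	A	0.0490799	-3.01431	0.222636;0.971651;0.814238;0.855435;0.979253;0.397085;0.855435;0.979253
88	ESSESSESE	9	E	0.0481181	-3.0341	0.978109;0.735776;0.855435;0.979253;0.397085;0.855435;0.979253;0.239954
89	SESSESE	7	S	0.0466906	-3.06421	0.588502;0.994006;0.397085;0.855435;0.979253;0.239954
90	ESSESESSE	9	E	0.0443431	-3.1158	0.978109;0.735776;0.855435;0.979253;0.239954;0.902428;0.397085;0.855435
91	ESSESESSES	10	E	0.0434231	-3.13676	0.978109;0.735776;0.855435;0.979253;0.239954;0.902428;0.397085;0.855435;0.979253
92	ESSESSESES	10	E	0.0434231	-3.13676	0.978109;0.735776;0.855435;0.979253;0.397085;0.855435;0.979253;0.239954;0.902428
93	SESESSE	7	S	0.0430276	-3.14591	0.588502;0.994006;0.239954;0.902428;0.397085;0.855435
94	SESESSES	8	S	0.0421349	-3.16688	0.588502;0.994006;0.239954;0.902428;0.397085;0.855435;0.979253
95	SESSESES	8	S	0.0421349	-3.16688	0.588502;0.994006;0.397085;0.855435;0.979253;0.239954;0.902428
96	GESSESE	7	G	0.0391312	-3.24083	0.254064;0.972703;0.787754;0.855435;0.979253;0.239954
97	QESSESE	7	Q	0.0387569	-3.25045	0.230028;0.967464;0.86641;0.855435;0.979253;0.239954
98	PESSESE	7	P	0.038021	-3.26962	0.264337;0.980027;0.730158;0.855435;0.979253;0.239954
99	AESSESE	7	A	0.0354052	-3.3409	0.222636;0.971651;0.814238;0.855435;0.979253;0.239954
100	GESSESES	8	G	0.0353131	-3.3435	0.254064;0.972703;0.787754;0.855435;0.979253;0.239954;0.902428
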