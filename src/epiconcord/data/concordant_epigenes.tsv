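gene_id	gene_symbol	delta_5mc_pct	diff_score	signed_fc	table
58475	MS4A7	6	-19.0	4.6	hypo_up
1439	CSF2RB	6.6	-35.4	3.8	hypo_up
9056	SLC7A7	6.6	-18.6	3.5	hypo_up
822	CAPG	5.8	-13.9	3.4	hypo_up
6556	SLC11A1	8.6	-34.4	3.1	hypo_up
54209	TREM2	7.1	-26.0	2.9	hypo_up
912	CD1D	5.6	-19.7	2.8	hypo_up
10457	GPNMB	10.1	-43.1	2.8	hypo_up
2203	FBP1	7.7	-96.5	2.7	hypo_up
11006	LILRB4	4.6	-14.0	2.7	hypo_up
27036	SIGLEC7	5.3	-15.9	2.7	hypo_up
4046	LSP1	6.4	-20.1	2.7	hypo_up
864	RUNX3	7.5	-32.8	2.6	hypo_up
11025	LILRB3	5.9	-14.0	2.5	hypo_up
2207	FCER1G	5.5	-20.2	2.4	hypo_up
10261	IGSF6	10.2	-50.2	2.3	hypo_up
286256	LCN12	5.2	-18.4	2.3	hypo_up
1230	CCR1	7.3	-25.2	2.3	hypo_up
51225	ABI3	6.3	-19.2	2.3	hypo_up
1522	CTSZ	5.8	-39.3	2.2	hypo_up
26157	GIMAP2	7.2	-35.0	2.2	hypo_up
10023	FRAT1	5.2	-46.0	2.2	hypo_up
1117	CHI3L2	7.1	-22.6	2.1	hypo_up
64344	HIF3A	5.8	-48.9	2.1	hypo_up
10320	IKZF1	6.8	-22.2	2.1	hypo_up
1051	C/EBPB	4.9	-54.7	2.1	hypo_up
1601	DAB2	3.9	-13.7	2.0	hypo_up
84898	PLXDC2	3	-23.7	2.0	hypo_up
10990	LILRB5	7.5	-36.6	2.0	hypo_up
254295	PHYHD1	3.1	-13.6	1.9	hypo_up
4488	MSX2	5.4	-51.9	1.9	hypo_up
558	AXL	3.3	-14.5	1.8	hypo_up
5359	PLSCR1	7.3	-82.6	1.8	hypo_up
23526	HMHA1	0	-33.5	1.8	hypo_up
50856	CLEC4A	9.5	-45.3	1.7	hypo_up
116843	C6orf192	3.4	-16.5	1.7	hypo_up
55544	RBM38	4.9	-20.8	1.7	hypo_up
23209	MLC1	7.4	-29.0	1.7	hypo_up
23418	CRB1	6.2	-15.2	1.7	hypo_up
1501	CTNND2	2.9	-18.0	1.6	hypo_up
5045	FURIN	5.9	-19.7	1.6	hypo_up
1317	SLC31A1	5.3	-19.4	1.6	hypo_up
123920	CMTM3	3.9	-16.6	1.6	hypo_up
6776	STAT5A	4.2	-16.6	1.6	hypo_up
57522	SRGAP1	0.3	-43.9	1.5	hypo_up
9404	LPXN	4	-13.9	1.5	hypo_up
122618	PLD4	5.5	-18.0	1.5	hypo_up
64859	OBFC2A	7.2	-99.8	1.5	hypo_up
10628	TXNIP	4.3	-26.1	1.4	hypo_up
79939	SLC35E1	0	-46.6	1.3	hypo_up
5660	PSAP	0	-33.5	1.3	hypo_up
7306	TYRP1	9	50	-7.2	hyper_down
2706	GJB2	16.3	18.4	-4.7	hyper_down
26266	SLC13A4	4.6	26.2	-4.2	hyper_down
4060	LUM	8.6	37	-4.1	hyper_down
90523	C6orf142	6.7	343.9	-4.1	hyper_down
149461	CLDN19	5.6	31.6	-4.1	hyper_down
112464	PRKCDBP	6.3	28.6	-3.8	hyper_down
195814	SDR16C5	8.1	16.7	-3.5	hyper_down
64073	C19orf33	5.3	29.2	-3.4	hyper_down
158038	LINGO2	2.4	42.7	-3.3	hyper_down
51299	NRN1	3.9	18.1	-2.5	hyper_down
8727	CTNNAL1	6.4	17.1	-2.5	hyper_down
51200	CPA4	7.3	47.3	-2.4	hyper_down
163782	KANK4	15.1	100.3	-2.4	hyper_down
57664	PLEKHA4	11.9	26.4	-2.4	hyper_down
283120	H19	5.6	48.2	-2.3	hyper_down
1755	DMBT1	9.6	36.3	-2.3	hyper_down
3045	HBD	7.8	77.9	-2.3	hyper_down
8743	TNFSF10	7.2	33	-2.2	hyper_down
4826	NNAT	5.8	21.1	-2.2	hyper_down
2676	GFRA3	4.9	19.3	-2	hyper_down
5121	PCP4	1.3	15.9	-2	hyper_down
90139	TSPAN18	5.2	24.8	-2	hyper_down
5858	PZP	9.5	48.7	-2	hyper_down
10586	MAB21L2	3.9	19.4	-1.9	hyper_down
64288	ZNF323	8.6	32.6	-1.9	hyper_down
84708	LNX1	9.4	30.5	-1.9	hyper_down
144347	FAM101A	6.9	33.9	-1.8	hyper_down
25960	GPR124	6.6	18.2	-1.8	hyper_down
6335	SCN9A	6.5	47.3	-1.8	hyper_down
23089	PEG10	10.1	21.2	-1.8	hyper_down
254228	FAM26E	5.8	97	-1.8	hyper_down
5332	PLCB4	6.7	49.5	-1.8	hyper_down
168537	GIMAP7	7.8	31.1	-1.7	hyper_down
4199	ME1	7.4	16.9	-1.7	hyper_down
135932	TMEM139	8.6	26.9	-1.7	hyper_down
6932	TCF7	5.3	87.4	-1.7	hyper_down
79827	ASAM	9.7	87.6	-1.6	hyper_down
152330	CNTN4	0.6	48.8	-1.6	hyper_down
55228	PNMAL1	8.8	30.6	-1.6	hyper_down
150350	ENTHD1	4.8	81.9	-1.5	hyper_down
27237	ARHGEF16	7.5	101.6	-1.5	hyper_down
57415	C3orf14	7.9	78.2	-1.5	hyper_down
84909	C9orf3	0.1	40.4	-1.5	hyper_down
2326	FMO1	9.4	61.1	-1.5	hyper_down
5172	SLC26A4	9.4	23.5	-1.5	hyper_down
9467	SH3BP5	7	50.6	-1.5	hyper_down
166	AES	5.8	42.7	-1.4	hyper_down
3768	KCNJ12	14.5	343.9	-1.4	hyper_down
22927	HABP4	12.2	45.1	-1.4	hyper_down
8537	BCAS1	8.7	59.2	-1.4	hyper_down
8817	FGF18	7.8	15.8	-1.4	hyper_down
5213	PFKM	5.9	29.3	-1.4	hyper_down
85453	TSPYL5	11.7	32	-1.4	hyper_down
4233	MET	6	22.9	-1.4	hyper_down
135250	RAET1E	9.6	89.7	-1.3	hyper_down
2260	FGFR1	5.1	18.7	-1.3	hyper_down
90135	BTBD6	9.3	23.5	-1.3	hyper_down
744	MPPED2	7.3	41.8	-1.3	hyper_down
3749	KCNC4	3.2	28.2	-1.3	hyper_down
91977	MYOZ3	5	15.3	-1.3	hyper_down
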