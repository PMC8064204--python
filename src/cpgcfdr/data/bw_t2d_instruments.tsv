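SNP	ea_E	oa_E	ea_O	oa_O	beta.E	beta.O	eaf.E	eaf.O	se.O	pval.O	outcome	se.E	pval.E	exposure
rs10818797	C	T	C	T	0.0345	0.0953102	0.14	0.141	0.076	0.3	T2D	0.0054	1.20E-10	BW
rs10830963	G	C	G	C	0.0232	0	0.28	0.276	0.039	0.27	T2D	0.0042	2.90E-08	BW
rs10872678	C	T	C	T	-0.0375	-0.040822	0.28	0.277	0.04	0.31	T2D	0.0041	6.90E-20	BW
rs10935733	C	T	C	T	-0.0221	-0.0953102	0.59	0.606	0.034	0.092001	T2D	0.0039	9.20E-09	BW
rs111778406	G	A	G	A	0.0492	-0.0202027	0.068	0.072	0.13	0.89	T2D	0.0075	5.80E-11	BW
rs113086489	T	C	T	C	0.0307	0	0.56	0.545	0.034	0.94	T2D	0.0038	9.10E-16	BW
rs11720108	T	C	T	C	0.046	0	0.23	0.249	0.045	0.61	T2D	0.0043	3.40E-26	BW
rs11765649	C	T	C	T	-0.0267	0	0.25	0.263	0.042	0.37	T2D	0.0043	5.80E-10	BW
rs1187118	T	A	T	A	-0.0299	0	0.83	0.833	0.058	0.73	T2D	0.0051	3.60E-09	BW
rs12543725	A	G	A	G	-0.0231	0	0.41	0.412	0.033	0.41	T2D	0.0038	1.20E-09	BW
rs12906125	A	G	A	G	-0.0228	-0.0100503	0.32	0.326	0.037	0.88	T2D	0.004	1.70E-08	BW
rs13266210	G	A	G	A	-0.0308	-0.0512933	0.21	0.212	0.051	0.36	T2D	0.0045	1.30E-11	BW
rs134594	T	C	T	C	-0.0227	0.0100503	0.65	0.65	0.036	0.77	T2D	0.004	1.00E-08	BW
rs1351394	C	T	C	T	-0.0436	0	0.51	0.511	0.032	0.760001	T2D	0.0037	1.90E-32	BW
rs1411424	A	G	A	G	0.0212	0.0202027	0.52	0.524	0.033	0.62	T2D	0.0038	2.20E-08	BW
rs1415701	A	G	A	G	-0.0253	0	0.26	0.269	0.041	0.9	T2D	0.0043	2.60E-09	BW
rs144843919	A	G	A	G	-0.066	-0.0100503	0.035	0.035	0.27	0.98	T2D	0.0116	1.40E-08	BW
rs17034876	T	C	T	C	0.0471	0.0304592	0.7	0.699	0.039	0.42	T2D	0.0042	2.60E-29	BW
rs1819436	C	T	C	T	0.0329	0.0100503	0.87	0.877	0.076	0.93	T2D	0.0057	6.30E-09	BW
rs2131354	A	G	A	G	0.0259	0	0.53	0.526	0.033	0.52	T2D	0.0037	4.10E-12	BW
rs2168443	A	T	A	T	-0.0228	0.0725707	0.62	0.621	0.035	0.053001	T2D	0.0039	3.50E-09	BW
rs2229742	C	G	C	G	-0.036	-0.040822	0.13	0.104	0.084	0.62	T2D	0.006	2.20E-09	BW
rs2306547	T	C	T	C	-0.0211	0	0.46	0.467	0.033	0.92	T2D	0.0037	1.80E-08	BW
rs2473248	C	T	C	T	0.0325	0	0.87	0.881	0.079	0.94	T2D	0.0057	1.00E-08	BW
rs2497304	T	C	T	C	-0.0282	0	0.48	0.478	0.033	0.97	T2D	0.0037	2.60E-14	BW
rs28530618	G	A	G	A	-0.0261	-0.0953102	0.51	0.529	0.033	0.041	T2D	0.0038	7.70E-12	BW
rs2946179	C	T	C	T	0.024	0	0.73	0.74	0.042	0.27	T2D	0.0042	1.30E-08	BW
rs35261542	A	C	A	C	-0.0444	-0.127833	0.27	0.263	0.039	0.00063	T2D	0.0041	4.40E-27	BW
rs3753639	C	T	C	T	0.0306	0.0953102	0.24	0.245	0.046	0.25	T2D	0.0045	7.30E-12	BW
rs3780573	A	G	A	G	0.0555	0.0953102	0.096	0.096	0.099	0.22	T2D	0.0064	7.00E-18	BW
rs4144829	T	C	T	C	-0.0341	0	0.73	0.739	0.043	0.56	T2D	0.0042	5.30E-16	BW
rs6016377	T	C	T	C	0.0239	0	0.43	0.446	0.035	0.53	T2D	0.0039	9.50E-10	BW
rs6040076	C	G	C	G	0.0231	-0.0512933	0.49	0.494	0.033	0.1	T2D	0.0039	2.00E-09	BW
rs72480273	C	A	C	A	0.0313	-0.0512933	0.17	0.189	0.056	0.38	T2D	0.0051	8.00E-10	BW
rs72833480	A	G	A	G	0.0226	-0.0304592	0.29	0.295	0.039	0.49	T2D	0.0041	4.60E-08	BW
rs72851023	T	C	T	C	0.0476	0	0.073	0.077	0.13	0.74	T2D	0.0075	2.90E-10	BW
rs7402982	G	A	G	A	-0.0232	0.0100503	0.57	0.586	0.034	0.67	T2D	0.0039	2.30E-09	BW
rs740746	A	G	A	G	0.0364	0	0.73	0.734	0.041	0.62	T2D	0.0042	3.80E-18	BW
rs753381	C	T	C	T	-0.0205	0	0.55	0.55	0.033	0.52	T2D	0.0037	2.80E-08	BW
rs7575873	G	A	G	A	-0.0384	-0.0618754	0.12	0.13	0.071	0.42	T2D	0.0057	1.20E-11	BW
rs7854962	G	C	G	C	-0.0279	-0.040822	0.22	0.216	0.047	0.36	T2D	0.0046	1.90E-09	BW
rs79237883	C	T	C	T	0.0371	-0.0833816	0.08	0.076	0.1	0.39	T2D	0.0067	3.50E-08	BW
rs7964361	A	G	A	G	0.0391	-0.105361	0.085	0.088	0.096	0.25	T2D	0.0067	4.70E-09	BW
rs798498	G	T	G	T	-0.0229	0	0.31	0.307	0.038	0.709999	T2D	0.004	1.30E-08	BW
rs7998537	A	G	A	G	-0.0222	0	0.32	0.321	0.037	0.35	T2D	0.004	3.90E-08	BW
rs854037	G	A	G	A	-0.0268	0.0953102	0.19	0.186	0.055	0.37	T2D	0.0048	2.20E-08	BW
rs900399	G	A	G	A	-0.0523	0	0.39	0.393	0.038	0.47	T2D	0.0039	2.20E-41	BW
rs9368777	C	G	C	G	0.0215	0.0304592	0.58	0.575	0.033	0.31	T2D	0.0038	2.20E-08	BW
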