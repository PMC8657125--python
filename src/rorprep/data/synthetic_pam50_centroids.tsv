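gene	Basal	Her2	LumA	LumB	Normal
ACTR3B	1.7115	0.0412	-0.7271	-0.7613	0.5788
ANLN	1.4490	0.8124	-0.7067	0.7791	-1.5202
BAG1	-1.5981	-0.9814	1.1230	0.7854	0.2716
BCL2	-1.5532	-0.8966	1.0855	0.5975	0.3628
BIRC5	1.5056	1.0957	-1.0461	0.8631	-1.6391
BLVRA	0.4323	-0.1676	0.0546	-0.0888	0.4823
CCNB1	1.5180	0.9391	-0.9351	1.0969	-1.4991
CCNE1	1.0965	0.9881	-0.8834	1.0542	-1.6311
CDC20	1.3817	0.7613	-1.0071	0.8926	-1.7244
CDC6	1.2849	0.9708	-0.7829	0.8862	-1.8726
CDH3	1.3281	0.1441	-0.8301	-1.0831	0.4549
CENPF	1.6360	1.0685	-1.2132	1.1955	-1.5129
CEP55	1.3725	0.8650	-1.0831	1.0411	-1.2210
CXXC5	-1.6730	-0.8133	0.8074	0.9628	0.1264
EGFR	1.5441	0.4439	-1.2116	-0.6594	0.4279
ERBB2	-0.4380	1.6597	-0.2749	0.0786	-0.1959
ESR1	-1.5039	-0.6660	1.3238	0.8695	0.4720
EXO1	1.3822	0.9322	-0.7844	0.9190	-1.7646
FGFR4	-0.5101	1.1668	0.1108	0.0556	-0.4348
FOXA1	-1.5244	-0.7619	1.0762	0.8935	0.2081
FOXC1	1.5977	0.1021	-0.7190	-0.6586	0.4602
GPR160	-1.5300	-0.9677	1.1522	1.0087	0.3692
GRB7	-0.7463	2.0890	-0.6423	-0.0124	-0.1226
KIF2C	1.5398	0.8279	-0.8742	0.6662	-1.4284
KRT14	1.4430	0.1765	-0.7005	-0.6114	1.1531
KRT17	1.4988	0.2464	-0.7572	-0.9233	1.1506
KRT5	1.5840	0.0866	-0.8267	-0.9578	0.9447
MAPT	-1.5347	-0.6045	1.2353	1.0454	0.2631
MDM2	-1.3712	-0.6937	0.8904	0.5635	0.3372
MELK	1.3737	1.0767	-0.9935	0.8736	-1.6083
MIA	1.2073	0.5252	-0.8657	-0.7458	0.8367
MKI67	1.2583	0.9568	-0.9346	0.8723	-1.5870
MLPH	-1.3454	-0.6988	0.9987	0.9869	0.2715
MMP11	-0.5680	0.2519	0.5528	0.6812	-0.7688
MYBL2	1.3573	0.8215	-1.1733	0.9666	-1.6824
MYC	1.2306	0.2006	-0.7671	-0.9017	0.9393
NAT1	-1.6178	-0.7016	1.0084	0.6111	0.3650
NDC80	1.1969	0.6964	-1.0849	1.1123	-1.4422
NUF2	1.6446	0.7288	-0.8806	0.7628	-1.5992
ORC6	1.3117	0.7718	-1.0927	1.0226	-1.6283
PGR	-1.5129	-1.1257	1.2074	1.0493	0.3944
PHGDH	1.4367	0.7496	-0.6522	-0.8938	0.7619
PTTG1	1.4438	1.0054	-1.0816	0.6730	-1.5120
RRM2	1.4880	0.7382	-1.0015	0.7450	-1.6450
SFRP1	1.2446	-0.0254	-0.7040	-0.5911	1.0609
SLC39A6	-1.4621	-0.6876	1.0256	0.8201	0.1162
TMEM45B	-1.2373	-0.5849	0.9501	0.5954	0.5105
TYMS	1.6525	0.9978	-0.6795	1.0443	-1.7587
UBE2C	1.2846	0.8138	-0.7445	0.9128	-1.4497
UBE2T	1.3660	0.8304	-1.1608	0.8538	-1.7956
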