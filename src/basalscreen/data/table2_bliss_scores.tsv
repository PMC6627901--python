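cell_line	subtype	Afatinib+Cobimetinib	Afatinib+Gedatolisib	Afatinib+Trastuzumab	Cetuximab+Cobimetinib	Cetuximab+Gedatolisib	Cetuximab+Trastuzumab	Erlotinib+Cobimetinib	Erlotinib+Gedatolisib	Erlotinib+Trastuzumab
BHY	Basal	3.777	5.658	-0.348	7.32	5.569	13.195	4.33	4.807	1.701
CAL27	Basal	6.881	6.787	6.243	4.252	3.649	18.943	-0.354	0.38	-0.958
CAL33	Basal	1.89	0.267	5.684	0.134	4.621	12.537	-4.981	2.219	-2.872
HSC2	Basal	-4.527	4.403	NA	NA	3.066	NA	-0.745	2.266	4.648
HSC3	Basal	-3.278	3.889	7.754	0.688	4.096	NA	0.517	1.721	-0.263
KYSE150	Basal	-0.552	2.649	NA	5.502	-0.469	-0.595	-1.648	-0.445	1.263
SCC4	Basal	5.145	4.867	2.687	1.146	0.522	2.728	2.702	2.979	-1.275
SCC9	Basal	-3.499	6.269	NA	-1.755	1.367	NA	-1.792	2.185	NA
SCC15	Basal	-3.148	3.646	14.661	5.549	-0.535	NA	-1.593	0.959	6.95
SCC25	Basal	2.244	3.184	NA	3.195	NA	NA	-0.986	-2.037	NA
HCE4	Non-Basal	-2.168	-0.69	2.283	0.468	NA	-2.688	4.937	-0.317	4.016
HSC4	Non-Basal	-1.389	1.218	3.527	-0.705	6.87	4.059	-5.899	-1.913	-3.647
KYSE70	Non-Basal	0.059	3.988	0.633	-2.264	1.621	1.546	0.589	-1.169	-1.116
KYSE140	Non-Basal	3.049	0.646	7.26	10.795	NA	6.541	0.466	-2.501	5.82
KYSE180	Non-Basal	1.067	2.902	NA	3.957	2.78	NA	1.759	3.795	NA
KYSE270	Non-Basal	-4.853	0.576	-1.243	NA	1.923	-2.788	1.111	-1.681	-3.602
KYSE510	Non-Basal	-0.962	6.481	-1.99	0.86	-0.325	2.142	1.738	4.474	6.968
LB771HNC	Non-Basal	3.722	-0.689	0.706	7.077	NA	NA	-3.277	0.658	-1.902
RPMI2650	Non-Basal	-2.515	4.699	-4.25	NA	NA	NA	NA	NA	NA
TT	Non-Basal	1.248	0.669	3.563	7.21	-0.107	0.137	7.854	1.774	-3.544
TE4	Non-Basal	6.516	4.268	3.194	-4.664	1.476	-0.945	3.363	1.593	7.991
TE5	Non-Basal	1.231	1.934	-2.293	-2.822	3.753	6.738	-1.631	4.127	7.413
TE6	Non-Basal	NA	-0.834	5.833	0.528	2.57	NA	-1.479	-0.38	4.62
TE10	Non-Basal	4.294	-0.084	-1.468	-6.371	-3.032	NA	0.085	0.77	-1.671
TE14	Non-Basal	5.072	2.447	5.155	-5.61	1.86	5.379	-2.549	-1.334	10.887
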