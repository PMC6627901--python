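cell_line	subtype	Afatinib	Erlotinib	Cetuximab	Gedatolisib	Cobimetinib	Trastuzumab
BHY	Basal	3.467751696	4.286063175	4.57727436	3.302462568	4.608746135	4.69416933
CAL27	Basal	3.814815676	4.444098626	5.680773203	3.184901695	3.747852593	5.5725818
CAL33	Basal	3.744753557	4.310451267	4.573913673	2.406624054	4.450866901	5.076910559
HSC2	Basal	4.3439915	4.741863856	5.127815501	2.566283234	4.420333039	4.946942339
HSC3	Basal	3.957972571	4.6095489	5.183631235	2.952916999	3.8894347	5.295803542
KYSE150	Basal	4.441065136	4.780103002	5.684081754	2.980021031	4.687959978	5.550264191
SCC15	Basal	4.315046458	4.766164343	4.54432253	3.764267942	4.6050741	5.494692438
SCC25	Basal	4.177447191	4.336103828	5.446338918	2.771755456	3.798183465	5.231781001
SCC4	Basal	4.019642792	5.002304825	5.305982451	2.737492906	4.32226842	5.256117469
SCC9	Basal	4.134972926	4.713456974	5.222760141	3.005065893	4.873465213	4.87701988
KYSE270	Non-Basal	3.805157987	5.500896683	5.647765664	3.332916543	5.232659439	5.565586558
KYSE180	Non-Basal	4.01491891	4.729217951	5.705364107	3.147861975	4.918800553	5.272014082
TE6	Non-Basal	4.258968922	4.879974238	5.750123119	3.639308374	5.517244329	4.979449358
TE5	Non-Basal	3.9331781	5.159062006	5.461107055	2.778634257	4.731403338	5.23314044
TE10	Non-Basal	4.006096215	5.513704267	5.222443794	3.497187601	4.890993502	4.946552101
KYSE140	Non-Basal	3.375761348	4.562986869	5.376787765	2.919235293	4.740974506	5.268327679
KYSE510	Non-Basal	4.845901636	5.515376689	5.879640984	3.013249683	5.011478461	5.476614796
RPMI2650	Non-Basal	4.780339567	5.726684777	6.149644208	3.600359879	5.476229419	5.540633467
LB771HNC	Non-Basal	4.793902186	5.152157915	5.694559888	3.158211825	5.585646234	5.618555173
HCE4	Non-Basal	4.424539135	5.687089202	5.91969998	3.64854173	4.638847027	5.069966605
KYSE70	Non-Basal	4.46079496	4.986291447	5.50519843	3.657912306	4.8211094	5.244702124
TE4	Non-Basal	1.814915762	3.96069768	5.420791576	2.170670697	4.2463357	5.08505704
TE14	Non-Basal	3.746428006	4.638733677	5.619299993	3.187628054	4.881707599	4.869384943
TT	Non-Basal	4.822344476	4.872688138	6.220243167	3.678272613	4.728732451	5.642166616
HSC4	Non-Basal	3.655491187	4.180726139	4.651136469	2.751213387	3.871130995	5.136060907
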