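	F0	F1	F2	F3	H0	H1	H2	H3	H4
P00	7.054095	7.425409	6.975897	7.13167	8.749396	9.213646	9.286928	8.853358	8.913934
P01	7.072638	7.152731	6.884864	7.272283	8.88118	8.761121	8.890871	8.685846	9.366165
P02	7.046622	7.014952	7.129973	6.81761	8.758215	8.957805	8.937127	9.010064	8.876119
P03	7.02378	7.015246	6.564871	7.211711	7.097883	7.196261	7.109832	7.391301	7.361581
P04	7.088532	6.785697	6.737463	7.325604	7.438116	6.936145	7.368565	6.717622	7.185197
P05	6.119536	8.01845	7.24181	7.341462	7.399567	6.722427	6.733258	6.805118	6.911719
P06	7.057053	7.05372	7.026446	7.023014	7.015655	7.061095	6.949459	7.082455	6.934594
P07	5.933453	7.682505	6.96377	6.854208	6.243608	6.972817	7.340399	7.092414	7.147183
P08	6.10941	7.07651	7.599014	6.513774	7.292009	8.24424	5.991172	6.147356	7.946739
P09	6.743961	7.11111	7.056666	7.108745	6.818623	6.753011	6.624033	7.004091	6.924811
P10	6.945086	7.025363	7.004091	7.303972	7.202177	6.77144	7.026158	6.979791	6.76608
P11	6.525418	7.045572	6.802118	7.117402	6.868699	7.046707	7.036675	6.889568	7.025161
P12	7.321535	7.224374	7.19885	6.588996	6.708598	6.953439	6.737838	5.985985	6.898471
P13	6.731519	7.029586	6.892696	7.217536	6.810276	6.601833	6.751895	6.882193	7.191921
P14	6.809135	6.76494	7.09168	6.650846	6.722949	6.733632	7.455472	7.250567	6.972146
P15	7.075942	7.092662	7.238286	7.010695	6.822534	6.844833	7.452694	7.353441	7.378222
P16	6.717407	6.894584	7.500797	7.373171	7.661544	6.632224	6.344501	6.834411	7.029361
P17	7.099004	6.970196	6.580539	6.140926	6.044288	6.911554	7.29722	6.616129	7.047513
P18	7.169634	6.449714	6.885102	7.131262	7.250158	6.992111	7.09255	7.256318	6.638013
P19	7.612499	7.138132	7.230161	6.735252	6.819886	7.557339	7.321075	6.663441	7.425342
P20	7.423973	6.824211	7.106754	7.22464	6.988688	7.021752	7.386608	7.135966	6.723593
P21	6.857351	6.90461	7.221786	7.050116	7.190581	7.020464	6.643336	7.527366	6.32372
P22	5.673268	8.918558	7.79921	7.11193	6.52147	7.547898	6.54227	6.477008	6.036581
P23	7.102179	6.664513	7.294343	7.045005	7.282187	7.317827	7.035556	7.154436	7.284027
P24	5.997538	6.925372	7.532292	6.822088	7.645362	6.725348	6.673039	7.62399	6.888312
P25	6.95164	7.050873	6.806671	7.13693	6.976334	6.929079	7.094202	7.015137	7.101668
P26	7.302558	6.828807	6.70488	7.167667	7.131631	6.885125	6.8527	7.229945	7.438718
P27	6.926057	7.045267	7.052272	6.672879	6.676136	7.124159	7.30235	6.909851	7.136582
P28	6.692915	7.269153	7.380204	6.801558	7.151758	7.093275	7.232179	6.800277	6.968417
P29	6.902326	7.204083	6.718985	7.032837	6.695957	6.863634	7.408849	6.960263	7.041585
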