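probe	logFC	t	p
P00	 1.85668465	12.3982253891426	3.36889496181e-07
P01	 1.82140760	11.8481510898669	5.07075719131e-07
P02	 1.90557675	18.2965866497269	9.45171274317e-09
P03	 0.27746960	 1.9195177692843	8.52767273767e-02
P04	 0.14480500	 0.7801706878460	4.54206287935e-01
P05	-0.26589670	-0.8047994704762	4.40525624613e-01
P06	-0.03140665	-0.3633038922710	7.24296364765e-01
P07	 0.10080020	 0.2998327976809	7.70733677862e-01
P08	 0.29962620	 0.5826047663330	5.73666722207e-01
P09	-0.18020670	-1.4652216525754	1.75016412180e-01
P10	-0.12049880	-0.9340049813033	3.73331729694e-01
P11	 0.10073450	 0.7469463581873	4.73097994028e-01
P12	-0.42657255	-1.8899634308453	8.94798206450e-02
P13	-0.12021065	-0.8173909292393	4.33638549735e-01
P14	 0.19780295	 1.1206906599103	2.89830269778e-01
P15	 0.06594855	 0.4090036505837	6.91564766823e-01
P16	-0.22108155	-0.8194476714631	4.32520497164e-01
P17	 0.08567455	 0.3096121134820	7.63510621111e-01
P18	 0.13690200	 0.7396027187005	4.77340793823e-01
P19	-0.02159440	-0.0928975870926	9.27906214342e-01
P20	-0.09357310	-0.5755042398753	5.78267311812e-01
P21	-0.06737235	-0.2953784803902	7.74031397419e-01
P22	-0.75069610	-1.3155257094657	2.19061971949e-01
P23	 0.18829660	 1.3627678564081	2.04246691247e-01
P24	 0.29188770	 0.8913455562775	3.94662675729e-01
P25	 0.03675550	 0.3584777684534	7.27788948431e-01
P26	 0.10664580	 0.6257244825921	5.46168493105e-01
P27	 0.10569685	 0.7110549143503	4.94062992409e-01
P28	 0.01322370	 0.0786001823171	9.38974306410e-01
P29	 0.02949985	 0.1835377555962	8.58217048489e-01
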