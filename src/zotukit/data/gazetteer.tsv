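country_name	aliases	geoname_id	continent	centroid_lat	centroid_lon	min_lat	min_lon	max_lat	max_lon
Netherlands	The Netherlands;Holland	2750405	Europe	52.1326	5.2913	50.75	3.20	53.70	7.23
Germany	Deutschland	2921044	Europe	51.1657	10.4515	47.27	5.87	55.06	15.04
France		3017382	Europe	46.2276	2.2137	41.33	-5.14	51.09	9.56
Spain		2510769	Europe	40.4637	-3.7492	27.64	-18.16	43.79	4.33
Italy		3175395	Europe	41.8719	12.5674	35.49	6.63	47.09	18.52
United Kingdom	UK;Great Britain;Britain	2635167	Europe	55.3781	-3.4360	49.90	-8.65	60.86	1.77
Sweden		2661886	Europe	60.1282	18.6435	55.34	11.11	69.06	24.17
Norway		3144096	Europe	64.5783	12.0000	57.98	4.65	71.19	31.08
Finland		660013	Europe	64.9515	26.0673	59.81	20.55	70.09	31.59
Estonia		453733	Europe	58.5953	25.0136	57.51	21.76	59.68	28.21
Poland		798544	Europe	51.9194	19.1451	49.00	14.12	54.84	24.15
Switzerland		2658434	Europe	46.8182	8.2275	45.82	5.96	47.81	10.49
Austria		2782113	Europe	47.5162	14.5501	46.37	9.53	49.02	17.16
Czechia	Czech Republic	3077311	Europe	49.8175	15.4730	48.55	12.09	51.06	18.86
Denmark		2623032	Europe	56.2639	9.5018	54.56	8.07	57.75	15.20
Belgium		2802361	Europe	50.5039	4.4699	49.50	2.55	51.51	6.41
Portugal		2264397	Europe	39.3999	-8.2245	36.96	-9.50	42.15	-6.19
Greece	Hellas	390903	Europe	39.0742	21.8243	34.80	19.37	41.75	28.25
Russia	Russian Federation	2017370	Europe	61.5240	105.3188	41.19	19.64	81.86	180.00
China	People's Republic of China;PR China	1814991	Asia	35.8617	104.1954	18.15	73.50	53.56	134.77
Japan		1861060	Asia	36.2048	138.2529	24.04	122.93	45.52	145.82
India		1269750	Asia	20.5937	78.9629	6.75	68.16	35.50	97.40
Indonesia		1643084	Asia	-0.7893	113.9213	-11.00	95.01	5.91	141.02
Malaysia		1733045	Asia	4.2105	101.9758	0.85	99.64	7.36	119.27
Thailand		1605651	Asia	15.8700	100.9925	5.61	97.34	20.46	105.64
Vietnam	Viet Nam	1562822	Asia	14.0583	108.2772	8.56	102.14	23.39	109.47
Iran	Islamic Republic of Iran	130758	Asia	32.4279	53.6880	25.06	44.03	39.78	63.33
Turkey	Türkiye	298795	Asia	38.9637	35.2433	35.81	25.66	42.11	44.82
South Korea	Republic of Korea;Korea	1835841	Asia	35.9078	127.7669	33.19	124.60	38.61	129.58
United States	USA;United States of America;US	6252001	North America	39.7837	-100.4459	24.54	-124.73	49.39	-66.95
Canada		6251999	North America	56.1304	-106.3468	41.68	-141.00	83.11	-52.62
Mexico		3996063	North America	23.6345	-102.5528	14.53	-118.45	32.72	-86.71
Costa Rica		3624060	North America	9.7489	-83.7534	8.03	-85.95	11.22	-82.55
Panama		3703430	North America	8.5380	-80.7821	7.20	-83.05	9.65	-77.17
Brazil	Brasil	3469034	South America	-14.2350	-51.9253	-33.75	-73.99	5.27	-34.79
Argentina		3865483	South America	-38.4161	-63.6167	-55.06	-73.58	-21.78	-53.64
Chile		3895114	South America	-35.6751	-71.5430	-55.98	-75.64	-17.50	-66.42
Peru		3932488	South America	-9.1900	-75.0152	-18.35	-81.33	-0.04	-68.67
Colombia		3686110	South America	4.5709	-74.2973	-4.23	-79.00	13.39	-66.87
Ecuador		3658394	South America	-1.8312	-78.1834	-5.00	-91.66	1.44	-75.19
Australia		2077456	Oceania	-25.2744	133.7751	-43.64	112.91	-10.06	153.64
New Zealand	Aotearoa	2186224	Oceania	-40.9006	174.8860	-47.29	166.43	-34.39	178.55
Papua New Guinea		2088628	Oceania	-6.3150	143.9555	-11.66	140.84	-1.32	155.96
South Africa		953987	Africa	-30.5595	22.9375	-34.83	16.45	-22.13	32.89
Kenya		192950	Africa	-0.0236	37.9062	-4.68	33.91	5.02	41.90
Tanzania	United Republic of Tanzania	149590	Africa	-6.3690	34.8888	-11.75	29.34	-0.99	40.44
Cameroon		2233387	Africa	7.3697	12.3547	1.65	8.49	13.08	16.19
Madagascar		1062947	Africa	-18.7669	46.8691	-25.61	43.22	-11.95	50.48
Ethiopia		337996	Africa	9.1450	40.4897	3.40	32.99	14.89	48.00
Egypt		357994	Africa	26.8206	30.8025	22.00	24.70	31.67	36.89
Antarctica		6697173	Antarctica	-82.8628	15.0000	-90.00	-180.00	-60.00	180.00
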