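name	gene_id	transcript_id	chromosome	cds_start	cds_end	cds_bp	exons	pp_aa	mw_kda	pi
GmGLYI-1.1	Glyma.01g146300	Glyma.01g146300.1	1	48150827	48154366	1044	9	347	39.3	7.01
GmGLYI-1.2	Glyma.01g146300	Glyma.01g146300.2	1	48150827	48154366	1038	9	345	39.1	7.01
GmGLYI-1.3	Glyma.01g146300	Glyma.01g146300.3	1	48150827	48154366	930	8	309	35.1	8.44
GmGLYI-2.1	Glyma.01g168400	Glyma.01g168400.1	1	50605679	50608020	579	3	192	22.0	5.04
GmGLYI-3.1	Glyma.04g083100	Glyma.04g083100.1	4	7006088	7009361	1041	9	346	38.5	5.83
GmGLYI-4.1	Glyma.05g228500	Glyma.05g228500.1	5	40646576	40651812	1101	9	366	40.6	8.17
GmGLYI-4.2	Glyma.05g228500	Glyma.05g228500.2	5	40646576	40651812	1089	9	362	40.2	6.28
GmGLYI-5.1	Glyma.06g084500	Glyma.06g084500.1	6	6498718	6501298	792	8	263	29.7	5.45
GmGLYI-6.1	Glyma.07g031700	Glyma.07g031700.1	7	2508024	2510223	519	2	172	19.6	5.10
GmGLYI-6.2	Glyma.07g031700	Glyma.07g031700.2	7	2508024	2510223	369	3	122	13.9	4.89
GmGLYI-6.3	Glyma.07g031700	Glyma.07g031700.3	7	2508024	2510223	381	2	126	14.5	5.03
GmGLYI-7.1	Glyma.07g261400	Glyma.07g261400.1	7	43645750	43649851	843	7	280	31.6	5.62
GmGLYI-7.2	Glyma.07g261400	Glyma.07g261400.2	7	43645750	43649851	732	8	243	27.2	5.34
GmGLYI-7.3	Glyma.07g261400	Glyma.07g261400.3	7	43645750	43649851	795	7	264	29.8	5.24
GmGLYI-7.4	Glyma.07g261400	Glyma.07g261400.4	7	43645750	43649851	843	8	280	31.6	5.62
GmGLYI-7.5	Glyma.07g261400	Glyma.07g261400.5	7	43645750	43649851	843	8	280	31.6	5.62
GmGLYI-7.6	Glyma.07g261400	Glyma.07g261400.6	7	43645750	43649851	819	8	272	30.7	6.11
GmGLYI-8.1	Glyma.08g035400	Glyma.08g035400.1	8	2811954	2818455	1071	9	356	39.6	6.56
GmGLYI-9.1	Glyma.08g211100	Glyma.08g211100.1	8	17046316	17048640	426	3	141	16.4	4.86
GmGLYI-10.1	Glyma.09g004300	Glyma.09g004300.1	9	340275	344376	975	8	324	36.9	6.62
GmGLYI-10.2	Glyma.09g004300	Glyma.09g004300.2	9	340275	344376	891	9	296	33.5	6.13
GmGLYI-10.3	Glyma.09g004300	Glyma.09g004300.3	9	340275	344376	864	9	287	32.4	5.74
GmGLYI-10.4	Glyma.09g004300	Glyma.09g004300.4	9	340275	344376	840	8	279	31.5	6.97
GmGLYI-10.5	Glyma.09g004300	Glyma.09g004300.5	9	340275	344376	951	9	316	35.9	8.45
GmGLYI-11.1	Glyma.09g193800	Glyma.09g193800.1	9	41830881	41834537	1041	9	346	39.0	6.68
GmGLYI-11.2	Glyma.09g193800	Glyma.09g193800.2	9	41830881	41834537	819	7	272	30.6	8.76
GmGLYI-12.1	Glyma.09g226500	Glyma.09g226500.1	9	45136253	45137166	333	2	110	12.8	5.23
GmGLYI-13.1	Glyma.11g075000	Glyma.11g075000.1	11	5598647	5600229	579	3	192	22.1	4.97
GmGLYI-14.1	Glyma.11g194200	Glyma.11g194200.1	11	26776807	26779603	747	8	248	28.5	5.48
GmGLYI-15.1	Glyma.11g194300	Glyma.11g194300.1	11	26780838	26784795	702	8	233	26.5	9.16
GmGLYI-16.1	Glyma.12g079700	Glyma.12g079700.1	12	6241940	6246776	708	7	235	26.8	9.28
GmGLYI-16.2	Glyma.12g079700	Glyma.12g079700.2	12	6241940	6246776	558	6	185	21.0	5.41
GmGLYI-16.3	Glyma.12g079700	Glyma.12g079700.3	12	6241940	6246776	525	8	174	20.0	9.69
GmGLYI-17.1	Glyma.12g167400	Glyma.12g167400.1	12	32196920	32200101	555	2	184	21.0	5.14
GmGLYI-18.1	Glyma.13g106600	Glyma.13g106600.1	13	22081599	22084230	630	5	209	23.4	6.49
GmGLYI-19.1	Glyma.13g168200	Glyma.13g168200.1	13	28259866	28261852	504	3	167	19.0	5.46
GmGLYI-20.1	Glyma.15g009500	Glyma.15g009500.1	15	737953	739806	522	3	173	19.4	5.58
GmGLYI-21.1	Glyma.15g108400	Glyma.15g108400.1	15	8534420	8539477	864	8	287	32.4	5.74
GmGLYI-22.1	Glyma.16g003500	Glyma.16g003500.1	16	194687	196274	549	2	182	20.6	5.22
GmGLYI-23.1	Glyma.17g052700	Glyma.17g052700.1	17	4011185	4013445	621	5	206	22.9	7.08
GmGLYI-24.1	Glyma.17g115900	Glyma.17g115900.1	17	9163290	9164088	438	4	145	16.5	6.88
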