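name	gene_id	transcript_id	chromosome	cds_start	cds_end	cds_bp	exons	pp_aa	mw_kda	pi
GmGLYII-1.1	Glyma.02g220100	Glyma.02g220100.1	2	40797403	40800820	609	5	202	22.8	5.62
GmGLYII-2.1	Glyma.04g224100	Glyma.04g224100.1	4	49456049	49460172	600	6	199	22.0	7.12
GmGLYII-2.2	Glyma.04g224100	Glyma.04g224100.2	4	49456049	49460172	546	6	181	20.0	6.54
GmGLYII-2.3	Glyma.04g224100	Glyma.04g224100.3	4	49456049	49460172	486	5	161	17.9	6.49
GmGLYII-2.4	Glyma.04g224100	Glyma.04g224100.4	4	49456049	49460172	432	4	143	15.9	7.59
GmGLYII-3.1	Glyma.06g140800	Glyma.06g140800.1	6	11478165	11482810	777	7	258	28.7	6.86
GmGLYII-4.1	Glyma.11g126200	Glyma.11g126200.1	11	9591802	9595913	948	7	315	34.7	6.06
GmGLYII-4.2	Glyma.11g126200	Glyma.11g126200.2	11	9591802	9595913	861	7	286	31.5	5.92
GmGLYII-5.1	Glyma.12g050800	Glyma.12g050800.1	12	3651594	3655661	951	8	316	35.0	5.93
GmGLYII-5.2	Glyma.12g050800	Glyma.12g050800.2	12	3651594	3655661	948	8	315	34.9	5.94
GmGLYII-5.3	Glyma.12g050800	Glyma.12g050800.3	12	3651594	3655661	924	8	307	34.0	6.22
GmGLYII-6.1	Glyma.13g261400	Glyma.13g261400.1	13	36531853	36536326	1134	9	377	41.4	8.87
GmGLYII-7.1	Glyma.13g345400	Glyma.13g345400.1	13	43601121	43604841	990	7	329	36.3	8.82
GmGLYII-7.2	Glyma.13g345400	Glyma.13g345400.2	13	43601121	43604841	876	8	291	32.0	7.71
GmGLYII-8.1	Glyma.14g187700	Glyma.14g187700.1	14	45250598	45254278	777	7	258	28.7	5.65
GmGLYII-8.2	Glyma.14g187700	Glyma.14g187700.2	14	45250598	45254278	546	5	181	20.0	5.84
GmGLYII-9.1	Glyma.15g028900	Glyma.15g028900.1	15	2325622	2329211	981	7	326	35.8	9.0
GmGLYII-9.2	Glyma.15g028900	Glyma.15g028900.2	15	2325622	2329211	948	8	315	34.7	8.88
GmGLYII-10.1	Glyma.15g245500	Glyma.15g245500.1	15	46785385	46788016	570	5	189	20.8	9.03
GmGLYII-11.1	Glyma.18g163500	Glyma.18g163500.1	18	37294122	37294499	258	2	85	9.5	6.34
GmGLYII-12.1	Glyma.20g118000	Glyma.20g118000.1	20	36083279	36091841	1584	12	527	58.8	6.56
GmGLYII-12.2	Glyma.20g118000	Glyma.20g118000.2	20	36083279	36091841	1467	12	488	54.5	5.92
GmGLYII-12.3	Glyma.20g118000	Glyma.20g118000.3	20	36083279	36091841	1467	12	488	54.5	5.92
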