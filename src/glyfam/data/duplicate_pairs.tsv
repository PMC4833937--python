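locus1	locus2	ka	ks	ka_ks	time_mya	dup_type
GmGLYI-1	GmGLYI-11	0.0354	0.1246	0.2841	10.2131	Segmental
GmGLYI-2	GmGLYI-13	0.0066	0.0983	0.0671	8.0574	Segmental
GmGLYI-3	GmGLYI-5	0.0317	0.0823	0.3852	6.7459	Segmental
GmGLYI-4	GmGLYI-8	0.0451	0.1094	0.4122	8.9672	Segmental
GmGLYI-6	GmGLYI-9	0.0418	0.1581	0.2644	12.9590	Segmental
GmGLYI-10	GmGLYI-21	0.0076	0.0455	0.1670	3.7295	Segmental
GmGLYI-14	GmGLYI-15	0.2260	0.4137	0.5463	33.9098	Tandem
GmGLYI-17	GmGLYI-22	0.0263	0.1434	0.1834	11.7541	Segmental
GmGLYI-18	GmGLYI-23	0.0839	0.1666	0.5036	13.6557	Segmental
GmGLYI-19	GmGLYI-24	0.0450	0.1442	0.3121	11.8197	Segmental
GmGLYII-1	GmGLYII-8	0.0804	0.1449	0.5549	11.8770	Segmental
GmGLYII-2	GmGLYII-3	0.1142	0.1502	0.7603	12.3115	Segmental
GmGLYII-4	GmGLYII-5	0.0278	0.1353	0.2055	11.0902	Segmental
GmGLYII-6	GmGLYII-10	0.0916	0.229	0.4000	18.7705	Segmental
GmGLYII-7	GmGLYII-9	0.0246	0.0767	0.3207	6.2869	Segmental
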