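protein	metal_motif	active_site	activity
GmGLYII-1.1	Absent	Present	No
GmGLYII-2.1	Present	Present	Yes
GmGLYII-2.2	Present	Present	Yes
GmGLYII-2.3	Present	Present	Yes
GmGLYII-2.4	Absent	Present	No
GmGLYII-3.1	Present	Present	Yes
GmGLYII-4.1	Present	Present	Yes
GmGLYII-4.2	Present	Present	Yes
GmGLYII-5.1	Present	Present	Yes
GmGLYII-5.2	Present	Present	Yes
GmGLYII-5.3	Present	Present	Yes
GmGLYII-6.1	Present	Present	Yes
GmGLYII-7.1	Present	Present	Yes
GmGLYII-7.2	Present	Present	Yes
GmGLYII-8.1	Present	Present	Yes
GmGLYII-8.2	Present	Present	Yes
GmGLYII-9.1	Present	Present	Yes
GmGLYII-9.2	Present	Present	Yes
GmGLYII-10.1	Present	Present	Yes
GmGLYII-11.1	Absent	Present	No
GmGLYII-12.1	Present	Present	Yes
GmGLYII-12.2	Present	Present	Yes
GmGLYII-12.3	Present	Present	Yes
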