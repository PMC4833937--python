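protein	site1	site2	site3	site4	activity	domain_length	metal
GmGLYI-1.1	1	1	1	1	Present	124	Ni
GmGLYI-1.2	1	1	1	1	Present	122	Ni
GmGLYI-1.3	1	1	1	1	Present	124	Ni
GmGLYI-2.1	1	1	1	1	Present	125	Ni
GmGLYI-3.1	1	1	1	1	Present	122	Ni
GmGLYI-4.1	1	1	1	1	Present	122	Ni
GmGLYI-4.2	1	1	1	1	Present	122	Ni
GmGLYI-5.1	1	1	1	0	Absent	115	-
GmGLYI-6.1	1	0	1	1	Absent	121	-
GmGLYI-6.2	0	0	1	1	Absent	83	-
GmGLYI-6.3	0	0	1	1	Absent	87	-
GmGLYI-7.1	1	1	1	0	Absent	122	-
GmGLYI-7.2	0	1	1	0	Absent	98	-
GmGLYI-7.3	1	1	1	0	Absent	122	-
GmGLYI-7.4	1	1	1	0	Absent	122	-
GmGLYI-7.5	1	1	1	0	Absent	122	-
GmGLYI-7.6	1	1	1	0	Absent	122	-
GmGLYI-8.1	1	1	1	1	Present	122	Ni
GmGLYI-9.1	1	0	1	1	Absent	120	-
GmGLYI-10.1	1	1	1	1	Present	122	Ni
GmGLYI-10.2	1	1	1	1	Present	122	Ni
GmGLYI-10.3	1	1	1	1	Present	122	Ni
GmGLYI-10.4	1	1	1	1	Present	122	Ni
GmGLYI-10.5	1	1	1	1	Present	122	Ni
GmGLYI-11.1	1	1	1	1	Present	122	Ni
GmGLYI-11.2	1	1	1	1	Present	122	Ni
GmGLYI-12.1	1	0	0	0	Absent	50	-
GmGLYI-13.1	1	0	1	1	Absent	125	-
GmGLYI-14.1	1	1	1	1	Present	169	Zn
GmGLYI-15.1	1	1	1	1	Present	145	Zn
GmGLYI-16.1	1	1	1	1	Present	146	Zn
GmGLYI-16.2	1	1	1	1	Present	145	Zn
GmGLYI-16.3	1	1	0	0	Absent	96	-
GmGLYI-17.1	1	0	1	1	Absent	119	-
GmGLYI-18.1	1	0	1	1	Absent	117	-
GmGLYI-19.1	1	0	1	1	Absent	121	-
GmGLYI-20.1	1	0	1	1	Absent	121	-
GmGLYI-21.1	1	1	1	1	Present	122	Ni
GmGLYI-22.1	1	0	1	1	Absent	119	-
GmGLYI-23.1	1	0	1	1	Absent	117	-
GmGLYI-24.1	1	0	1	0	Absent	126	-
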