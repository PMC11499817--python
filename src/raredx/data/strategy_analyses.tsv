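# Per-analysis strategy/outcome roster reproducing the printed per-stratum counts.
# Proband ids are SYNTHETIC: the source prints only stratum-level counts, not
# per-proband strategy assignments. 113 analyses over 103 probands; the ten
# uninformative clinical-exome probands C05..C14 were re-sequenced as ES-Solo.
strategy	proband_id	informative
CES	C01	1
CES	C02	1
CES	C03	1
CES	C04	1
CES	C05	0
CES	C06	0
CES	C07	0
CES	C08	0
CES	C09	0
CES	C10	0
CES	C11	0
CES	C12	0
CES	C13	0
CES	C14	0
CES	C15	0
CES	C16	0
ES-Solo	C05	0
ES-Solo	C06	0
ES-Solo	C07	0
ES-Solo	C08	0
ES-Solo	C09	0
ES-Solo	C10	0
ES-Solo	C11	0
ES-Solo	C12	0
ES-Solo	C13	0
ES-Solo	C14	0
ES-Solo	S01	1
ES-Solo	S02	1
ES-Solo	S03	1
ES-Solo	S04	1
ES-Solo	S05	1
ES-Solo	S06	1
ES-Solo	S07	1
ES-Solo	S08	1
ES-Solo	S09	1
ES-Duo	D01	1
ES-Duo	D02	1
ES-Duo	D03	0
ES-Duo	D04	0
ES-Duo	D05	0
ES-Duo	D06	0
ES-Duo	D07	0
ES-Trio	T01	1
ES-Trio	T02	1
ES-Trio	T03	1
ES-Trio	T04	1
ES-Trio	T05	1
ES-Trio	T06	1
ES-Trio	T07	1
ES-Trio	T08	1
ES-Trio	T09	1
ES-Trio	T10	1
ES-Trio	T11	1
ES-Trio	T12	1
ES-Trio	T13	1
ES-Trio	T14	1
ES-Trio	T15	1
ES-Trio	T16	1
ES-Trio	T17	1
ES-Trio	T18	1
ES-Trio	T19	1
ES-Trio	T20	1
ES-Trio	T21	1
ES-Trio	T22	1
ES-Trio	T23	1
ES-Trio	T24	1
ES-Trio	T25	1
ES-Trio	T26	1
ES-Trio	T27	1
ES-Trio	T28	1
ES-Trio	T29	1
ES-Trio	T30	1
ES-Trio	T31	1
ES-Trio	T32	1
ES-Trio	T33	0
ES-Trio	T34	0
ES-Trio	T35	0
ES-Trio	T36	0
ES-Trio	T37	0
ES-Trio	T38	0
ES-Trio	T39	0
ES-Trio	T40	0
ES-Trio	T41	0
ES-Trio	T42	0
ES-Trio	T43	0
ES-Trio	T44	0
ES-Trio	T45	0
ES-Trio	T46	0
ES-Trio	T47	0
ES-Trio	T48	0
ES-Trio	T49	0
ES-Trio	T50	0
ES-Trio	T51	0
ES-Trio	T52	0
ES-Trio	T53	0
ES-Trio	T54	0
ES-Trio	T55	0
ES-Trio	T56	0
ES-Trio	T57	0
ES-Trio	T58	0
ES-Trio	T59	0
ES-Trio	T60	0
ES-Trio	T61	0
ES-Trio	T62	0
ES-Trio	T63	0
ES-Trio	T64	0
ES-Trio	T65	0
ES-Trio	T66	0
ES-Trio	T67	0
ES-Trio	T68	0
ES-Trio	T69	0
ES-Trio	T70	0
ES-Trio	T71	0
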