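id	name	ob	bbb	dl
M1	(-)-Alloaromadendrene	54.04	2.07	0.1
M2	(-)-alpha-Cedrene	55.56	2.16	0.1
M3	(+)-alpha-Longipinene	57.47	2.05	0.12
M4	(-)-Caryophyllene oxide	32.67	1.76	0.13
M5	(+)-11-Epispathulenol	81.61	1.55	0.12
M6	(+)-Ledene	51.84	2.16	0.1
M7	(+)-Veraguensin	25.53	0.72	0.39
M8	2'-O-Methylisoliquiritigenin	75.86	-0.16	0.17
M9	Aminacrine	35	0.33	0.12
M10	alpha-Cubebene	16.73	2.1	0.11
M11	Aristolone	45.31	1.54	0.13
M12	Bergapten	42.21	0.69	0.13
M13	beta-Asarone	35.61	1.24	0.06
M14	beta-Cubebene	32.81	2.02	0.11
M15	beta-Gurjunene	51.36	2.07	0.1
M16	beta-Humulene	26.87	2.01	0.06
M17	Bisasarcin	18.55	0.54	0.5
M18	Bisasaricin	28.94	0.65	0.5
M19	Calamendiol	61.13	0.67	0.11
M20	Calarene	52.16	2.04	0.11
M21	cis-Methylisoeugenol	74.21	1.48	0.04
M22	Cycloartenol	38.69	1.33	0.78
M23	Eudesmin	52.35	0.05	0.62
M24	gamma-Asarone	22.76	1.33	0.06
M25	Isocalamendiol	57.63	0.74	0.11
M26	Isopimpinellin	25.93	0.5	0.17
M27	Longicyclene	46.07	2.16	0.15
M28	Marmesin	50.28	0.07	0.18
M29	Methyleugenol	73.36	1.41	0.04
M30	Murolan-3,9(11)-diene-10-peroxy	36.72	1.04	0.11
M31	Patchoulene	49.06	2.17	0.11
M32	alpha-Panasinsene	56.77	2.11	0.12
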