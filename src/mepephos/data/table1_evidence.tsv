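peptide	start	end	phospho	counts	expect	ppm	conservation
INQELSSKENIVQER	37	51	42	2	1.6e-07	0.14	36
RINQELSSKENIVQER	36	51	43	39	1.1e-08	0.9	21
KDLSLSEASENK	53	64	56	7	2.9e-06	0.055	64
KKDLSLSEASENK	52	64	58	2	2.9e-04	0.56	21
DLSLSEASENKGSSK	54	68	61	7	1.2e-06	1	43
DLSLSEASENKGSSK	54	68	66	1	4.2e-04	0.55	86
STGNKGFEDGDDAISK	103	118	103|104	1	6.0e-07	0.11	79,79
NVLNIIPASMNYAK	158	171	166	3	4.3e-05	2.74	36
KIPSDFEGSGYTDLQER	214	230	222	20	6.1e-09	0.87	100
GDNDISPFSGDGQPFK	231	246	236	1	5.6e-05	0.06	86
GDNDISPFSGDGQPFK	231	246	239	6	4.9e-08	0.36	100
DIQTGFAGPSEAESTHLDTK	263	282	272	1	5.4e-07	0.92	79
DIQTGFAGPSEAESTHLDTK	263	282	276	7	7.0e-12	1.02	71
DIQTGFAGPSEAESTHLDTK	263	282	277	3	1.5e-06	2.75	50
EADAVDVSLVEGSNDIMGSTNFK	309	331	316	1	1.3e-09	5.3	93
EGNRVDAGSQNAHQGK	337	352	345	1	2.7e-06	0.69	100
VEFHYPPAPSK	353	363	362	30	4.3e-05	0.67	93
RKEGSSDAAESTNYNEIPK	366	384	370|371	4	3.8e-07	1.43	79,64
GKSQGLPIPSR	414	424	416	4	8.2e-05	0.39	64
NEMDSFNGPSHENIITHGR	432	450	436	5	1.6e-05	0.39	93
NEMDSFNGPSHENIITHGR	432	450	441	31	4.6e-09	1.56	29
NEMDSFNGPSHENIITHGR	432	450	436;441	1	5.6e-04	1.1	93,29
GMPQGKGSWGR	467	477	474	2	4.8e-04	0.05	86
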