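sample	dilution	ilm_density_per_ml	ilm_n_tracked	ilm_rh_nm	ilm_sd_nm	dls_main_rh_nm	uvvis_a280
LA	1000	9.7e13	329	152	59	189	370
LB	1000	9.9e13	96	147	59	235	340
LC	1000	1.5e14	138	136	55	122	400
LA	100	1.1e14	403	148	54	150	355
LB	100	7.8e13	342	143	61	187	322
LC	100	1.1e14	371	152	64	133	378
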