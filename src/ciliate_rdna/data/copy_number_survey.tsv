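species	classification	mtssu_mean	mtssu_sd	nssu_mean	nssu_sd
Epistylis_sp	Oligohymenophorea	8.1e5	4.7e4	3.3e5	1.6e5
Paramecium_caudatum	Oligohymenophorea	1.5e5	4.9e4	1.7e5	1.3e5
Paramecium_sp	Oligohymenophorea	1.1e5	2.4e4	4.3e5	2.1e5
Tetrahymena_thermophila	Oligohymenophorea	1.1e4	9.6e3	1.5e4	7.1e3
Favella_ehrenbergii	Spirotrichea	1.5e5	9.7e4	4.9e5	2.7e5
Sterkiella_sp	Spirotrichea	8.4e4	3.0e4	1.1e6	3.5e5
Phacodinium_metchnikoffi	Spirotrichea	7.1e4	3.4e4	6.0e5	4.7e5
Neobakuella_aenigmatica	Spirotrichea	4.7e4	1.3e4	1.9e5	1.2e3
Euplotes_vannus	Spirotrichea	3.1e4	3.8e3	1.0e5	7.2e4
Oxytricha_trifallax	Spirotrichea	2.9e4	9.3e3	1.1e5	5.7e4
Spirostomum_sp	Heterotrichea	1.4e5	1.9e4	2.1e5	1.3e5
Trithigmostoma_sp	Phyllopharyngea	1.0e5	2.2e4	1.7e4	8.3e3
Coleps_sp	Prostomatea	1.0e4	9.5e2	5.8e3	2.1e3
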