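# binary mitochondrial genome organisation: 0 = single chromosome, 1 = fragmented
L_sp1	0
L_sp2	0
L_sp3	0
L_tinnunculi	1
Plegadiphilus_sp	0
Menacanthus_cornutus	0
Amyrsidea_minuta	0
Myr_sp1	1
Myr_sp2	1
Act_sp1	1
Act_sp2	1
Aus_sp1	0
Aus_sp2	1
Ciconiphilus_sp	0
Colpocephalum_sp1	0
Colpocephalum_griffoneae	0
Colpocephalum_sp2	0
Eomenopon_sp	0
Franciscoloa_sp1	0
Franciscoloa_sp2	0
Franciscoloa_sp3	0
Osborniella_crotophagae	0
Piagetiella_sp	0
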