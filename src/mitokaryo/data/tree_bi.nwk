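(((L_sp1:0.06,L_sp3:0.05):0.09,(L_sp2:0.08,L_tinnunculi:0.10):0.07):0.18,(((Plegadiphilus_sp:0.22,(Menacanthus_cornutus:0.18,Amyrsidea_minuta:0.16):0.05):0.06,(Myr_sp1:0.25,Myr_sp2:0.28):0.32):0.03,((Act_sp1:0.21,Act_sp2:0.19):0.26,((Aus_sp1:0.17,Aus_sp2:0.20):0.12,(Ciconiphilus_sp:0.15,((Colpocephalum_sp1:0.05,(Colpocephalum_griffoneae:0.06,Colpocephalum_sp2:0.04):0.02):0.10,((Eomenopon_sp:0.18,Piagetiella_sp:0.12):0.03,((Franciscoloa_sp1:0.04,(Franciscoloa_sp2:0.05,Franciscoloa_sp3:0.03):0.02):0.09,Osborniella_crotophagae:0.16):0.03):0.02):0.04):0.06):0.05):0.03):0.13);
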