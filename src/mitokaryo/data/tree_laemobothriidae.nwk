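((L_sp1:0.06,L_sp3:0.05):0.09,(L_sp2:0.08,L_tinnunculi:0.10):0.07);
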