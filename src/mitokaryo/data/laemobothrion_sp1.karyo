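# Laemobothrion sp. 1 — typical single-chromosome mt genome, 14,155 bp;
# all 37 genes; all genes transcribed in the same orientation except trnE;
# a 111-bp NCR between trnD and rrnL.
# Synthetic reconstruction: order constrained by the in-text statements
# (identical arrangement to L. sp. 3; differs from L. sp. 2 in the location
# of nad3, trnG, trnW, trnV, trnF, trnM and trnQ only).
species: L_sp1
host: Eurasian coot (Fulica atra)
chr (14155 bp): cox1 L2 cox2 atp8 atp6 cox3 G nad3 A R N S1 -E F nad5 H nad4 nad4L T P nad6 cob Q nad1 S2 L1 D NCR:111 rrnL V rrnS I M W C Y K nad2
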