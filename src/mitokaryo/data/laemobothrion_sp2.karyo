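# Laemobothrion sp. 2 — typical single-chromosome mt genome, 14,626 bp;
# all 37 genes; a 327-bp NCR between cob and nad1.
# Synthetic reconstruction constrained by: differs from L. sp. 1 / sp. 3 in
# the location of exactly seven genes (nad3, trnG, trnW, trnV, trnF, trnM,
# trnQ), every other gene retaining at least one ancestral neighbour.
species: L_sp2
host: black kite (Milvus migrans)
chr (14626 bp): nad5 H nad4 nad4L F T P nad3 nad6 cob NCR:327 nad1 S2 Q L1 D rrnL G rrnS I A R N S1 -E C Y W K nad2 M cox1 L2 cox2 V atp8 atp6 cox3
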