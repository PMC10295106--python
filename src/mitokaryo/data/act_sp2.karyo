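# Actornithophilus sp. 2 — fragmented mt genome: six minichromosomes
# (1,698–4,361 bp); 35 of 37 genes identified (trnP, trnR not found).
# Synthetic reconstruction constrained by the in-text statements: M1 is the
# E-nad4L-nad4 minichromosome (3 genes, written here in a rotated frame of
# the same circle), M6 the largest (12 genes); see act_sp1.karyo for the
# pairwise constraints both fixtures satisfy jointly.
species: Act_sp2
host: masked lapwing (Vanellus miles)
M1 (1698 bp): nad4 NCR:380 E nad4L
M2 (2400 bp): nad5 V K cob nad1 NCR:160
M3 (1900 bp): -A T NCR:95 L1
M4 (2600 bp): nad6 H S2 -Q -rrnS D NCR:130
M5 (2700 bp): nad2 S1 F -W nad3 L2 NCR:205
M6 (4361 bp): Y atp8 atp6 N NCR:120 rrnL G I cox2 cox1 C cox3 -M NCR:240
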