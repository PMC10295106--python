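# Actornithophilus sp. 1 — fragmented mt genome: five minichromosomes
# (2,005–6,112 bp); 35 of 37 genes identified (trnP, trnR not found).
# Synthetic reconstruction constrained by the in-text statements: M1 is the
# E-nad4L-nad4 minichromosome (3 genes), M5 the largest (15 genes); M2
# carries four NCRs of 86–832 bp; the pair with Act. sp. 2 shares the five
# derived clusters V-K-cob-nad1, nad6-H-S2, nad2-S1-F, Y-atp8-atp6-N and
# G-I-cox2-cox1-C-cox3, differs by one split/merge (M2 vs M2+M3),
# translocation of trnQ, trnW, trnL1, nad5, trnD, trnL2 and inversion of
# trnA, trnQ, trnW.
species: Act_sp1
host: pied oystercatcher (Haematopus longirostris)
M1 (2005 bp): E nad4L nad4 NCR:430
M2 (4800 bp): V K cob nad1 NCR:86 A NCR:300 T NCR:170 Q W NCR:832
M3 (3200 bp): nad6 H S2 L2 -rrnS NCR:210
M4 (2900 bp): nad2 S1 F nad3 NCR:140
M5 (6112 bp): Y atp8 atp6 N G I cox2 cox1 C cox3 rrnL -M nad5 L1 D NCR:480
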