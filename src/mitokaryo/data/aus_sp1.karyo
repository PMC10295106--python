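# Austromenopon sp. 1 — typical single-chromosome mt genome, 14,992 bp.
# Synthetic reconstruction: the published figure was not machine-readable, so
# this gene order is constrained by the in-text statements only (37 genes on
# one chromosome; a 127-bp NCR between cox1 and atp6 and a 327-bp NCR between
# trnM and trnD; shares six gene clusters with Aus. sp. 2: cox2-cox1-atp6-atp8,
# nad2-nad5-I, nad3-Y, rrnL-rrnS-L1, nad4L-nad4-E, P-K-S1).
species: Aus_sp1
host: sooty shearwater (Ardenna grisea)
chr (14992 bp): cox2 cox1 NCR:127 atp6 atp8 G nad2 nad5 I T nad3 Y A rrnL rrnS L1 V nad4L nad4 E W P K S1 cob nad1 cox3 nad6 C F H L2 N R S2 M NCR:327 D Q
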