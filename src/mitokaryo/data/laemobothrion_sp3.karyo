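# Laemobothrion sp. 3 — typical single-chromosome mt genome, 14,308 bp;
# same gene arrangement as L. sp. 1 (all genes forward except trnE; 111-bp
# NCR between trnD and rrnL).  Synthetic reconstruction; see
# laemobothrion_sp1.karyo for the constraints.
species: L_sp3
host: Australasian swamphen (Porphyrio porphyrio bellus)
chr (14308 bp): cox1 L2 cox2 atp8 atp6 cox3 G nad3 A R N S1 -E F nad5 H nad4 nad4L T P nad6 cob Q nad1 S2 L1 D NCR:111 rrnL V rrnS I M W C Y K nad2
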