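# Myrsidea sp. 1 — fragmented mt genome: four minichromosomes
# (1,969–6,185 bp); 23 of 37 genes identified (13 protein-coding, 2 rRNA,
# 8 tRNA; 14 tRNAs not found).
# Synthetic reconstruction constrained by the in-text statements: M1 carries
# only rrnL plus a 790-bp NCR; M2 only rrnS plus a 2,494-bp NCR; M3 has 8
# genes with a 27-bp NCR between nad3 and trnS1 and is the minichromosome
# shared with Myr. sp. 2 (Y-nad5-L1-nad3-S1-cox2-cox1-cox3); M4 has 13
# genes with a 59-bp NCR between nad2 and trnM and carries the shared
# cluster G-cob-Q-atp6-atp8-nad4L-nad4-nad6-nad1.
species: Myr_sp1
host: satin bowerbird (Ptilonorhynchus violaceus)
M1 (1969 bp): rrnL NCR:790
M2 (3194 bp): rrnS NCR:2494
M3 (5167 bp): Y nad5 L1 nad3 NCR:27 S1 cox2 cox1 cox3
M4 (6185 bp): nad2 NCR:59 M G cob Q atp6 atp8 nad4L nad4 nad6 nad1 C W
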