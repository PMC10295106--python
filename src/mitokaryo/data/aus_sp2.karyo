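# Austromenopon sp. 2 — fragmented mt genome: two minichromosomes,
# M1 9,499 bp with 16 genes and M2 4,943 bp with 21 genes.
# Synthetic reconstruction constrained by the in-text statements: per
# minichromosome two NCRs (M1: 50 bp between cox1 and atp6, 49 bp between
# nad2 and atp8; M2: 141 bp between trnS1 and trnQ, 80 bp between trnQ and
# nad4L); exactly six maximal gene clusters shared with Aus. sp. 1.
species: Aus_sp2
host: sooty tern (Onychoprion fuscatus) and crested tern (Thalasseus bergii)
M1 (9499 bp): atp6 atp8 NCR:49 nad2 nad5 I G cob A cox3 T C M H N cox2 cox1 NCR:50
M2 (4943 bp): P K S1 NCR:141 Q NCR:80 nad4L nad4 E D nad3 Y F rrnL rrnS L1 R nad1 W nad6 S2 V L2
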