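# Myrsidea sp. 2 — fragmented mt genome, three minichromosomes (published
# previously; only the elements restated in the comparative analysis are
# packaged, at cluster-level granularity).
# Synthetic reconstruction constrained by: one whole minichromosome
# Y-nad5-L1-nad3-S1-cox2-cox1-cox3 in common with Myr. sp. 1; rrnL and rrnS
# on the same minichromosome (unlike Myr. sp. 1); the shared cluster
# G-cob-Q-atp6-atp8-nad4L-nad4-nad6-nad1; the same protein-coding gene
# placement as Myr. sp. 1 but different tRNA placement; 7 tRNAs identified.
species: Myr_sp2
host: citrine warbler (Myiothlypis luteoviridis)
MA: Y nad5 L1 nad3 S1 cox2 cox1 cox3
MB: rrnL rrnS T
MC: G cob Q atp6 atp8 nad4L nad4 nad6 nad1 M nad2
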