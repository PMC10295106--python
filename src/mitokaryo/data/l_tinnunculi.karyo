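# Laemobothrion (Laemobothrion) tinnunculi — fragmented mt genome, three
# minichromosomes (published previously; restated in the comparative
# analysis): cob alone on one minichromosome; nad2, trnP, trnW and trnG on a
# second; all other 32 genes on the third.
# Synthetic reconstruction: the 32-gene order follows the L. sp. 1
# arrangement with the five relocated genes removed.
species: L_tinnunculi
host: Australian hobby (Falco longipennis)
M1: cob
M2: nad2 P W G
M3: cox1 L2 cox2 atp8 atp6 cox3 nad3 A R N S1 -E F nad5 H nad4 nad4L T nad6 Q nad1 S2 L1 D rrnL V rrnS I M C Y K
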