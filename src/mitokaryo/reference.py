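"""The ancestral single-chromosome reference arrangement.

The standard insect mitochondrial gene order (the arrangement inferred as
ancestral for insects and shared by e.g. *Drosophila yakuba*) serves as the
default reference when screening shared clusters for *derived* status: a
conserved run already present in this arrangement is plesiomorphic and
carries no grouping information, whereas a run created by rearrangement is
a candidate synapomorphy.
"""

from __future__ import annotations

from .karyotype import Karyotype, Minichromosome, OrientedGene

# (symbol, orientation) in the conventional reading; -1 marks genes encoded
# on the opposite strand (reverse transcription orientation).
ANCESTRAL_INSECT_ORDER: tuple[tuple[str, int], ...] = (
    ("cox1", 1), ("L2", 1), ("cox2", 1), ("K", 1), ("D", 1), ("atp8", 1),
    ("atp6", 1), ("cox3", 1), ("G", 1), ("nad3", 1), ("A", 1), ("R", 1),
    ("N", 1), ("S1", 1), ("E", 1), ("F", -1), ("nad5", -1), ("H", -1),
    ("nad4", -1), ("nad4L", -1), ("T", 1), ("P", -1), ("nad6", 1),
    ("cob", 1), ("S2", 1), ("nad1", -1), ("L1", -1), ("rrnL", -1),
    ("V", -1), ("rrnS", -1), ("I", 1), ("Q", -1), ("M", 1), ("nad2", 1),
    ("W", 1), ("C", -1), ("Y", -1),
)


def ancestral_reference() -> Karyotype:
    """The 37-gene single-chromosome ancestral arrangement as a Karyotype."""
    genes = [OrientedGene(g, s) for g, s in ANCESTRAL_INSECT_ORDER]
    return Karyotype(
        species_id="ancestral_insect_reference",
        chromosomes=[Minichromosome("chr", list(genes))],
    )


def single_circle_root() -> Karyotype:
    """Alias used as the simulator's default root genome: the full 37-gene
    complement on one circular chromosome."""
    return ancestral_reference()
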