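"""Data model for multichromosomal circular mitochondrial karyotypes.

A *karyotype* describes a species' mitochondrial genome as a set of circular
chromosomes ("minichromosomes" when there are several), each an ordered ring
of oriented genes and non-coding regions (NCRs).  The written left-to-right
order of a chromosome is one arbitrary linearization of the circle: rotations
of the element list, and the full reversal of the list with every orientation
flipped, all denote the same molecule.  Equality of chromosomes is therefore
defined on :func:`canonical_form` only.

NCRs carry only length metadata; every comparison operation in this package
works on the gene-only circular order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Union

from .genes import GENE_NAMESPACE, normalize_symbol

FORWARD = 1
REVERSE = -1


class KaryotypeError(ValueError):
    """Raised on violation of a karyotype invariant (e.g. duplicate gene)."""


@dataclass(frozen=True)
class OrientedGene:
    """A gene with its transcription orientation relative to the written
    linearization of its chromosome (+1 forward, -1 reverse)."""

    gene: str
    orientation: int = FORWARD

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", normalize_symbol(self.gene))
        if self.orientation not in (FORWARD, REVERSE):
            raise KaryotypeError(
                f"orientation must be +1 or -1, got {self.orientation!r}"
            )

    def reversed(self) -> "OrientedGene":
        return OrientedGene(self.gene, -self.orientation)

    @property
    def token(self) -> str:
        return self.gene if self.orientation == FORWARD else "-" + self.gene


@dataclass(frozen=True)
class NonCodingRegion:
    """A non-coding stretch; only its length (bp) matters to the model."""

    length: int
    label: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise KaryotypeError(f"NCR length must be >= 1, got {self.length}")


Element = Union[OrientedGene, NonCodingRegion]

# Signed gene as a plain tuple, the working currency of the comparison and
# simulation modules: ("cox1", 1) / ("Q", -1).
SignedGene = tuple[str, int]


@dataclass
class Minichromosome:
    """One circular chromosome: a label, a ring of elements, and an optional
    total size in bp (assembly metadata, never used in comparisons)."""

    label: str
    elements: list[Element]
    total_size_bp: int | None = None

    def __post_init__(self) -> None:
        if not any(isinstance(e, OrientedGene) for e in self.elements):
            raise KaryotypeError(f"chromosome {self.label!r} contains no gene")
        ncr_total = sum(
            e.length for e in self.elements if isinstance(e, NonCodingRegion)
        )
        if self.total_size_bp is not None and self.total_size_bp < ncr_total:
            raise KaryotypeError(
                f"chromosome {self.label!r}: total_size_bp={self.total_size_bp} "
                f"is smaller than the sum of its NCR lengths ({ncr_total})"
            )

    @property
    def genes(self) -> list[OrientedGene]:
        return [e for e in self.elements if isinstance(e, OrientedGene)]

    def signed_genes(self) -> list[SignedGene]:
        """Gene-only circular order as (symbol, orientation) pairs."""
        return [(g.gene, g.orientation) for g in self.genes]

    def gene_set(self) -> frozenset[str]:
        return frozenset(g.gene for g in self.genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class Karyotype:
    """A species' mitochondrial genome organisation."""

    species_id: str
    chromosomes: list[Minichromosome]
    host: str | None = None

    def __post_init__(self) -> None:
        labels = [c.label for c in self.chromosomes]
        if len(set(labels)) != len(labels):
            raise KaryotypeError(
                f"{self.species_id}: duplicate chromosome labels in {labels}"
            )
        seen: dict[str, str] = {}
        for chrom in self.chromosomes:
            for g in chrom.genes:
                if g.gene in seen:
                    raise KaryotypeError(
                        f"{self.species_id}: gene {g.gene!r} occurs on both "
                        f"{seen[g.gene]!r} and {chrom.label!r}"
                    )
                seen[g.gene] = chrom.label

    def __iter__(self) -> Iterator[Minichromosome]:
        return iter(self.chromosomes)

    def __getitem__(self, label: str) -> Minichromosome:
        for chrom in self.chromosomes:
            if chrom.label == label:
                return chrom
        raise KeyError(label)

    def gene_set(self) -> frozenset[str]:
        return frozenset().union(*(c.gene_set() for c in self.chromosomes))

    def chromosome_of(self, gene: str) -> str:
        """Label of the chromosome carrying *gene*."""
        for chrom in self.chromosomes:
            if gene in chrom.gene_set():
                return chrom.label
        raise KeyError(gene)


@dataclass(frozen=True)
class GeneCensus:
    """Partition of the 37-gene namespace into identified and missing genes."""

    present: frozenset[str]
    missing: frozenset[str]

    def __post_init__(self) -> None:
        if self.present | self.missing != frozenset(GENE_NAMESPACE) or (
            self.present & self.missing
        ):
            raise KaryotypeError("census does not partition the 37-gene namespace")


def gene_census(k: Karyotype) -> GeneCensus:
    """Which of the 37 typical mt genes were identified in this karyotype."""
    present = k.gene_set()
    return GeneCensus(present, frozenset(GENE_NAMESPACE) - present)


def fragmentation_state(k: Karyotype) -> str:
    """``"fragmented"`` iff the complement is spread over >= 2 chromosomes,
    else ``"single"`` — the binary character mapped on the trees."""
    return "fragmented" if len(k.chromosomes) >= 2 else "single"


def _rotations(seq: tuple[SignedGene, ...]) -> Iterable[tuple[SignedGene, ...]]:
    for i in range(len(seq)):
        yield seq[i:] + seq[:i]


def reverse_sequence(seq: Iterable[SignedGene]) -> tuple[SignedGene, ...]:
    """Full reversal: reverse the order and flip every orientation (reading
    the circle in the other direction / from the other strand)."""
    return tuple((g, -s) for g, s in reversed(list(seq)))


def _orient_sort_key(seq: Iterable[SignedGene]):
    # forward orientations sort before reverse, so the canonical
    # representative of an all-forward run is the run itself
    return tuple((g, 0 if s == FORWARD else 1) for g, s in seq)


def linear_canonical(seq: Iterable[SignedGene]) -> tuple[SignedGene, ...]:
    """Normal form of a *linear* oriented gene run: the lesser of the run
    and its full reversal (a run and its reversal are the same object)."""
    seq = tuple(seq)
    return min(seq, reverse_sequence(seq), key=_orient_sort_key)


def canonical_form(mc: Minichromosome | Iterable[SignedGene]) -> tuple[SignedGene, ...]:
    """Normal form of a circular oriented gene order.

    NCRs are dropped; among all rotations of the sequence and all rotations
    of its full reversal, the lexicographically least is returned (symbols
    compare as strings; at equal symbol, forward sorts before reverse).
    Two chromosomes describe the same circle iff their canonical forms are
    equal; the map is idempotent by construction.
    """
    if isinstance(mc, Minichromosome):
        seq = tuple(mc.signed_genes())
    else:
        seq = tuple(mc)
    if not seq:
        raise KaryotypeError("cannot canonicalize an empty gene sequence")
    candidates = list(_rotations(seq)) + list(_rotations(reverse_sequence(seq)))
    return min(candidates, key=_orient_sort_key)
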