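"""Pairwise karyotype comparison.

Given two karyotypes this module answers the questions a comparative
mitogenomics study asks of a species pair:

* which minichromosomes are homologous (:func:`match_chromosomes` — a
  maximum-weight one-to-one matching on shared gene content);
* whether a chromosome split in one lineage / two merged in the other
  (:func:`detect_split_merge`);
* which oriented gene runs are conserved between the two genomes
  (:func:`shared_clusters`), and which of those are *derived*, i.e. absent
  from a reference ancestral arrangement (:func:`derived_clusters`) — the
  candidate synapomorphies;
* which genes moved between homologous chromosome units
  (:func:`translocated_genes`) and which changed transcription orientation
  (:func:`inverted_genes`).

All comparisons work on gene-only circular orders: non-coding regions are
transparent, and a circular chromosome has no absolute strand, so every
orientation-sensitive call is made in the reading frame that maximizes
concordance within a homologous unit (ties resolved toward the first
karyotype).  A conserved run and its full reversal are the same cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .karyotype import (
    Karyotype,
    SignedGene,
    canonical_form,
    linear_canonical,
)


class NoHomologyError(ValueError):
    """The two karyotypes share no gene; no matching is defined."""


# ---------------------------------------------------------------------------
# positional index of a karyotype's gene-only circular orders


class _Positions:
    """gene -> (chromosome label, index, sign); plus per-chromosome rings."""

    def __init__(self, k: Karyotype):
        self.rings: dict[str, list[SignedGene]] = {
            c.label: c.signed_genes() for c in k.chromosomes
        }
        self.loc: dict[str, tuple[str, int, int]] = {}
        for label, ring in self.rings.items():
            for idx, (gene, sign) in enumerate(ring):
                self.loc[gene] = (label, idx, sign)

    def has_adjacency(self, x: SignedGene, y: SignedGene) -> bool:
        """Is the signed adjacency x->y present (in either reading direction
        of the circle)?  Genes are unique, so this is a local check."""
        gx, sx = x
        gy, sy = y
        if gx not in self.loc or gy not in self.loc:
            return False
        lx, ix, bx = self.loc[gx]
        ly, iy, by = self.loc[gy]
        if lx != ly:
            return False
        n = len(self.rings[lx])
        if n < 2:
            return False
        # forward reading: x at i, y at i+1, signs as written
        if iy == (ix + 1) % n and bx == sx and by == sy:
            return True
        # reverse reading: ring read backwards with flipped signs
        if ix == (iy + 1) % n and bx == -sx and by == -sy:
            return True
        return False


# ---------------------------------------------------------------------------
# chromosome homology


@dataclass(frozen=True)
class ChromosomeHomology:
    pairs: tuple[tuple[str, str], ...]
    unmatched_a: tuple[str, ...]
    unmatched_b: tuple[str, ...]
    weights: dict[tuple[str, str], int] = field(hash=False, compare=False, default_factory=dict)


def _optimal_weight(w: np.ndarray) -> int:
    """Maximum total weight of a one-to-one (partial) matching."""
    n = max(w.shape)
    padded = np.zeros((n, n))
    padded[: w.shape[0], : w.shape[1]] = w
    rows, cols = linear_sum_assignment(-padded)
    return int(padded[rows, cols].sum())


def match_chromosomes(a: Karyotype, b: Karyotype) -> ChromosomeHomology:
    """Maximum-weight one-to-one matching of chromosomes, edge weight =
    number of shared genes.  Zero-weight edges are excluded; among optimal
    matchings the one with the lexicographically least sorted pair list
    (by ``(label_a, label_b)``) is returned.
    """
    if not (a.gene_set() & b.gene_set()):
        raise NoHomologyError(
            f"{a.species_id} and {b.species_id} share no mitochondrial gene"
        )
    labels_a = sorted(c.label for c in a.chromosomes)
    labels_b = sorted(c.label for c in b.chromosomes)
    sets_a = {c.label: c.gene_set() for c in a.chromosomes}
    sets_b = {c.label: c.gene_set() for c in b.chromosomes}
    w = np.array(
        [[len(sets_a[la] & sets_b[lb]) for lb in labels_b] for la in labels_a],
        dtype=float,
    )
    best = _optimal_weight(w)

    # lexicographic refinement: fix candidate pairs in label order whenever
    # doing so still attains the optimum on the remaining subproblem
    fixed: list[tuple[str, str]] = []
    rem_a, rem_b = list(labels_a), list(labels_b)
    remaining = best
    for la in labels_a:
        if la not in rem_a:
            continue
        for lb in sorted(rem_b):
            wt = len(sets_a[la] & sets_b[lb])
            if wt == 0:
                continue
            sub_a = [x for x in rem_a if x != la]
            sub_b = [x for x in rem_b if x != lb]
            sub = np.array(
                [[len(sets_a[x] & sets_b[y]) for y in sub_b] for x in sub_a],
                dtype=float,
            ) if sub_a and sub_b else np.zeros((1, 1))
            if wt + _optimal_weight(sub) == remaining:
                fixed.append((la, lb))
                rem_a.remove(la)
                rem_b.remove(lb)
                remaining -= wt
                break
    weights = {(la, lb): len(sets_a[la] & sets_b[lb]) for la, lb in fixed}
    return ChromosomeHomology(
        pairs=tuple(sorted(fixed)),
        unmatched_a=tuple(x for x in labels_a if x not in {p[0] for p in fixed}),
        unmatched_b=tuple(x for x in labels_b if x not in {p[1] for p in fixed}),
        weights=weights,
    )


# ---------------------------------------------------------------------------
# split / merge grouping


@dataclass(frozen=True)
class SplitMergeGroup:
    """One chromosome on one side homologous to >= 2 on the other
    (a fission in one lineage or a fusion in the other)."""

    one_side: str  # "a" or "b": the side holding the single chromosome
    one_label: str
    many_labels: tuple[str, ...]


def detect_split_merge(
    a: Karyotype, b: Karyotype, h: ChromosomeHomology
) -> tuple[tuple[SplitMergeGroup, ...], dict[str, tuple[str, ...]]]:
    """Group each unmatched chromosome with the matched pair whose partner
    (the chromosome on the opposite side) shares the most genes with it.

    Returns ``(groups, orphans)`` where orphans maps side -> labels of
    unmatched chromosomes sharing no gene with any partner.
    """
    sets_a = {c.label: c.gene_set() for c in a.chromosomes}
    sets_b = {c.label: c.gene_set() for c in b.chromosomes}
    attached: dict[tuple[str, str], list[tuple[str, str]]] = {}
    orphans: dict[str, list[str]] = {"a": [], "b": []}

    for side, unmatched, own_sets, partner_sets, partner_ix in (
        ("a", h.unmatched_a, sets_a, sets_b, 1),
        ("b", h.unmatched_b, sets_b, sets_a, 0),
    ):
        for u in unmatched:
            scored = []
            for pair in h.pairs:
                partner = pair[partner_ix]  # chromosome on the opposite side
                overlap = len(own_sets[u] & partner_sets[partner])
                if overlap > 0:
                    scored.append((-overlap, pair))
            if not scored:
                orphans[side].append(u)
                continue
            scored.sort()
            attached.setdefault(scored[0][1], []).append((side, u))

    groups = []
    for pair, extras in sorted(attached.items()):
        pa, pb = pair
        for side in ("a", "b"):
            added = [u for s, u in extras if s == side]
            if not added:
                continue
            if side == "b":
                groups.append(
                    SplitMergeGroup("a", pa, tuple(sorted([pb] + added)))
                )
            else:
                groups.append(
                    SplitMergeGroup("b", pb, tuple(sorted([pa] + added)))
                )
    return tuple(groups), {s: tuple(v) for s, v in orphans.items()}


def _units(
    a: Karyotype, b: Karyotype, h: ChromosomeHomology,
    groups: tuple[SplitMergeGroup, ...],
) -> tuple[dict[str, int], dict[str, int]]:
    """Assign a homologous-unit id to every grouped chromosome label."""
    unit_a: dict[str, int] = {}
    unit_b: dict[str, int] = {}
    for uid, (la, lb) in enumerate(h.pairs):
        unit_a[la] = uid
        unit_b[lb] = uid
    for g in groups:
        if g.one_side == "a":
            uid = unit_a[g.one_label]
            for lb in g.many_labels:
                unit_b[lb] = uid
        else:
            uid = unit_b[g.one_label]
            for la in g.many_labels:
                unit_a[la] = uid
    return unit_a, unit_b


# ---------------------------------------------------------------------------
# shared clusters


@dataclass(frozen=True, eq=False)
class SharedCluster:
    """A maximal oriented gene run (length >= 2) common to two karyotypes.

    ``genes`` is the run as read in karyotype A's frame; a run and its full
    reversal are the same cluster, so identity and hashing use the
    lexicographically least of the two readings (``key``).
    """

    genes: tuple[SignedGene, ...]
    location_a: tuple[str, int]
    location_b: tuple[str, int]
    spans_whole_a: bool = False
    spans_whole_b: bool = False
    #: the run's own closure adjacency is shared too: the cluster is an
    #: entire conserved circle, not a linear run
    circular: bool = False

    @property
    def key(self) -> tuple[SignedGene, ...]:
        if self.circular:
            return canonical_form(self.genes)
        return linear_canonical(self.genes)

    @property
    def spans_whole_chromosomes(self) -> bool:
        return self.spans_whole_a and self.spans_whole_b

    def gene_names(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.genes)

    def __eq__(self, other) -> bool:
        return isinstance(other, SharedCluster) and self.key == other.key

    def __hash__(self) -> int:
        return hash(self.key)

    def __repr__(self) -> str:  # the field's hyphenated cluster notation
        return "-".join(("-" + g if s < 0 else g) for g, s in self.genes)


def _runs_on_ring(
    ring: list[SignedGene], pos_b: _Positions
) -> list[tuple[int, int]]:
    """Maximal arcs (start, length) of *ring* whose internal adjacencies are
    all preserved in B.  length == len(ring) means the whole circle."""
    n = len(ring)
    if n == 0:
        return []
    if n == 1:
        return [(0, 1)] if ring[0][0] in pos_b.loc else []
    ok = [pos_b.has_adjacency(ring[i], ring[(i + 1) % n]) for i in range(n)]
    if all(ok):
        return [(0, n)]
    runs = []
    # scan starting right after each broken edge
    for i in range(n):
        if not ok[i - 1]:  # edge into position i is broken -> run may start
            j = i
            length = 1
            while ok[j % n] and length < n:
                j += 1
                length += 1
            runs.append((i, length))
    return runs


def shared_clusters(
    a: Karyotype, b: Karyotype, min_len: int = 2
) -> list[SharedCluster]:
    """All maximal oriented gene runs of length >= *min_len* common to both
    karyotypes (NCRs ignored; a run equals its full reversal).  Runs that
    cover an entire chromosome on both sides carry the
    ``spans_whole_chromosomes`` flag — shared whole minichromosomes.
    """
    pos_a, pos_b = _Positions(a), _Positions(b)
    out: dict[tuple, SharedCluster] = {}
    for label, ring in pos_a.rings.items():
        n = len(ring)
        for start, length in _runs_on_ring(ring, pos_b):
            if length < min_len:
                continue
            run = tuple(ring[(start + i) % n] for i in range(length))
            whole_a = length == n
            whole_b = length == len(pos_b.rings[pos_b.loc[run[0][0]][0]])
            # a run whose own closure adjacency is also shared is a whole
            # conserved circle; it has no distinguished start, so use the
            # circular canonical rotation (identical from either frame)
            circular = whole_a and pos_b.has_adjacency(run[-1], run[0])
            if circular:
                run = canonical_form(run)
            first_gene = run[0][0]
            lb, ib, _ = pos_b.loc[first_gene]
            la_idx = next(
                i for i, (g, _) in enumerate(ring) if g == first_gene
            )
            cluster = SharedCluster(
                genes=run,
                location_a=(label, la_idx),
                location_b=(lb, ib),
                spans_whole_a=whole_a,
                spans_whole_b=whole_b,
                circular=circular,
            )
            out[cluster.key] = cluster
    return sorted(out.values(), key=lambda c: c.key)


def occurs_in(run: tuple[SignedGene, ...], k: Karyotype) -> bool:
    """Does *run* occur contiguously (up to rotation frame and full
    reversal, NCRs ignored) in karyotype *k*?"""
    pos = _Positions(k)
    if any(g not in pos.loc for g, _ in run):
        return False
    if len(run) == 1:
        return True
    return all(pos.has_adjacency(run[i], run[i + 1]) for i in range(len(run) - 1))


def derived_clusters(
    clusters: list[SharedCluster], reference: Karyotype
) -> list[SharedCluster]:
    """Retain only clusters absent from the reference (ancestral/outgroup)
    arrangement — the candidate synapomorphies."""
    return [c for c in clusters if not occurs_in(c.genes, reference)]


# ---------------------------------------------------------------------------
# translocation / inversion calls


def translocated_genes(
    a: Karyotype, b: Karyotype, h: ChromosomeHomology,
    groups: tuple[SplitMergeGroup, ...],
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Shared genes whose homologous-unit assignment differs between the two
    karyotypes.  Returns ``(translocated, on_orphans)``: genes on chromosomes
    outside any homologous unit are excluded and reported separately."""
    unit_a, unit_b = _units(a, b, h, groups)
    shared = a.gene_set() & b.gene_set()
    moved, orphaned = [], []
    for gene in sorted(shared):
        ua = unit_a.get(a.chromosome_of(gene))
        ub = unit_b.get(b.chromosome_of(gene))
        if ua is None or ub is None:
            orphaned.append(gene)
        elif ua != ub:
            moved.append(gene)
    return tuple(moved), tuple(orphaned)


def _frames(
    a: Karyotype, b: Karyotype, h: ChromosomeHomology,
    groups: tuple[SplitMergeGroup, ...],
) -> dict[str, int]:
    """Reading frame (+1/-1) of every unit-assigned B chromosome, chosen to
    maximize orientation concordance of its resident (non-translocated)
    shared genes; ties resolve to karyotype A's written frame (+1)."""
    unit_a, unit_b = _units(a, b, h, groups)
    pos_a, pos_b = _Positions(a), _Positions(b)
    shared = a.gene_set() & b.gene_set()
    frames: dict[str, int] = {}
    for lb, uid in unit_b.items():
        concord = discord = 0
        for gene, sign in pos_b.rings[lb]:
            if gene not in shared:
                continue
            la = a.chromosome_of(gene)
            if unit_a.get(la) != uid:
                continue  # translocated into this unit: not frame evidence
            sa = pos_a.loc[gene][2]
            if sa == sign:
                concord += 1
            else:
                discord += 1
        frames[lb] = 1 if concord >= discord else -1
    return frames


def inverted_genes(
    a: Karyotype, b: Karyotype, h: ChromosomeHomology,
    groups: tuple[SplitMergeGroup, ...],
) -> tuple[str, ...]:
    """Shared genes whose transcription orientation is discordant in the
    reading frame of the B chromosome that carries them (so a translocated
    gene is assessed in its destination unit)."""
    unit_a, unit_b = _units(a, b, h, groups)
    pos_a, pos_b = _Positions(a), _Positions(b)
    frames = _frames(a, b, h, groups)
    shared = a.gene_set() & b.gene_set()
    flipped = []
    for gene in sorted(shared):
        la, lb = a.chromosome_of(gene), b.chromosome_of(gene)
        if unit_a.get(la) is None or unit_b.get(lb) is None:
            continue
        sa = pos_a.loc[gene][2]
        sb = pos_b.loc[gene][2]
        if sa != frames[lb] * sb:
            flipped.append(gene)
    return tuple(flipped)


# ---------------------------------------------------------------------------
# the composite report


@dataclass(frozen=True)
class RearrangementReport:
    species_a: str
    species_b: str
    chromosome_count_delta: int
    split_merge_groups: tuple[SplitMergeGroup, ...]
    translocated: tuple[str, ...]
    inverted: tuple[str, ...]
    repositioned: tuple[str, ...]
    orphan_genes: tuple[str, ...]
    shared_whole_chromosomes: int
    clusters: tuple[SharedCluster, ...]
    derived: tuple[SharedCluster, ...] | None = None

    def to_dict(self) -> dict:
        d = {
            "species_a": self.species_a,
            "species_b": self.species_b,
            "chromosome_count_delta": self.chromosome_count_delta,
            "split_merge_groups": [
                {"one_side": g.one_side, "one": g.one_label, "many": list(g.many_labels)}
                for g in self.split_merge_groups
            ],
            "translocated_genes": list(self.translocated),
            "inverted_genes": list(self.inverted),
            "repositioned_genes": list(self.repositioned),
            "orphan_genes": list(self.orphan_genes),
            "shared_whole_chromosomes": self.shared_whole_chromosomes,
            "shared_clusters": [repr(c) for c in self.clusters],
        }
        if self.derived is not None:
            d["derived_clusters"] = [repr(c) for c in self.derived]
        return d


def compare(
    a: Karyotype,
    b: Karyotype,
    reference: Karyotype | None = None,
    min_len: int = 2,
) -> RearrangementReport:
    """Full pairwise comparison: homology, split/merge, shared and derived
    clusters, translocated / inverted / repositioned genes.

    ``chromosome_count_delta`` is anti-symmetric and the gene sets symmetric
    under argument swap.  A *repositioned* gene moved within its homologous
    unit (its neighbourhood changed but not its chromosome assignment) —
    a positional shuffle, reported separately from translocations.
    """
    h = match_chromosomes(a, b)
    groups, orphan_chroms = detect_split_merge(a, b, h)
    clusters = tuple(shared_clusters(a, b, min_len=min_len))
    moved, orphan_genes = translocated_genes(a, b, h, groups)
    flipped = inverted_genes(a, b, h, groups)

    clustered = {g for c in clusters for g in c.gene_names()}
    unit_a, unit_b = _units(a, b, h, groups)
    shared = a.gene_set() & b.gene_set()
    repositioned = []
    for gene in sorted(shared):
        la, lb = a.chromosome_of(gene), b.chromosome_of(gene)
        ua, ub = unit_a.get(la), unit_b.get(lb)
        if ua is None or ub is None or ua != ub:
            continue
        if gene in flipped or gene in clustered:
            continue
        # a lone gene on a chromosome has no adjacency to conserve
        if len(a[la]) < 2 or len(b[lb]) < 2:
            continue
        repositioned.append(gene)

    return RearrangementReport(
        species_a=a.species_id,
        species_b=b.species_id,
        chromosome_count_delta=len(a.chromosomes) - len(b.chromosomes),
        split_merge_groups=groups,
        translocated=moved,
        inverted=flipped,
        repositioned=tuple(repositioned),
        orphan_genes=orphan_genes,
        shared_whole_chromosomes=sum(
            1 for c in clusters if c.spans_whole_chromosomes
        ),
        clusters=clusters,
        derived=tuple(derived_clusters(list(clusters), reference))
        if reference is not None
        else None,
    )
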