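"""Synthetic-data generator: karyotype evolution along a tree.

Minichromosome karyotypes evolve under four rearrangement event classes —
fission (a circle cut at two inter-gene positions into two circles), fusion
(two circles joined at uniform positions with uniform relative orientation),
translocation (a contiguous gene block excised and reinserted elsewhere on
another chromosome, orientation uniform) and inversion (a block reversed in
place, flipping orientations).  Event counts per branch are
Poisson(total rate x branch length); classes are drawn proportionally to
their rates; gene content is conserved by every event.  Every applied event
is recorded in an :class:`EventLog` whose replay reproduces each node's
karyotype exactly — the ground truth behind the comparison and
reconstruction recovery tests.

A two-state Markov simulator for the binary fragmentation character
(:func:`simulate_binary_character`) and an end-to-end bundle mirroring the
study's clade structure (:func:`make_paper_like_dataset`) complete the
module.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import dendropy
import numpy as np

from .karyotype import Karyotype, Minichromosome, OrientedGene, SignedGene
from .phylo import MkModel, TipStates, parse_newick
from .reference import single_circle_root

EVENT_KINDS = ("fission", "fusion", "translocation", "inversion")


@dataclass(frozen=True)
class SimConfig:
    """Rates are events per unit branch length; ``max_block`` caps the
    length of translocated/inverted segments."""

    fission: float = 0.0
    fusion: float = 0.0
    translocation: float = 0.0
    inversion: float = 0.0
    max_block: int = 3
    seed: int = 0
    root_karyotype: Karyotype | None = None

    def rates(self) -> np.ndarray:
        return np.array(
            [self.fission, self.fusion, self.translocation, self.inversion]
        )


@dataclass(frozen=True)
class Event:
    """One recorded rearrangement; carries every sampled choice so that
    replaying the log is deterministic without an RNG."""

    branch: str            # id of the child node of the branch
    kind: str
    chrom: str             # chromosome acted on (source for translocation)
    positions: tuple[int, ...]   # cut/excision/insertion indices
    block: tuple[SignedGene, ...]
    dest: str | None = None      # destination chromosome / fusion partner
    flip: bool = False           # orientation flip on reinsertion/fusion
    new_labels: tuple[str, ...] = ()
    skipped: bool = False


Genome = dict[str, list[SignedGene]]


def _genome_of(k: Karyotype) -> Genome:
    return {c.label: c.signed_genes() for c in k.chromosomes}


def _karyotype_of(genome: Genome, species_id: str) -> Karyotype:
    chroms = [
        Minichromosome(label, [OrientedGene(g, s) for g, s in ring])
        for label, ring in sorted(genome.items())
    ]
    return Karyotype(species_id, chroms)


def apply_event(genome: Genome, ev: Event) -> None:
    """Apply a recorded event in place (no randomness)."""
    if ev.skipped:
        return
    if ev.kind == "fission":
        ring = genome.pop(ev.chrom)
        i, j = ev.positions
        part_a = ring[i:j]
        part_b = ring[j:] + ring[:i]
        la, lb = ev.new_labels
        genome[la] = part_a
        genome[lb] = part_b
    elif ev.kind == "fusion":
        ring_a = genome.pop(ev.chrom)
        ring_b = genome.pop(ev.dest)
        p, q = ev.positions
        ra = ring_a[p:] + ring_a[:p]
        rb = ring_b[q:] + ring_b[:q]
        if ev.flip:
            rb = [(g, -s) for g, s in reversed(rb)]
        genome[ev.new_labels[0]] = ra + rb
    elif ev.kind == "translocation":
        src = genome[ev.chrom]
        start, length, ins = ev.positions
        idx = [(start + i) % len(src) for i in range(length)]
        block = [src[i] for i in idx]
        genome[ev.chrom] = [g for i, g in enumerate(src) if i not in set(idx)]
        if ev.flip:
            block = [(g, -s) for g, s in reversed(block)]
        dest = genome[ev.dest]
        genome[ev.dest] = dest[:ins] + block + dest[ins:]
    elif ev.kind == "inversion":
        ring = genome[ev.chrom]
        start, length = ev.positions
        n = len(ring)
        idx = [(start + i) % n for i in range(length)]
        block = [(ring[i][0], -ring[i][1]) for i in reversed(idx)]
        for slot, val in zip(idx, block):
            ring[slot] = val
    else:
        raise ValueError(f"unknown event kind {ev.kind!r}")


def _sample_event(
    rng: np.random.Generator, genome: Genome, cfg: SimConfig, branch: str,
    counter: list[int],
) -> Event:
    """Draw an event class proportional to rates and sample its parameters;
    an infeasible class is recorded as skipped and redrawn by the caller."""
    rates = cfg.rates()
    kind = EVENT_KINDS[rng.choice(4, p=rates / rates.sum())]
    labels = sorted(genome)

    if kind == "fission":
        eligible = [l for l in labels if len(genome[l]) >= 2]
        if not eligible:
            return Event(branch, kind, "", (), (), skipped=True)
        chrom = eligible[rng.integers(len(eligible))]
        n = len(genome[chrom])
        i, j = sorted(rng.choice(n, size=2, replace=False))
        counter[0] += 1
        la = f"x{counter[0]}"
        counter[0] += 1
        lb = f"x{counter[0]}"
        block = tuple(genome[chrom][int(i):int(j)])
        return Event(branch, kind, chrom, (int(i), int(j)), block,
                     new_labels=(la, lb))

    if kind == "fusion":
        if len(labels) < 2:
            return Event(branch, kind, "", (), (), skipped=True)
        a, b = rng.choice(len(labels), size=2, replace=False)
        ca, cb = labels[int(a)], labels[int(b)]
        p = int(rng.integers(len(genome[ca])))
        q = int(rng.integers(len(genome[cb])))
        flip = bool(rng.integers(2))
        counter[0] += 1
        return Event(branch, kind, ca, (p, q), tuple(genome[cb]), dest=cb,
                     flip=flip, new_labels=(f"x{counter[0]}",))

    if kind == "translocation":
        sources = [l for l in labels if len(genome[l]) >= 2]
        if len(labels) < 2 or not sources:
            return Event(branch, kind, "", (), (), skipped=True)
        chrom = sources[rng.integers(len(sources))]
        n = len(genome[chrom])
        length = int(rng.integers(1, min(cfg.max_block, n - 1) + 1))
        start = int(rng.integers(n))
        dests = [l for l in labels if l != chrom]
        dest = dests[rng.integers(len(dests))]
        ins = int(rng.integers(len(genome[dest]) + 1))
        flip = bool(rng.integers(2))
        block = tuple(genome[chrom][(start + i) % n] for i in range(length))
        return Event(branch, kind, chrom, (start, length, ins), block,
                     dest=dest, flip=flip)

    # inversion: block strictly shorter than the circle, else it is the
    # identity rearrangement on an unoriented circle
    eligible = [l for l in labels if len(genome[l]) >= 2]
    if not eligible:
        return Event(branch, kind, "", (), (), skipped=True)
    chrom = eligible[rng.integers(len(eligible))]
    n = len(genome[chrom])
    length = int(rng.integers(1, min(cfg.max_block, n - 1) + 1))
    start = int(rng.integers(n))
    block = tuple(genome[chrom][(start + i) % n] for i in range(length))
    return Event(branch, kind, chrom, (start, length), block)


@dataclass
class SimResult:
    tips: dict[str, Karyotype]
    internals: dict[str, Karyotype]
    events: list[Event]
    tree: dendropy.Tree


def _branch_ids(tree: dendropy.Tree) -> dict:
    ids = {}
    counter = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            ids[node] = node.taxon.label
        else:
            counter += 1
            ids[node] = f"N{counter}"
    return ids


def evolve_on_tree(
    tree: dendropy.Tree, cfg: SimConfig,
    events_per_branch: int | None = None,
) -> SimResult:
    """Evolve the root karyotype down the tree.

    Per branch the number of events is Poisson(total rate x length), or the
    fixed ``events_per_branch`` when given (the controlled setting used by
    recovery experiments).  Infeasible draws (e.g. fusion on a
    single-chromosome genome) are logged as skipped and redrawn so Poisson
    counts stay interpretable.  Identical seeds give identical output.
    """
    root = cfg.root_karyotype or single_circle_root()
    rng = np.random.default_rng(cfg.seed)
    ids = _branch_ids(tree)
    counter = [0]
    genomes: dict = {tree.seed_node: _genome_of(root)}
    events: list[Event] = []
    tips: dict[str, Karyotype] = {}
    internals: dict[str, Karyotype] = {}
    internals[ids[tree.seed_node]] = _karyotype_of(
        genomes[tree.seed_node], ids[tree.seed_node]
    )
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        genome = copy.deepcopy(genomes[node.parent_node])
        bl = node.edge.length if node.edge.length is not None else 1.0
        total = cfg.rates().sum()
        if events_per_branch is not None:
            n_events = events_per_branch
        else:
            n_events = int(rng.poisson(total * bl)) if total > 0 else 0
        applied = 0
        guard = 0
        while applied < n_events and guard < 50 * (n_events + 1):
            guard += 1
            ev = _sample_event(rng, genome, cfg, ids[node], counter)
            events.append(ev)
            if ev.skipped:
                continue
            apply_event(genome, ev)
            applied += 1
        genomes[node] = genome
        k = _karyotype_of(genome, ids[node])
        if node.is_leaf():
            tips[ids[node]] = k
        else:
            internals[ids[node]] = k
    return SimResult(tips=tips, internals=internals, events=events, tree=tree)


def replay(
    root: Karyotype, tree: dendropy.Tree, events: list[Event]
) -> dict[str, Karyotype]:
    """Re-apply an event log from the root; returns karyotypes for every
    node id.  Replay is exact: the log carries all sampled choices."""
    ids = _branch_ids(tree)
    by_branch: dict[str, list[Event]] = {}
    for ev in events:
        by_branch.setdefault(ev.branch, []).append(ev)
    genomes: dict = {tree.seed_node: _genome_of(root)}
    out: dict[str, Karyotype] = {
        ids[tree.seed_node]: _karyotype_of(_genome_of(root), ids[tree.seed_node])
    }
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        genome = copy.deepcopy(genomes[node.parent_node])
        for ev in by_branch.get(ids[node], []):
            apply_event(genome, ev)
        genomes[node] = genome
        out[ids[node]] = _karyotype_of(genome, ids[node])
    return out


# ---------------------------------------------------------------------------
# binary character simulation


def simulate_binary_character_history(
    tree: dendropy.Tree, model: MkModel, root_state: int = 0, seed: int = 0
) -> tuple[TipStates, dict, int]:
    """Forward-simulate the two-state chain down the tree.

    Returns (tip states, per-node states keyed by branch id, number of
    0->1 transitions along branches counted at branch granularity)."""
    rng = np.random.default_rng(seed)
    ids = _branch_ids(tree)
    node_states = {tree.seed_node: root_state}
    gains = 0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_state = node_states[node.parent_node]
        bl = node.edge.length if node.edge.length is not None else 1.0
        p = model.transition_matrix(bl)[parent_state]
        state = int(rng.random() < p[1])
        if (parent_state, state) == (0, 1):
            gains += 1
        node_states[node] = state
    tips = {
        n.taxon.label: node_states[n] for n in tree.leaf_node_iter()
    }
    return tips, {ids[n]: s for n, s in node_states.items()}, gains


def simulate_binary_character(
    tree: dendropy.Tree, model: MkModel, root_state: int = 0, seed: int = 0
) -> TipStates:
    tips, _, _ = simulate_binary_character_history(tree, model, root_state, seed)
    return tips


# ---------------------------------------------------------------------------
# controlled experiments: random trees, single-event recovery


def random_bifurcating_tree(
    n_tips: int, seed: int = 0, mean_brlen: float = 0.5
) -> dendropy.Tree:
    """Random rooted bifurcating tree built by successive random joins, with
    exponential branch lengths (mean *mean_brlen*)."""
    rng = np.random.default_rng(seed)
    subtrees = [f"t{i}:{rng.exponential(mean_brlen):.6f}" for i in range(1, n_tips + 1)]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(int(j))
        a = subtrees.pop(int(i))
        if len(subtrees) == 0:
            subtrees.append(f"({a},{b})")
        else:
            subtrees.append(f"({a},{b}):{rng.exponential(mean_brlen):.6f}")
    return parse_newick(subtrees[0] + ";")


def fragmented_root(n_chromosomes: int = 4) -> Karyotype:
    """The 37-gene complement pre-cut into *n_chromosomes* circles — a
    fragmented starting genome large enough that single-event recovery is
    never confounded by tiny chromosomes."""
    from .reference import ANCESTRAL_INSECT_ORDER

    genes = list(ANCESTRAL_INSECT_ORDER)
    size = len(genes) // n_chromosomes
    chroms = []
    for i in range(n_chromosomes):
        part = genes[i * size:] if i == n_chromosomes - 1 else genes[i * size:(i + 1) * size]
        chroms.append(
            Minichromosome(f"M{i + 1}", [OrientedGene(g, s) for g, s in part])
        )
    return Karyotype("fragmented_root", chroms)


def recover_event(parent: Karyotype, child: Karyotype):
    """Classify the single rearrangement separating *parent* from *child*
    from the pairwise comparison alone.

    Returns ``(kind, blocks)`` where blocks is a frozenset of gene
    frozensets: the two fission/fusion products, or the moved/inverted gene
    block.  Returns ("none", empty) for indistinguishable genomes.
    """
    from .compare import compare as _compare

    rep = _compare(parent, child)
    if rep.chromosome_count_delta == -1 and rep.split_merge_groups:
        g = rep.split_merge_groups[0]
        parts = frozenset(child[l].gene_set() for l in g.many_labels)
        return "fission", parts
    if rep.chromosome_count_delta == 1 and rep.split_merge_groups:
        g = rep.split_merge_groups[0]
        parts = frozenset(parent[l].gene_set() for l in g.many_labels)
        return "fusion", parts
    if rep.translocated:
        return "translocation", frozenset({frozenset(rep.translocated)})
    if rep.inverted:
        return "inversion", frozenset({frozenset(rep.inverted)})
    return "none", frozenset()


def run_recovery_experiment(
    n_replicates: int = 1000, seed: int = 0
) -> dict:
    """Single-event recovery: per replicate one event (class drawn with
    equal weights) is applied to the fragmented root genome; the pairwise
    comparison must recover both the event class and the affected gene
    block.  Gene-content conservation is asserted on every replicate."""
    from .karyotype import Karyotype as _K

    rng = np.random.default_rng(seed)
    root = fragmented_root()
    cfg = SimConfig(
        fission=1.0, fusion=1.0, translocation=1.0, inversion=1.0,
        max_block=3, seed=0,
    )
    counter = [0]
    correct = 0
    conserved = 0
    failures = []
    for rep_i in range(n_replicates):
        genome = _genome_of(root)
        ev = _sample_event(rng, genome, cfg, "b", counter)
        while ev.skipped:
            ev = _sample_event(rng, genome, cfg, "b", counter)
        apply_event(genome, ev)
        child = _karyotype_of(genome, "child")
        if child.gene_set() == root.gene_set():
            conserved += 1
        kind, blocks = recover_event(root, child)
        expected_block = frozenset(g for g, _ in ev.block)
        if ev.kind in ("fission", "fusion"):
            rest = root.gene_set() if ev.kind == "fission" else None
            if ev.kind == "fission":
                whole = root[ev.chrom].gene_set()
            else:
                whole = root[ev.chrom].gene_set() | root[ev.dest].gene_set()
            truth = frozenset({expected_block, whole - expected_block}) \
                if ev.kind == "fission" \
                else frozenset({root[ev.chrom].gene_set(), root[ev.dest].gene_set()})
            ok = kind == ev.kind and blocks == truth
        else:
            ok = kind == ev.kind and blocks == frozenset({expected_block})
        if ok:
            correct += 1
        else:
            failures.append((rep_i, ev.kind, kind))
    return {
        "n": n_replicates,
        "correct": correct,
        "recovery_rate": correct / n_replicates,
        "conservation_rate": conserved / n_replicates,
        "failures": failures,
    }


# ---------------------------------------------------------------------------
# end-to-end integration bundle


@dataclass
class PaperLikeDataset:
    tree: dendropy.Tree
    tip_states: TipStates
    sim: SimResult
    true_gains: int
    fragmented_tips: tuple[str, ...]


def _clade(names: list[str], bl: float = 0.1) -> str:
    if len(names) == 1:
        return f"{names[0]}:{bl}"
    inner = f"({names[0]}:{bl},{names[1]}:{bl})"
    for n in names[2:]:
        inner = f"({inner}:{bl},{n}:{bl})"
    return inner


def make_paper_like_dataset(seed: int = 0) -> PaperLikeDataset:
    """A 23-tip integration fixture mirroring the study design: five ingroup
    clades of 3, 2, 2, 2 and 10 species plus a 4-tip outgroup; the
    fragmentation character gains placed as in the ML-tree scenario (one
    gain on the stem uniting the two all-fragmented clades, one terminal
    gain inside the two-species clade pair, one in the outgroup); karyotypes
    evolved from the 37-gene single-circle root."""
    clades = {
        "A": [f"cladeA_sp{i}" for i in range(1, 4)],
        "B": [f"cladeB_sp{i}" for i in range(1, 3)],
        "C": [f"cladeC_sp{i}" for i in range(1, 3)],
        "D": [f"cladeD_sp{i}" for i in range(1, 3)],
        "E": [f"cladeE_sp{i}" for i in range(1, 11)],
        "OUT": [f"outgroup_sp{i}" for i in range(1, 5)],
    }
    newick = (
        f"({_clade(clades['OUT'])}:0.15,"
        f"({_clade(clades['A'])}:0.08,"
        f"(({_clade(clades['B'])}:0.1,{_clade(clades['C'])}:0.1):0.07,"
        f"({_clade(clades['D'])}:0.08,{_clade(clades['E'])}:0.06):0.04"
        "):0.05):0.12);"
    )
    tree = parse_newick(newick)
    fragmented = tuple(
        clades["B"] + clades["C"] + ["cladeD_sp2", "outgroup_sp4"]
    )
    states: TipStates = {
        leaf: (1 if leaf in fragmented else 0)
        for leaf in (n.taxon.label for n in tree.leaf_node_iter())
    }
    cfg = SimConfig(
        fission=0.3, fusion=0.1, translocation=0.3, inversion=0.3,
        max_block=3, seed=seed,
    )
    sim = evolve_on_tree(tree, cfg)
    # gains: stem of (B,C), tip cladeD_sp2, tip outgroup_sp4
    return PaperLikeDataset(
        tree=tree, tip_states=states, sim=sim, true_gains=3,
        fragmented_tips=fragmented,
    )
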