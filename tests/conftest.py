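"""Shared fixtures and independent brute-force oracles.

The oracles here re-derive each quantity by exhaustive enumeration and stay
deliberately independent of the implementation paths they check: matching by
trying every injective chromosome assignment, cluster discovery by scanning
every arc of every rotation, parsimony and Mk likelihood by summing or
minimizing over every internal-state assignment.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from mitokaryo.karyotype import (
    Karyotype,
    Minichromosome,
    OrientedGene,
    canonical_form,
    linear_canonical,
    reverse_sequence,
)
from mitokaryo.genes import GENE_NAMESPACE
from mitokaryo.pipeline import load_fixtures


@pytest.fixture(scope="session")
def fx():
    return load_fixtures()


# ---------------------------------------------------------------------------
# random karyotype generation


def random_karyotype(
    rng: np.random.Generator,
    n_genes: int = 10,
    n_chromosomes: int = 3,
    species_id: str = "random",
    gene_pool: tuple[str, ...] | None = None,
) -> Karyotype:
    pool = list(gene_pool or GENE_NAMESPACE)
    genes = list(rng.choice(pool, size=n_genes, replace=False))
    signs = rng.choice([1, -1], size=n_genes)
    cuts = sorted(rng.choice(range(1, n_genes), size=n_chromosomes - 1, replace=False)) if n_chromosomes > 1 else []
    bounds = [0, *cuts, n_genes]
    chroms = []
    for i in range(n_chromosomes):
        part = [
            OrientedGene(str(g), int(s))
            for g, s in zip(genes[bounds[i]:bounds[i + 1]], signs[bounds[i]:bounds[i + 1]])
        ]
        chroms.append(Minichromosome(f"M{i + 1}", part))
    return Karyotype(species_id, chroms)


# ---------------------------------------------------------------------------
# matching oracle


def exhaustive_matching_weight(a: Karyotype, b: Karyotype) -> int:
    """Best total shared-gene weight over every one-to-one assignment."""
    sets_a = [c.gene_set() for c in a.chromosomes]
    sets_b = [c.gene_set() for c in b.chromosomes]
    small, large = (sets_a, sets_b) if len(sets_a) <= len(sets_b) else (sets_b, sets_a)
    best = 0
    for perm in itertools.permutations(range(len(large)), len(small)):
        total = sum(len(small[i] & large[j]) for i, j in enumerate(perm))
        best = max(best, total)
    return best


# ---------------------------------------------------------------------------
# shared-run oracle


def _ring_variants(ring):
    """Both reading directions of a circle, doubled for wraparound scans."""
    fwd = list(ring)
    rev = list(reverse_sequence(ring))
    return [fwd + fwd, rev + rev]


def _occurs(run, rings) -> bool:
    L = len(run)
    run = list(run)
    for ring in rings:
        n = len(ring) // 2
        if L > n:
            continue
        for start in range(n):
            if ring[start:start + L] == run:
                return True
    return False


def brute_force_shared_runs(a: Karyotype, b: Karyotype, min_len: int = 2) -> set:
    """Every maximal common oriented run, via exhaustive arc scanning.

    Keys: whole-circle runs are circular-canonical, arcs linear-canonical
    (the lexicographically least of the run and its full reversal)."""
    rings_b = []
    for c in b.chromosomes:
        rings_b.extend(_ring_variants(c.signed_genes()))
    common: set = set()
    for c in a.chromosomes:
        ring = c.signed_genes()
        n = len(ring)
        for length in range(min_len, n + 1):
            for start in range(n):
                run = tuple(ring[(start + i) % n] for i in range(length))
                if len({g for g, _ in run}) < length:
                    break  # wrapped past a full circle
                if _occurs(run, rings_b):
                    common.add(run)
        if n >= min_len and _occurs(tuple(ring), rings_b):
            common.add(tuple(ring))
    # keep only runs not contained in a longer common run
    def contained(r1, r2) -> bool:
        if len(r1) >= len(r2):
            return False
        doubled = list(r2) + list(r2)
        rev = list(reverse_sequence(r2))
        return _occurs(r1, [doubled, rev + rev])

    maximal = {r for r in common if not any(contained(r, s) for s in common if s != r)}
    keys = set()
    for r in maximal:
        # a run is a whole conserved circle only when both karyotypes carry
        # it as a complete chromosome
        circular = all(
            any(
                len(r) == len(c.signed_genes())
                and canonical_form(r) == canonical_form(c.signed_genes())
                for c in k.chromosomes
            )
            for k in (a, b)
        )
        keys.add(canonical_form(r) if circular else linear_canonical(r))
    return keys


def cluster_keys(clusters) -> set:
    """Implementation clusters mapped to the oracle's key convention."""
    return {c.key for c in clusters}


# ---------------------------------------------------------------------------
# tree oracles (enumeration over internal-state assignments)


def _internal_nodes(tree):
    return [n for n in tree.preorder_node_iter() if not n.is_leaf()]


def _edge_len(node):
    return node.edge.length if node.edge.length is not None else 1.0


def enum_fitch(tree, states, root_state=0):
    """(min_changes, min_gains, max_gains) by exhaustive enumeration."""
    internals = _internal_nodes(tree)
    best_changes = None
    gains_at_best = []
    for assignment in itertools.product((0, 1), repeat=len(internals)):
        node_state = dict(zip(internals, assignment))
        if root_state is not None and node_state[tree.seed_node] != root_state:
            continue
        for leaf in tree.leaf_node_iter():
            node_state[leaf] = states[leaf.taxon.label]
        changes = gains = 0
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            sp, sc = node_state[node.parent_node], node_state[node]
            if sp != sc:
                changes += 1
            if (sp, sc) == (0, 1):
                gains += 1
        if best_changes is None or changes < best_changes:
            best_changes, gains_at_best = changes, [gains]
        elif changes == best_changes:
            gains_at_best.append(gains)
    return best_changes, min(gains_at_best), max(gains_at_best)


def enum_mk_likelihood(tree, states, model) -> float:
    """Likelihood by summing over every internal-state assignment."""
    internals = _internal_nodes(tree)
    total = 0.0
    for assignment in itertools.product((0, 1), repeat=len(internals)):
        node_state = dict(zip(internals, assignment))
        for leaf in tree.leaf_node_iter():
            node_state[leaf] = states[leaf.taxon.label]
        p = model.root_prior[node_state[tree.seed_node]]
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            P = model.transition_matrix(_edge_len(node))
            p *= P[node_state[node.parent_node], node_state[node]]
        total += p
    return total


def enum_mk_loglik(tree, states, model) -> float:
    lik = enum_mk_likelihood(tree, states, model)
    return math.log(lik) if lik > 0 else -math.inf


def enum_marginals(tree, states, model) -> dict:
    """Per-internal-node marginal P(state) by enumeration; keyed by the
    frozenset of descendant tip labels."""
    internals = _internal_nodes(tree)
    weights: dict = {n: [0.0, 0.0] for n in internals}
    for assignment in itertools.product((0, 1), repeat=len(internals)):
        node_state = dict(zip(internals, assignment))
        for leaf in tree.leaf_node_iter():
            node_state[leaf] = states[leaf.taxon.label]
        p = model.root_prior[node_state[tree.seed_node]]
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            P = model.transition_matrix(_edge_len(node))
            p *= P[node_state[node.parent_node], node_state[node]]
        for n in internals:
            weights[n][node_state[n]] += p
    out = {}
    for n in internals:
        total = sum(weights[n])
        clade = frozenset(l.taxon.label for l in n.leaf_iter())
        out[clade] = (weights[n][0] / total, weights[n][1] / total)
    return out
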