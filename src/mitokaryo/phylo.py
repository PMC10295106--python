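"""Mapping the binary genome-fragmentation character on fixed trees.

The character is 0 = single-chromosome mitochondrial genome, 1 = fragmented
into minichromosomes.  Two complementary analyses are provided:

* **Fitch/Sankoff parsimony** (:func:`fitch_origins`): the minimum number of
  independent 0->1 gains over all most-parsimonious reconstructions, with
  the root constrained to the single-chromosome state by default (the
  single circular chromosome is ancestral for animals), plus the gain range
  across MPRs.

* **Mk likelihood** (:func:`mk_loglik`, :func:`fit_rates`,
  :func:`marginal_asr`): a two-state continuous-time Markov chain with one
  symmetric rate (Mk1) or separate gain/loss rates (AsymmMk), pruned with
  Felsenstein's algorithm, maximum-likelihood rate estimation, and marginal
  ancestral state probabilities at every internal node.

Trees are ``dendropy.Tree`` objects (rooted; polytomies handled natively);
missing branch lengths default to 1.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize, minimize_scalar

TipStates = dict[str, int]

RATE_BOUNDS = (1e-9, 1e3)


class TreeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Newick I/O (dendropy-backed)


def parse_newick(text: str, default_brlen: float = 1.0) -> dendropy.Tree:
    """Parse a rooted Newick tree; tips must be uniquely labeled and missing
    branch lengths are filled with *default_brlen*."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=False,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises various parse error types
        raise TreeError(f"malformed Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise TreeError(f"duplicate tip labels: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node and edge.length is None:
            edge.length = default_brlen
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and len(node.child_nodes()) == 1:
            raise TreeError("internal node with a single child")
    return tree


def read_newick(path, default_brlen: float = 1.0) -> dendropy.Tree:
    with open(path, encoding="utf-8") as fh:
        return parse_newick(fh.read(), default_brlen=default_brlen)


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip() + "\n"


def read_tip_states(path) -> TipStates:
    """Two-column TSV (species_id, state in {0,1}); '#' comments allowed."""
    states: TipStates = {}
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            name, value = line.split("\t") if "\t" in line else line.split()
            states[name.strip()] = int(value)
    return states


def _tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _check_states(tree: dendropy.Tree, states: TipStates) -> None:
    missing = [t for t in _tip_labels(tree) if t not in states]
    if missing:
        raise TreeError(f"tips without a character state: {missing}")
    bad = {t: s for t, s in states.items() if s not in (0, 1)}
    if bad:
        raise TreeError(f"states must be 0 or 1: {bad}")


# ---------------------------------------------------------------------------
# Fitch/Sankoff parsimony with gain counting


@dataclass(frozen=True)
class FitchResult:
    min_changes: int
    min_gains: int
    max_gains: int

    @property
    def gain_range(self) -> tuple[int, int]:
        return (self.min_gains, self.max_gains)


def _sankoff_gains(tree, states, root_state, sense: int) -> tuple[int, int]:
    """Lexicographic Sankoff DP: minimize total changes, then *sense* times
    the number of 0->1 gain edges (sense=+1 -> fewest gains among MPRs,
    sense=-1 -> most gains).  Returns (changes, gains)."""
    INF = (10**9, 10**9)
    dp: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = states[node.taxon.label]
            dp[node] = {s: (0, 0), 1 - s: INF}
            continue
        table = {}
        for sv in (0, 1):
            changes = gains = 0
            feasible = True
            for child in node.child_nodes():
                best = None
                for sc in (0, 1):
                    c, g = dp[child][sc]
                    if c >= INF[0]:
                        continue
                    c += 1 if sc != sv else 0
                    g += 1 if (sv, sc) == (0, 1) else 0
                    cand = (c, sense * g)
                    if best is None or cand < best:
                        best = cand
                if best is None:
                    feasible = False
                    break
                changes += best[0]
                gains += sense * best[1]
            table[sv] = (changes, gains) if feasible else INF
        dp[node] = table
    root = tree.seed_node
    if root_state is None:
        c0, g0 = dp[root][0]
        c1, g1 = dp[root][1]
        best = min((c0, sense * g0), (c1, sense * g1))
    else:
        c, g = dp[root][root_state]
        best = (c, sense * g)
    if best[0] >= INF[0]:
        raise TreeError("no feasible reconstruction (conflicting constraints)")
    return best[0], sense * best[1]


def fitch_origins(
    tree: dendropy.Tree, states: TipStates, root_state: int | None = 0
) -> FitchResult:
    """Minimum number of independent fragmentation origins (0->1 gain edges)
    over all most-parsimonious reconstructions, and the gain range across
    MPRs.  The root is constrained to the single-chromosome state by
    default; pass ``root_state=None`` for an unconstrained count."""
    _check_states(tree, states)
    changes, lo = _sankoff_gains(tree, states, root_state, sense=+1)
    _, hi = _sankoff_gains(tree, states, root_state, sense=-1)
    return FitchResult(min_changes=changes, min_gains=lo, max_gains=hi)


def origin_tally(groups: list[tuple[str, int]]) -> dict:
    """Sum per-lineage minimum origin counts into an overall tally."""
    for name, n in groups:
        if n < 0 or int(n) != n:
            raise ValueError(f"{name}: origin count must be a non-negative integer")
    return {
        "total": sum(n for _, n in groups),
        "breakdown": {name: n for name, n in groups},
    }


# ---------------------------------------------------------------------------
# Mk models


@dataclass(frozen=True)
class MkModel:
    """Two-state CTMC for the fragmentation character.

    q01 is the fragmentation (gain) rate, q10 the re-assembly (loss) rate;
    Mk1 constrains them equal.  root_prior defaults to uniform (0.5, 0.5),
    matching the common default for likelihood ancestral state
    reconstruction; ``stationary=True`` uses the model's stationary
    distribution instead.
    """

    kind: str  # "Mk1" | "AsymmMk"
    q01: float
    q10: float
    root_prior: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        if self.kind not in ("Mk1", "AsymmMk"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.q01 < 0 or self.q10 < 0:
            raise ValueError("rates must be non-negative")
        if self.kind == "Mk1" and self.q01 != self.q10:
            raise ValueError("Mk1 requires q01 == q10")
        if abs(sum(self.root_prior) - 1.0) > 1e-9 or min(self.root_prior) < 0:
            raise ValueError("root_prior must be a probability pair")

    def stationary(self) -> tuple[float, float]:
        r = self.q01 + self.q10
        if r == 0:
            return (0.5, 0.5)
        return (self.q10 / r, self.q01 / r)

    def transition_matrix(self, t: float) -> np.ndarray:
        """Closed-form 2x2 transition probabilities over time *t*."""
        r = self.q01 + self.q10
        if r == 0 or t == 0:
            return np.eye(2)
        e = math.exp(-r * t)
        pi0, pi1 = self.q10 / r, self.q01 / r
        return np.array(
            [
                [pi0 + pi1 * e, pi1 * (1 - e)],
                [pi0 * (1 - e), pi1 + pi0 * e],
            ]
        )


def mk1(q: float, root_prior=(0.5, 0.5)) -> MkModel:
    return MkModel("Mk1", q, q, root_prior)


def _edge_length(node) -> float:
    return node.edge.length if node.edge.length is not None else 1.0


def _partials(tree, states, model) -> tuple[dict, float]:
    """Post-order conditional likelihoods with per-node scaling.

    Returns (partials, log_scale); partials[node] is the 2-vector of
    P(tip data below node | state at node) divided by exp(accumulated
    scaling).
    """
    partials: dict = {}
    log_scale = 0.0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            vec = np.zeros(2)
            vec[states[node.taxon.label]] = 1.0
            partials[node] = vec
            continue
        vec = np.ones(2)
        for child in node.child_nodes():
            P = model.transition_matrix(_edge_length(child))
            vec = vec * (P @ partials[child])
        m = vec.max()
        if m > 0:
            vec = vec / m
            log_scale += math.log(m)
        partials[node] = vec
    return partials, log_scale


def mk_loglik(tree: dendropy.Tree, states: TipStates, model: MkModel) -> float:
    """Log-likelihood of the tip states by Felsenstein pruning; -inf when
    the data have probability zero (e.g. a zero rate with both states
    present)."""
    _check_states(tree, states)
    partials, log_scale = _partials(tree, states, model)
    lik = float(np.dot(model.root_prior, partials[tree.seed_node]))
    if lik <= 0:
        return -math.inf
    return math.log(lik) + log_scale


def fit_rates(
    tree: dendropy.Tree,
    states: TipStates,
    kind: str = "Mk1",
    root_prior: tuple[float, float] = (0.5, 0.5),
) -> tuple[MkModel, float]:
    """Maximum-likelihood rate estimation within bounds [1e-9, 1e3].

    Mk1 is a bounded scalar optimization in log-rate; AsymmMk a 2-D
    quasi-Newton search seeded from the Mk1 optimum (among other starts),
    which guarantees the nested-model inequality
    ``loglik(AsymmMk) >= loglik(Mk1)`` up to optimizer tolerance.
    Returns ``(model, log_likelihood)``.
    """
    _check_states(tree, states)
    lo, hi = math.log(RATE_BOUNDS[0]), math.log(RATE_BOUNDS[1])

    def nll1(logq: float) -> float:
        return -mk_loglik(tree, states, mk1(math.exp(logq), root_prior))

    res1 = minimize_scalar(
        nll1, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8}
    )
    q_mk1 = math.exp(res1.x)
    if kind == "Mk1":
        model = mk1(q_mk1, root_prior)
        return model, mk_loglik(tree, states, model)
    if kind != "AsymmMk":
        raise ValueError(f"unknown model kind {kind!r}")

    def nll2(logqs) -> float:
        m = MkModel("AsymmMk", math.exp(logqs[0]), math.exp(logqs[1]), root_prior)
        ll = mk_loglik(tree, states, m)
        return -ll if math.isfinite(ll) else 1e12

    starts = [
        (res1.x, res1.x),
        (res1.x + 1.0, res1.x - 1.0),
        (res1.x - 1.0, res1.x + 1.0),
        (math.log(0.1), math.log(0.1)),
    ]
    best = None
    for x0 in starts:
        res = minimize(
            nll2,
            x0=np.array(x0),
            method="L-BFGS-B",
            bounds=[(lo, hi), (lo, hi)],
            options={"ftol": 1e-12, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    model = MkModel(
        "AsymmMk", math.exp(best.x[0]), math.exp(best.x[1]), root_prior
    )
    return model, mk_loglik(tree, states, model)


# ---------------------------------------------------------------------------
# marginal ancestral state reconstruction


@dataclass(frozen=True)
class AsrResult:
    """Marginal state probabilities at every node, with the model used.

    ``probs`` maps node id -> (P(single), P(fragmented)); ``clades`` maps
    node id -> the tip set below that node, for stable addressing of
    unlabeled internal nodes.
    """

    model: MkModel
    log_likelihood: float
    probs: dict[str, tuple[float, float]] = field(hash=False)
    clades: dict[str, frozenset[str]] = field(hash=False)

    def p_fragmented(self, tips) -> float:
        """Marginal P(fragmented) at the MRCA whose clade is exactly *tips*."""
        target = frozenset(tips)
        for node_id, clade in self.clades.items():
            if clade == target:
                return self.probs[node_id][1]
        raise KeyError(f"no node with clade {sorted(target)}")

    @property
    def root_p_fragmented(self) -> float:
        root_id = max(self.clades, key=lambda n: len(self.clades[n]))
        return self.probs[root_id][1]


def _node_id(node, counter: dict) -> str:
    if node.is_leaf():
        return node.taxon.label
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    if node.label:
        return node.label
    counter["i"] += 1
    return f"N{counter['i']}"


def marginal_asr(
    tree: dendropy.Tree, states: TipStates, model: MkModel
) -> AsrResult:
    """Marginal posterior of the character at every node via the standard
    two-pass (re-rooting) construction: each node's marginal combines the
    partial likelihoods of all incident subtrees with the root prior.
    Probabilities at every node sum to 1."""
    _check_states(tree, states)
    partials, _ = _partials(tree, states, model)
    ll = mk_loglik(tree, states, model)

    # pre-order "outside" messages
    up: dict = {tree.seed_node: np.array(model.root_prior, dtype=float)}
    for node in tree.preorder_node_iter():
        children = node.child_nodes()
        if not children:
            continue
        down = {c: model.transition_matrix(_edge_length(c)) @ partials[c] for c in children}
        for child in children:
            sib = np.ones(2)
            for other in children:
                if other is not child:
                    sib = sib * down[other]
            msg = (up[node] * sib) @ model.transition_matrix(_edge_length(child))
            m = msg.max()
            up[child] = msg / m if m > 0 else msg

    probs: dict[str, tuple[float, float]] = {}
    clades: dict[str, frozenset[str]] = {}
    counter = {"i": 0}
    for node in tree.preorder_node_iter():
        joint = up[node] * partials[node]
        total = joint.sum()
        if total <= 0:
            raise TreeError("zero marginal likelihood at a node")
        joint = joint / total
        nid = _node_id(node, counter)
        probs[nid] = (float(joint[0]), float(joint[1]))
        clades[nid] = frozenset(
            leaf.taxon.label for leaf in node.leaf_iter()
        )
    return AsrResult(model=model, log_likelihood=ll, probs=probs, clades=clades)
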