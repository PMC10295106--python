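# Methods

This note records the modelling assumptions, conventions and numerical
choices behind `mitokaryo`, in the order the data flow through the package.

## Karyotype model

A karyotype is a set of circular chromosomes over the canonical 37-gene
bilaterian mitochondrial complement. The model forbids duplicate genes
across chromosomes: every karyotype described in the study system carries
each gene at most once, and uniqueness is what makes chromosome homology
and cluster detection well-posed (each shared gene has exactly one location
in each genome). Genomes with duplicated mt genes are outside scope.

The written left-to-right order of a chromosome is one arbitrary
linearization of the circle. There is no global "plus strand" for a circular
molecule, so gene orientations are stored relative to the written frame, and
every orientation-sensitive comparison is frame-relative. Chromosome
equality is defined on a canonical form: the lexicographically least of all
rotations of the gene order and all rotations of its full reversal (reverse
order, all orientations flipped), with forward orientations sorting before
reverse so that all-forward circles canonicalize to themselves.

Non-coding regions (NCRs) are retained in the model — they carry length
metadata that mirrors published genome descriptions — but are transparent to
every comparison: the cluster characters of interest are defined purely on
gene order, and published shared clusters span NCRs (e.g. a conserved
cox2-cox1-atp6-atp8 run with an NCR between cox1 and atp6 in both genomes).
Chromosome and NCR bp sizes are assembly metadata only; nothing downstream
consumes them.

## Pairwise comparison

**Homology.** Chromosomes of two karyotypes are matched one-to-one by
maximum-weight matching with edge weight = number of shared genes
(zero-weight edges excluded). The assignment is solved with
`scipy.optimize.linear_sum_assignment`, followed by a lexicographic
refinement: candidate pairs are fixed in `(label_a, label_b)` order whenever
doing so still attains the optimum, making tie-breaks deterministic.

**Split/merge.** Each unmatched chromosome is grouped with the matched pair
whose opposite-side partner shares the most genes with it (ties by label);
a group of one chromosome vs ≥ 2 chromosomes is reported as one
fission/fusion unit. Unmatched chromosomes sharing no gene with any partner
are flagged as orphans, not grouped. Matched pairs plus groups define
*homologous units*, the frame for all gene-level calls.

**Shared clusters.** A shared cluster is a maximal run of ≥ 2 oriented genes
contiguous in both genomes (a run equals its full reversal). Because genes
are unique, a run is found by chaining shared signed adjacencies; an
adjacency is shared when the second gene follows the first, with matching
relative orientations, in either reading direction of its chromosome. The
default minimum length is 2: singleton "sharing" is vacuous. When a run's
own closure adjacency is also shared, the cluster is an entire conserved
circle (a shared whole minichromosome) and is represented by its circular
canonical form; this is also what the `shared_whole_chromosomes` count
reports. `min_len` and these semantics make cluster sets symmetric in the
two genomes, which the test suite checks against an exhaustive arc-scanning
oracle on small random karyotypes.

**Derived clusters.** A cluster is *derived* when it does not occur (same
run semantics) in a reference ancestral arrangement. The reference is an
explicit argument: published analyses do not state one, so the pipeline
defaults to the standard insect mitochondrial gene order, packaged in
`mitokaryo.reference`. Derived clusters are the candidate synapomorphies.

**Translocation / inversion / repositioning.** A gene is *translocated*
when its homologous-unit assignment differs between the genomes. A gene is
*inverted* when its orientation is discordant in the reading frame of the
chromosome that carries it in the second genome; each chromosome's frame is
the one maximizing orientation concordance of its resident
(non-translocated) shared genes, with ties resolved toward the first
karyotype's written frame. A translocated gene is assessed in its
destination unit, so a gene can be both translocated and inverted. Genes
that stay in their unit, keep their orientation, but retain no shared
adjacency are reported separately as *repositioned* (within-unit shuffles —
for single-chromosome genomes this is the only kind of relocation
possible). Genes on orphan chromosomes are excluded from all three calls
and listed separately. All reported sets are lexicographically sorted.

No minimal-event edit distance (DCJ/HP) is computed: the analyses this
package supports report gene sets and split/merge units, not rearrangement
distances, and multi-genome questions are answered pairwise plus
derived-cluster screening against a reference.

## Phylogenetic character mapping

The fragmentation character is binary: 0 = all genes on one chromosome,
1 = fragmented. Trees are rooted `dendropy` trees; polytomies are handled
natively by both dynamic programs; missing branch lengths default to 1.0.

**Parsimony.** Origin counting uses a Sankoff-style DP that minimizes total
state changes and, lexicographically within that optimum, minimizes (or
maximizes) the number of 0→1 gain edges — yielding the gain range across all
most-parsimonious reconstructions. The root is constrained to state 0 by
default, reflecting that the single circular chromosome is ancestral for
animals; an unconstrained mode (`root_state=None`) is provided.

**Mk models.** Mk1 has one symmetric rate; AsymmMk separate gain (q01) and
loss (q10) rates. Transition probabilities use the closed form for the
2-state chain; the likelihood is computed by pruning with per-node rescaling
(scale factors accumulated in log space), so zero-probability data return
−inf rather than underflowing. The root prior is uniform (0.5, 0.5) by
default — the common default for likelihood ancestral state reconstruction —
with the stationary distribution available as an option. Rates are fitted in
log space within [1e-9, 1e3]: bounded scalar search for Mk1 (xatol 1e-8) and
L-BFGS-B for AsymmMk, seeded from the Mk1 optimum among other starts so the
nested-model inequality holds up to optimizer tolerance. Marginal ancestral
probabilities use the standard two-pass construction (outside messages
combined with subtree partial likelihoods and the prior) and are normalized
per node. The pruning likelihood is validated two ways: against brute-force
enumeration over internal-state assignments (|Δ| < 1e-10 on random trees of
≤ 6 tips) and against an independent reference implementation (a pinned
phytools::fitMk log-likelihood, matched to 1e-9).

## Simulator

The generator evolves a root karyotype down a tree under four event
classes. Per branch the event count is Poisson(total rate × branch length);
classes are drawn proportionally to their rates. Fission cuts a ≥ 2-gene
circle at two uniform inter-gene positions; fusion joins two circles at
uniform positions with uniform relative orientation; translocation excises
a contiguous block (length uniform on [1, max_block], strictly smaller than
its chromosome) and reinserts it at a uniform position on another
chromosome with uniform orientation; inversion reverses an in-place block
(strictly shorter than the circle — reversing a whole unoriented circle is
the identity). Events infeasible in the current genome (e.g. fusion of a
single-chromosome genome) are logged as skipped and redrawn, keeping
Poisson counts interpretable. Every applied event records all its sampled
choices, so replaying the log reproduces each node's karyotype exactly;
gene content is conserved by construction and asserted in tests.

The published record implies this event vocabulary but parameterizes no
process; the rates, the uniform block-length and insertion-position
distributions, and the default `max_block = 3` are simulator conventions.
NCR dynamics are not simulated (comparisons ignore NCRs). The binary
character simulator draws states forward along the tree from the Mk
transition probabilities. What passing recovery tests show is therefore
that the *comparison logic* is sound on genomes whose history matches the
event vocabulary — not that real minichromosome evolution follows uniform
block sizes, rate homogeneity, or independence of events.

`make_paper_like_dataset` assembles an integration fixture mirroring the
study design — five ingroup clades of 3, 2, 2, 2 and 10 tips plus a 4-tip
outgroup (23 species), fragmentation gains placed as in the ML-tree
scenario (a single gain uniting the two all-fragmented clades, one terminal
gain in the two-species clade pair, one in the outgroup) — with karyotypes
evolved from the 37-gene single-circle root.

## Packaged fixtures

The published figures carrying the full gene orders are not machine-
readable, so the `.karyo` fixtures are *constrained reconstructions*: gene
orders chosen to satisfy, jointly and exactly, every statement printed in
the text — chromosome counts, per-chromosome gene counts, missing genes,
NCR sizes with their flanking genes, the shared cluster strings, the
translocated/inverted gene lists, and the split/merge structure. Each
fixture file declares this in its header. `transcription_lint` pins all
those counts and reports mismatches as findings rather than exceptions; the
one known internal inconsistency of the source description (six clusters
listed with 18 genes, described as "20 genes in total") is always emitted
as a waived finding. The ML/BI tree fixtures likewise reconstruct
inter-clade arrangements consistent with the stated clade memberships and
origin counts (2 origins within Menoponidae on the ML topology, 3 on the
BI topology), with plausible branch lengths. Conclusions that depend on the
exact unpublished gene orders beyond these constraints cannot be checked
against the fixtures.

## Problem sizes and tolerances

The statistical checks run at sizes chosen to make their targets
well-estimated while keeping the whole suite quick: 500 random ≤ 6-tip
trees for pruning-vs-enumeration (tolerance 1e-10), 200 replicates of
64-tip trees for Mk1 rate recovery (median fitted rate within 25% of the
simulating rate 0.5), 1000 single-event replicates for rearrangement
recovery (≥ 99% class-and-block recovery, 100% gene conservation, starting
from a four-chromosome genome so no event is confounded by tiny
chromosomes). Marginal probabilities must sum to 1 within 1e-9 per node.

## Known limitations

* Duplicate genes, partial gene complements from degraded assemblies, and
  nucleotide-level evidence (sizes, identities, coverage) are out of scope;
  bp values are carried as metadata only.
* Homology is gene-content based; two chromosomes sharing only convergently
  co-located genes would still be matched.
* The inversion frame is majority-concordance per chromosome; for a merged
  unit read from two independently written circles the majority vote mixes
  frames, which can matter in adversarial cases with many inversions.
* Parsimony and Mk results are conditional on the fixed input topology;
  tree inference is deliberately not part of the package.
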