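# Methods

This note records the models, the numerical choices, and what the synthetic
benchmark does and does not establish.

## Profile HMMs

Each family carries a single boolean match-column mask: a column is a match
column iff its non-gap occupancy is at least `occupancy_min` (default 0.5).
Every subtree profile of the family — including single-sequence leaf
profiles — is built on this shared mask, which is what makes bit scores of
different subtree profiles comparable for one query: they describe the same
model coordinates against the same null.

**Architecture.** A match/insert/delete chain of `k` match states. `I_j`
lives between match columns `j` and `j+1` (no inserts outside the first and
last match column; residues there belong to the free flanks). The nine
transition types per layer (M/I/D × M/I/D) are estimated from the weighted
paths of the training rows. Two scoring modes:

* `glocal` (whole-protein, "mda" families): the model must be traversed from
  layer 0 to layer `k`; the query flanks are free (an unpenalized self-loop
  emitting at background frequencies, contributing zero log-odds).
* `local` (domain families): free entry into any match state with prior
  `1/k`, free exit after any match state; delete-chain entry/exit is not
  allowed in local mode.

**Estimation.** Sequence weights are position-based (Henikoff) over the match
columns of the training subset, normalized to sum to one — duplicating a row
therefore changes nothing. Match emissions are
`(weighted counts + α·background) / (total + α)` with a single background-
mixture pseudocount `α = 0.5` (Dirichlet mixtures are deliberately out of
scope); transitions use the same scheme with a uniform prior over the targets
available to each source state. The null model is a fixed Robinson–Robinson
amino-acid background; unknown residues (`X`) score as background (zero
log-odds) in every state.

**Scores.** The reported bit score is the *forward* log2-odds (sum over all
paths); alignment spans and coverages come from the Viterbi path, with ties
broken toward match states so tracebacks are deterministic. Forward ≥ Viterbi
by construction, and both are checked against an explicit path-enumeration
oracle on small models in the test suite. Dynamic programming runs in
natural-log space inside numba kernels.

**E-values.** The original system's E-value machinery is not specified
anywhere we could follow, so calibration is this package's own: `n_random`
(default 150, minimum 100) i.i.d. background sequences of the profile's mean
training length are scored, a Gumbel is fitted by maximum likelihood
(`scipy.stats.gumbel_r.fit`), and `E(s) = db_size · P(S ≥ s)` under the fit.
`db_size` is the number of profiles scored in the current stage (the number
of families in stage 1, the number of tree nodes in stage 2) — a per-search
multiplicity correction. Degenerate score distributions raise a calibration
error rather than returning a fit.

## Tree operations

* **Identity cut (Kerf-style).** Top-down: accept a clade iff its minimum
  pairwise leaf identity (identical residues over co-occupied alignment
  columns) reaches the threshold (default 0.70), else recurse. This yields
  the unique partition into maximal subtrees satisfying the floor.
* **Duplication inference.** Species overlap: an internal node is a
  duplication iff at least two child subtrees share a taxon. This exactly
  reproduces the conservative super-ortholog endpoint (tree-distance
  threshold zero); general positive-threshold variants are out of scope.
* **Super-ortholog groups.** Maximal clades containing no duplication node;
  they partition the leaves and never repeat a taxon within a group.
* **Bracketing of external labels.** A subtree is consistent with one
  external orthology group iff all its labeled leaves carry a single group
  and at least two children each contain a labeled member; unlabeled leaves
  are carried along. "At least two children" is the polytomy-safe
  generalization of the left/right-child requirement. Maximal such subtrees
  per source are reported; they are pairwise disjoint.
* **Enclosing clade.** The largest supported clade containing the placement
  node wins; ties break by source priority (bracket > super-ortholog >
  identity cut), then node id. With no containing support the placement node
  itself is returned flagged `none`, and the preset decides admissibility.

Trees must be rooted; an input whose root has more than two children is
treated as unrooted and midpoint-rooted with a logged warning.

## Stage-3 alignments and clustering

Pairwise alignments use Biopython's `PairwiseAligner` with BLOSUM62, gap
open −11 / extend −1. Modes per preset: `global` (high precision; end gaps
penalized on both sequences), `glocal_query` (default and partial-sequence;
subject end overhangs free), `local` (remote homolog). Percent identity is
identical pairs over aligned pairs; coverages are aligned residues over each
sequence's length. Same-genome clustering is single linkage at row identity
≥ `intra_identity_min` (default 0.97 — isoforms and redundant gene models
are near-identical; no value is published, this is a package default).
Representatives prefer curated-tier sequences, then identity to the query,
then the smallest identifier.

The fast bypass ranks clade members by shared distinct k-tuples (default
k = 4), keeps the `fastcat_top_n` best, and prunes further to the smallest
query-containing subtree (≥ 5 members by default) of a neighbor-joining tree
over `d = −ln(identity)` distances (capped at 5). Member–member identities
come from the family alignment and query–member identities from pairwise
alignment — self-contained substitutes for the external aligner/tree tools a
server would shell out to. When `fastcat_top_n` covers the whole clade the
bypass is the identity on membership, so the fast and full pipelines return
identical ortholog sets in that regime (asserted in the tests).

## Annotation weighting

`weight = tier_weight(evidence) · identity²` with tier weights experimental
1.0, curated 0.8, computational 0.3. Identity to the query is used as the
distance proxy because the query is not a leaf of the family tree, so no
patristic distance to it exists; identity is always available from stage 3.
Confidence of a value is its summed weight over the total weight of all
competing values of the same kind, so confidences per kind sum to one.
Descriptions are compared case-folded and whitespace-normalized; no synonym
resolution, GO-graph propagation or EC hierarchy logic is attempted.

## Preset parameter values

The published description names the four presets and their intent but the
numeric thresholds live in supplementary material not reproduced here; the
values in `config.py` are this package's own defaults chosen to realize the
stated intents (high recall: E ≤ 1e-3, coverage ≥ 0.5, identity ≥ 0.30;
high precision: E ≤ 1e-5, coverage ≥ 0.8, identity ≥ 0.60, orthology support
required; remote homolog: E ≤ 1.0, coverage ≥ 0.3, identity ≥ 0.15; partial
sequence: query coverage unconstrained, subject coverage ≥ 0.5). They are
mutually nested so that the ortholog sets of high_precision ⊆ high_recall ⊆
remote_homolog on any fixed input — a property the tests assert. Every value
is user-overridable.

## The simulator: what the stated world is

Each family is a gene tree generated top-down over `n_taxa = 10` genomes:
with probability `duplication_prob = 0.2` a node (holding ≥ 2 available
taxa) duplicates and both children inherit the full taxon set; otherwise it
speciates and the taxon set is partitioned disjointly. Leaves appear at
singleton taxon sets. Consequently species overlap recovers exactly the
flagged duplications, and the true orthology groups are the maximal
duplication-free clades — the generator asserts this equivalence. Topologies
are redrawn until the leaf count lands in 12–32 and every group has at least
two members (so a held-out sequence always leaves a witness of its group).

Sequences (120 residues) evolve from a random ancestral sequence with
Poisson-like per-site substitution `p = 1 − exp(−t)`, each substitution
uniform over the other 19 residues — identity targets, not biochemical
realism, drive the benchmark. Edges inside groups are short, backbone edges
long, and each class has a global scale tuned by bisection until the minimum
within-group identity is ≥ 0.70 (aimed at a 0.73–0.88 band) and the maximum
between-group identity ≤ 0.50; unattainable targets raise a generation error
after bounded retries. No indels are simulated, so rows are born aligned.
Two partial label sources (80% coverage each) subsample the truth to
exercise bracketing; annotations share a description per group with a mixed
evidence-tier profile.

What a green benchmark therefore establishes: that exhaustive subtree-HMM
scoring places held-out sequences inside duplication-delimited groups when
within-group identity comfortably exceeds between-group identity. What it
does not establish: robustness to alignment error, indels/partial sequences,
rate heterogeneity, promiscuous domains, or tree-estimation error — real
libraries have all of these and the published 83-family experiment drew on
curated database families we cannot reconstruct.

## Leave-one-out benchmark

For every family and every sequence: drop the row, prune the leaf (merging
branch lengths through suppressed degree-one nodes), recompute the match
mask, rebuild all node profiles, and classify the held-out sequence with the
default high-recall settings. A classification is correct iff the top node's
leaf set is a subset of the held-out sequence's true group; precision is
measured over stage-2-passing placements only, and zero passing placements
report precision as undefined rather than zero. A permuted-labels control
(shuffling group labels within each family) must strictly reduce precision.
The default benchmark (20 families) runs in a few minutes on one CPU; the
published experiment used 83 curated families, so this is a deliberately
scaled-down twin.

## Determinism

All randomness flows through `numpy.random.default_rng` seeded from explicit
arguments (per-family calibration seeds are derived via CRC32 of stable
identifiers). Same seed, same inputs → byte-identical simulated libraries
and byte-identical JSON reports. Viterbi ties prefer match states; placement
ties prefer fewer leaves, then the smallest node id; representative and
status ties prefer curated sequences, then identifiers.
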