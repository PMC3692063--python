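"""Independent brute-force oracles shared by the unit and acceptance tests.

Everything here is deliberately naive — exhaustive enumeration or direct
set computation — and independent of the package's implementation paths.
"""

from __future__ import annotations

import math

import numpy as np

from orthoplace.msa import encode_residues
from orthoplace.trees import PhyloTree, TreeNode

MM, MI, MD, IM, II, ID, DM, DD, DI = range(9)


# ---------------------------------------------------------------------------
# random rooted trees
# ---------------------------------------------------------------------------

def random_tree(rng: np.random.Generator, leaf_ids: list[str]) -> PhyloTree:
    """Random rooted binary topology over the given leaves."""
    nodes = [TreeNode(seq_id=s, length=float(rng.uniform(0.1, 1.0))) for s in leaf_ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=float(rng.uniform(0.1, 1.0)))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)]
        nodes.append(parent)
    return PhyloTree(nodes[0])


# ---------------------------------------------------------------------------
# tree-operation oracles (direct evaluation at every node)
# ---------------------------------------------------------------------------

def oracle_duplications(tree: PhyloTree, taxon_of: dict[str, str]) -> set[str]:
    """Species-overlap check evaluated independently at every internal node."""
    dups = set()
    for node in tree.internal_nodes():
        child_taxa = [
            {taxon_of[s] for s in tree.leaves_under(c.node_id)} for c in node.children
        ]
        for i in range(len(child_taxa)):
            for j in range(i + 1, len(child_taxa)):
                if child_taxa[i] & child_taxa[j]:
                    dups.add(node.node_id)
    return dups


def oracle_phog_groups(tree: PhyloTree, dups: set[str]) -> set[frozenset[str]]:
    """Maximal clades containing no duplication node, by exhaustive search."""
    def contains_dup(node) -> bool:
        return node.node_id in dups or any(contains_dup(c) for c in node.children)

    groups = set()
    for node in tree.preorder():
        if contains_dup(node):
            continue
        # maximal iff the parent clade (if any) is impure
        if node.parent is None or contains_dup(node.parent):
            groups.add(tree.leaves_under(node.node_id))
    return groups


def oracle_brackets(tree: PhyloTree, assignments: dict[str, str]) -> set[frozenset[str]]:
    """Evaluate both bracket criteria at every internal node, keep maximal ones."""
    def qualifies(node) -> bool:
        if node.is_leaf:
            return False
        labels = {
            assignments[s]
            for s in tree.leaves_under(node.node_id)
            if s in assignments
        }
        if len(labels) != 1:
            return False
        (g,) = labels
        n_children = sum(
            1
            for c in node.children
            if any(assignments.get(s) == g for s in tree.leaves_under(c.node_id))
        )
        return n_children >= 2

    passing = [n for n in tree.preorder() if qualifies(n)]
    out = set()
    for node in passing:
        anc, maximal = node.parent, True
        while anc is not None:
            if qualifies(anc):
                maximal = False
                break
            anc = anc.parent
        if maximal:
            out.add(tree.leaves_under(node.node_id))
    return out


def oracle_kerf_valid(tree: PhyloTree, identities, min_identity: float,
                      clades: list) -> bool:
    """Check partition, the identity floor, and maximality of a proposed cut."""
    leaf_set = set(tree.leaf_ids)
    covered: list[str] = []
    for clade in clades:
        members = sorted(clade.members)
        covered.extend(members)
        sub = identities.loc[members, members].to_numpy()
        if sub.min() < min_identity:
            return False
        node = tree.node(clade.node_id)
        if node.parent is not None:
            parent_members = sorted(tree.leaves_under(node.parent.node_id))
            sub = identities.loc[parent_members, parent_members].to_numpy()
            if sub.min() >= min_identity:
                return False  # the parent clade would also qualify: not maximal
    return sorted(covered) == sorted(leaf_set)


# ---------------------------------------------------------------------------
# profile-HMM forward oracle: explicit path enumeration
# ---------------------------------------------------------------------------

def enumerate_forward_bits(hmm, residues: str, mode: str) -> float:
    """Sum over every state path of the model (tiny models only)."""
    enc = encode_residues(residues)
    k = hmm.n_match
    L = len(enc)
    tr = hmm.transitions

    def em(j, i):
        a = enc[i]
        if a == 20:
            return 1.0
        return hmm.match_emissions[j - 1, a] / hmm.null_model[a]

    total = 0.0

    def step(j, state, i, prob):
        nonlocal total
        if mode == "local" and state == 0 and j >= 1:
            total += prob  # free exit right after a match emission
        if j == k:
            if mode == "glocal":
                total += prob
            return
        if i < L:
            t = tr[j, {0: MM, 1: IM, 2: DM}[state]]
            if t > 0:
                step(j + 1, 0, i + 1, prob * t * em(j + 1, i))
        t = tr[j, {0: MD, 1: ID, 2: DD}[state]]
        if t > 0:
            step(j + 1, 2, i, prob * t)
        if 1 <= j <= k - 1 and i < L:
            t = tr[j, {0: MI, 1: II, 2: DI}[state]]
            if t > 0:
                step(j, 1, i + 1, prob * t)

    for n_pre in range(L + 1):
        if mode == "glocal":
            step(0, 0, n_pre, 1.0)
        else:
            for j0 in range(1, k + 1):
                if n_pre < L:
                    step(j0, 0, n_pre + 1, (1.0 / k) * em(j0, n_pre))
    return math.log(total) / math.log(2.0)


# ---------------------------------------------------------------------------
# affine-gap alignment oracle: enumerate all alignments of two short strings
# ---------------------------------------------------------------------------

def enumerate_alignment_score(
    query: str,
    subject: str,
    matrix,
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
    mode: str = "global",
) -> float:
    """Optimal affine-gap score by exhaustive recursion (len <= ~6).

    ``mode`` matches the package's conventions: global (end gaps on both
    penalized), glocal_query (subject end overhangs free), local (best score
    over all substring pairs, floored at 0 pairs -> 0 handled by caller).
    """
    best = -math.inf

    def sub(a, b):
        return float(matrix[a, b])

    def gap_cost(n, terminal_subject):
        if n == 0:
            return 0.0
        if mode == "glocal_query" and terminal_subject:
            return 0.0
        return gap_open + gap_extend * (n - 1)

    if mode == "local":
        # enumerate all substring pairs, globally aligned without end gaps
        for qs in range(len(query)):
            for qe in range(qs + 1, len(query) + 1):
                for ss in range(len(subject)):
                    for se in range(ss + 1, len(subject) + 1):
                        s = enumerate_alignment_score(
                            query[qs:qe], subject[ss:se], matrix,
                            gap_open, gap_extend, "global",
                        )
                        best = max(best, s)
        return max(best, 0.0)

    def rec(i, j, score, state):
        # i over query, j over subject; state: 0 diag, 1 gap-in-query, 2 gap-in-subject
        nonlocal best
        if i == len(query) and j == len(subject):
            best = max(best, score)
            return
        if i < len(query) and j < len(subject):
            rec(i + 1, j + 1, score + sub(query[i], subject[j]), 0)
        if j < len(subject):  # subject residue unaligned (gap in query row)
            terminal = i == 0 or i == len(query)
            cost = (
                0.0
                if (mode == "glocal_query" and terminal)
                else (gap_extend if state == 1 else gap_open)
            )
            rec(i, j + 1, score + cost, 1)
        if i < len(query):  # query residue unaligned (gap in subject row)
            cost = gap_extend if state == 2 else gap_open
            rec(i + 1, j, score + cost, 2)

    rec(0, 0, 0.0, -1)
    return best


# ---------------------------------------------------------------------------
# single-linkage closure
# ---------------------------------------------------------------------------

def single_linkage_clusters(ids: list[str], edge) -> set[frozenset[str]]:
    """Transitive closure over ``edge(a, b)`` pairs (BFS)."""
    remaining = set(ids)
    out = set()
    while remaining:
        seed = min(remaining)
        cluster = {seed}
        frontier = [seed]
        while frontier:
            a = frontier.pop()
            for b in list(remaining - cluster):
                if edge(a, b):
                    cluster.add(b)
                    frontier.append(b)
        out.add(frozenset(cluster))
        remaining -= cluster
    return out
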