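"""Rooted gene-tree operations for orthology structure.

Provides the tree container plus the orthology decorations used to justify
extracting orthologs from a clade: identity-threshold tree cuts, duplication
inference by species overlap, super-ortholog (duplication-free) groups,
bracketing of partial third-party orthology labels, and resolution of the
enclosing clade around a placement node.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import pandas as pd

from .errors import LoadError

logger = logging.getLogger(__name__)

#: support-source priority when several supported clades tie on size
_SOURCE_PRIORITY = {"bracket": 0, "phog_t0": 1, "kerf": 2, "none": 3}


class TreeNode:
    __slots__ = ("node_id", "children", "parent", "length", "seq_id")

    def __init__(self, seq_id: str | None = None, length: float = 0.0):
        self.node_id: str | None = None
        self.children: list["TreeNode"] = []
        self.parent: "TreeNode | None" = None
        self.length = float(length)
        self.seq_id = seq_id

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child


class PhyloTree:
    """A rooted tree whose leaves carry sequence identifiers.

    Internal nodes get deterministic preorder identifiers ``n000, n001, ...``;
    leaf node identifiers equal their ``seq_id``.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._index: dict[str, TreeNode] = {}
        self._leaves_under: dict[str, frozenset[str]] = {}
        self._assign_ids()

    # -- construction -----------------------------------------------------
    def _assign_ids(self) -> None:
        self._index.clear()
        self._leaves_under.clear()
        counter = 0
        for node in self.preorder():
            if node.is_leaf:
                if not node.seq_id:
                    raise ValueError("leaf without seq_id")
                node.node_id = node.seq_id
            else:
                node.node_id = f"n{counter:03d}"
                counter += 1
            if node.node_id in self._index:
                raise ValueError(f"duplicate node id {node.node_id}")
            self._index[node.node_id] = node

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(data=text, schema="newick")
        except Exception as exc:  # dendropy raises several parse error types
            raise LoadError(f"cannot parse newick: {exc}") from exc
        seed = dtree.seed_node
        if len(seed.child_nodes()) > 2:
            logger.warning(
                "input tree looks unrooted (root with %d children); midpoint rooting",
                len(seed.child_nodes()),
            )
            dtree.reroot_at_midpoint(update_bipartitions=False)
        return cls(cls._convert(dtree.seed_node))

    @staticmethod
    def _convert(dnode) -> TreeNode:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label.replace(" ", "_")
        elif dnode.is_leaf() and dnode.label:
            label = dnode.label
        node = TreeNode(seq_id=label if not dnode.child_nodes() else None,
                        length=dnode.edge.length or 0.0)
        for child in dnode.child_nodes():
            node.add_child(PhyloTree._convert(child))
        return node

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                core = node.seq_id
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
            return f"{core}:{node.length:.6g}" if node.parent is not None else core
        return fmt(self.root) + ";"

    # -- traversal --------------------------------------------------------
    def preorder(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def postorder(self) -> list[TreeNode]:
        return list(reversed([n for n in self._postorder_rev()]))

    def _postorder_rev(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def leaf_ids(self) -> list[str]:
        return [n.seq_id for n in self.leaves()]

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.preorder() if not n.is_leaf]

    def node(self, node_id: str) -> TreeNode:
        return self._index[node_id]

    def leaves_under(self, node_id: str) -> frozenset[str]:
        if node_id not in self._leaves_under:
            node = self.node(node_id)
            out, stack = [], [node]
            while stack:
                n = stack.pop()
                if n.is_leaf:
                    out.append(n.seq_id)
                else:
                    stack.extend(n.children)
            self._leaves_under[node_id] = frozenset(out)
        return self._leaves_under[node_id]

    # -- editing ----------------------------------------------------------
    def copy(self) -> "PhyloTree":
        def clone(node: TreeNode) -> TreeNode:
            c = TreeNode(seq_id=node.seq_id, length=node.length)
            for child in node.children:
                c.add_child(clone(child))
            return c
        return PhyloTree(clone(self.root))

    def prune_leaf(self, seq_id: str) -> "PhyloTree":
        """A new tree without the given leaf; degree-one nodes are suppressed."""
        if seq_id not in self._index or not self.node(seq_id).is_leaf:
            raise KeyError(f"no leaf {seq_id!r}")
        if len(self.leaf_ids) < 2:
            raise ValueError("cannot prune the last leaf")
        new = self.copy()
        leaf = new.node(seq_id)
        parent = leaf.parent
        if parent is None:
            raise ValueError("cannot prune the root")
        parent.children.remove(leaf)
        while parent is not None and len(parent.children) == 1:
            only = parent.children[0]
            grand = parent.parent
            only.length += parent.length
            if grand is None:
                only.parent = None
                new.root = only
                if only.is_leaf:
                    raise ValueError("pruning left fewer than two leaves")
                break
            grand.children[grand.children.index(parent)] = only
            only.parent = grand
            parent = grand
        new._assign_ids()
        return new

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhyloTree):
            return NotImplemented
        return self.to_newick() == other.to_newick()


@dataclass(frozen=True)
class SupportedClade:
    """A clade backed by an orthology criterion; members are its leaf set."""

    node_id: str
    sources: frozenset[str]
    members: frozenset[str]


@dataclass(frozen=True)
class EnclosingClade:
    """The orthology-supported clade that contains a placement node."""

    node_id: str
    sources: frozenset[str]
    members: frozenset[str]
    top_node_id: str


def kerf_cut(
    tree: PhyloTree, identities: pd.DataFrame, min_identity: float
) -> list[SupportedClade]:
    """Cut the tree into maximal subtrees whose leaves all share ``min_identity``.

    Top-down: a clade is accepted iff its minimum pairwise leaf identity
    reaches the threshold, otherwise its children are examined; every leaf
    ends up in exactly one clade (singletons allowed).
    """
    if not (0 < min_identity <= 1):
        raise ValueError("min_identity must be in (0, 1]")
    out: list[SupportedClade] = []

    def min_ident(leaf_ids: list[str]) -> float:
        if len(leaf_ids) == 1:
            return 1.0
        sub = identities.loc[leaf_ids, leaf_ids].to_numpy()
        return float(sub.min())

    def visit(node: TreeNode) -> None:
        leaf_ids = sorted(tree.leaves_under(node.node_id))
        if min_ident(leaf_ids) >= min_identity:
            out.append(
                SupportedClade(node.node_id, frozenset({"kerf"}), frozenset(leaf_ids))
            )
            return
        for child in node.children:
            visit(child)

    visit(tree.root)
    return out


def infer_duplication_nodes(tree: PhyloTree, taxon_of: dict[str, str]) -> set[str]:
    """Species-overlap duplication inference.

    An internal node is a duplication iff at least two of its child subtrees
    share at least one taxon.
    """
    missing = [s for s in tree.leaf_ids if s not in taxon_of]
    if missing:
        raise ValueError(f"leaves without taxon: {missing}")
    dups: set[str] = set()
    taxa_below: dict[str, set[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            taxa_below[node.node_id] = {taxon_of[node.seq_id]}
            continue
        child_sets = [taxa_below[c.node_id] for c in node.children]
        merged: set[str] = set()
        overlap = False
        for cs in child_sets:
            if merged & cs:
                overlap = True
            merged |= cs
        taxa_below[node.node_id] = merged
        if overlap:
            dups.add(node.node_id)
    return dups


def phog_t0_groups(
    tree: PhyloTree, taxon_of: dict[str, str], duplications: set[str] | None = None
) -> list[SupportedClade]:
    """Maximal duplication-free clades: conservative super-ortholog groups.

    Within a returned group every pair of sequences is separated only by
    speciation events, so all members are predicted mutual orthologs.
    """
    if duplications is None:
        duplications = infer_duplication_nodes(tree, taxon_of)
    impure: dict[str, bool] = {}
    for node in tree.postorder():
        if node.is_leaf:
            impure[node.node_id] = False
        else:
            impure[node.node_id] = node.node_id in duplications or any(
                impure[c.node_id] for c in node.children
            )
    out: list[SupportedClade] = []

    def visit(node: TreeNode) -> None:
        if not impure[node.node_id]:
            out.append(
                SupportedClade(
                    node.node_id,
                    frozenset({"phog_t0"}),
                    tree.leaves_under(node.node_id),
                )
            )
            return
        for child in node.children:
            visit(child)

    visit(tree.root)
    return out


def subtree_bracket(tree: PhyloTree, labeling) -> list[SupportedClade]:
    """Maximal subtrees consistent with one external orthology group.

    A subtree qualifies iff (a) every labeled leaf below it belongs to a single
    group of the labeling, and (b) at least two of its children each contain a
    leaf labeled with that group (unlabeled leaves are carried along). The
    two-children criterion is the polytomy-safe reading of requiring labeled
    members in both the left and right child.
    """
    assignments: dict[str, str] = labeling.assignments
    groups_below: dict[str, set[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            g = assignments.get(node.seq_id)
            groups_below[node.node_id] = {g} if g is not None else set()
        else:
            s: set[str] = set()
            for c in node.children:
                s |= groups_below[c.node_id]
            groups_below[node.node_id] = s

    def qualifies(node: TreeNode) -> bool:
        if node.is_leaf:
            return False
        gb = groups_below[node.node_id]
        if len(gb) != 1:
            return False
        (g,) = gb
        with_label = sum(1 for c in node.children if g in groups_below[c.node_id])
        return with_label >= 2

    out: list[SupportedClade] = []

    def visit(node: TreeNode) -> None:
        if qualifies(node):
            (g,) = groups_below[node.node_id]
            out.append(
                SupportedClade(
                    node.node_id,
                    frozenset({f"bracket:{labeling.source_name}"}),
                    tree.leaves_under(node.node_id),
                )
            )
            return
        for child in node.children:
            if not child.is_leaf:
                visit(child)

    visit(tree.root)
    return out


def _priority(sources: frozenset[str]) -> int:
    best = _SOURCE_PRIORITY["none"]
    for s in sources:
        key = "bracket" if s.startswith("bracket:") else s
        best = min(best, _SOURCE_PRIORITY.get(key, _SOURCE_PRIORITY["none"]))
    return best


def resolve_enclosing_clade(
    tree: PhyloTree, top_node_id: str, supports: list[SupportedClade]
) -> EnclosingClade:
    """Largest supported clade containing the placement node.

    Falls back to the placement node itself, flagged ``none``, when no
    supported clade contains it; whether an unsupported clade is admissible
    is a downstream preset decision. Ties on size are broken by source
    priority (bracket > super-ortholog > identity cut), then node id.
    """
    target = tree.leaves_under(top_node_id)
    containing = [c for c in supports if target <= c.members]
    if not containing:
        return EnclosingClade(
            node_id=top_node_id,
            sources=frozenset({"none"}),
            members=target,
            top_node_id=top_node_id,
        )
    # merge sources of clades sharing the same node
    by_node: dict[str, set[str]] = {}
    for c in containing:
        by_node.setdefault(c.node_id, set()).update(c.sources)
    best = min(
        by_node,
        key=lambda nid: (
            -len(tree.leaves_under(nid)),
            _priority(frozenset(by_node[nid])),
            nid,
        ),
    )
    return EnclosingClade(
        node_id=best,
        sources=frozenset(by_node[best]),
        members=tree.leaves_under(best),
        top_node_id=top_node_id,
    )


def family_supported_clades(family, config) -> list[SupportedClade]:
    """All supported clades of a family: identity cuts, super-ortholog groups,
    and one bracket set per attached orthology labeling."""
    from .msa import pairwise_identity_matrix

    identities = pairwise_identity_matrix(family.alignment)
    taxon_of = family.taxon_of
    supports = list(kerf_cut(family.tree, identities, config.kerf_threshold))
    supports += phog_t0_groups(family.tree, taxon_of)
    for labeling in family.labelings:
        supports += subtree_bracket(family.tree, labeling)
    return supports
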