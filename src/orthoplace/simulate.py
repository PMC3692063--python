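"""Seeded simulator of protein families with known orthology ground truth.

Each family is a duplication-bearing gene tree plus aligned sequences evolved
down it. Topology generation guarantees that the species-overlap rule recovers
exactly the flagged duplications: at a speciation node the available taxon set
is partitioned disjointly between the children, while at a duplication node
both children inherit the full set, so sister subtrees repeat taxa. The true
orthology groups are the maximal duplication-free clades.

Branch lengths come in two classes — short edges inside orthology groups and
long edges on the duplication backbone — and each class has a global scale
factor tuned by bisection so that within-group identities stay above and
between-group identities below the configured targets. Substitutions replace
a residue with one of the other 19 uniformly; no indels are simulated, so the
rows are born aligned and every column is a match column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import GenerationError
from .io import (
    AnnotationRecord,
    Family,
    OrthologyLabeling,
    SequenceRecord,
    write_library,
)
from .msa import AMINO_ACIDS, BACKGROUND, FamilyAlignment
from .trees import PhyloTree, TreeNode, infer_duplication_nodes, phog_t0_groups


@dataclass
class SimulationConfig:
    n_families: int = 20
    leaves_range: tuple[int, int] = (12, 32)
    n_taxa: int = 10
    duplication_prob: float = 0.2
    seq_length: int = 120
    within_group_identity_min: float = 0.70
    between_group_identity_max: float = 0.50
    tier_mix: dict[str, float] = field(
        default_factory=lambda: {
            "experimental": 0.2,
            "curated": 0.3,
            "computational": 0.5,
        }
    )
    label_coverage: float = 0.8
    curated_fraction: float = 0.3
    annotation_prob: float = 0.9
    seed: int = 0
    max_retries: int = 60

    def __post_init__(self) -> None:
        lo, hi = self.leaves_range
        if not (1 <= lo <= hi):
            raise ValueError("leaves_range must be a non-degenerate range")
        if not (0.0 <= self.duplication_prob <= 1.0):
            raise ValueError("duplication_prob must be in [0, 1]")
        if abs(sum(self.tier_mix.values()) - 1.0) > 1e-9:
            raise ValueError("tier_mix must sum to 1")


class _SimNode(TreeNode):
    __slots__ = ("is_duplication", "taxa")

    def __init__(self, seq_id=None, length=0.0):
        super().__init__(seq_id=seq_id, length=length)
        self.is_duplication = False
        self.taxa: tuple[str, ...] = ()


def _gen_topology(rng: np.random.Generator, taxa: list[str], dup_prob: float) -> _SimNode:
    node = _SimNode()
    node.taxa = tuple(taxa)
    if len(taxa) >= 2 and rng.random() < dup_prob:
        node.is_duplication = True
        node.add_child(_gen_topology(rng, taxa, dup_prob))
        node.add_child(_gen_topology(rng, taxa, dup_prob))
        return node
    if len(taxa) == 1:
        node.seq_id = "pending"  # filled in once leaves are numbered
        return node
    shuffled = list(taxa)
    rng.shuffle(shuffled)
    cut = int(rng.integers(1, len(shuffled)))
    node.add_child(_gen_topology(rng, shuffled[:cut], dup_prob))
    node.add_child(_gen_topology(rng, shuffled[cut:], dup_prob))
    return node


def _collect(node: _SimNode):
    yield node
    for c in node.children:
        yield from _collect(c)


def _mark_pure(node: _SimNode, purity: dict[int, bool]) -> bool:
    child_pure = [_mark_pure(c, purity) for c in node.children]
    pure = not node.is_duplication and all(child_pure)
    purity[id(node)] = pure
    return pure


def _true_groups(root: _SimNode, purity: dict[int, bool]) -> dict[int, int]:
    """Map node-object-id -> group index for the maximal duplication-free clades."""
    groups: dict[int, int] = {}
    counter = [0]

    def visit(node: _SimNode, current: int | None):
        if current is None and purity[id(node)]:
            current = counter[0]
            counter[0] += 1
        if node.is_leaf:
            groups[id(node)] = current
            return
        for c in node.children:
            visit(c, current)

    visit(root, None)
    return groups


def _evolve(root: _SimNode, length: int, s_short: float, s_long: float,
            short_edge: dict[int, bool], rng: np.random.Generator) -> dict[int, np.ndarray]:
    seqs: dict[int, np.ndarray] = {}
    root_seq = rng.choice(20, size=length, p=BACKGROUND)

    def down(node: _SimNode, seq: np.ndarray):
        seqs[id(node)] = seq
        for c in node.children:
            scale = s_short if short_edge[id(c)] else s_long
            t = c.length * scale
            p = 1.0 - math.exp(-t)
            child_seq = seq.copy()
            hit = rng.random(length) < p
            n_hit = int(hit.sum())
            if n_hit:
                child_seq[hit] = (
                    child_seq[hit] + 1 + rng.integers(0, 19, size=n_hit)
                ) % 20
            down(c, child_seq)

    down(root, root_seq)
    return seqs


def _identity(a: np.ndarray, b: np.ndarray) -> float:
    return float((a == b).mean())


def simulate_family(
    config: SimulationConfig, family_index: int
) -> tuple[Family, dict[str, str]]:
    """One simulated family plus its ground-truth seq_id -> group_id map."""
    family_id = f"fam{family_index:03d}"
    taxa = [f"tax{i:02d}" for i in range(config.n_taxa)]
    lo, hi = config.leaves_range
    for attempt in range(config.max_retries):
        rng = np.random.default_rng(
            [config.seed % (2**31), family_index, attempt]
        )
        root = _gen_topology(rng, taxa, config.duplication_prob)
        leaves = [n for n in _collect(root) if n.is_leaf]
        if not (lo <= len(leaves) <= hi):
            continue
        purity: dict[int, bool] = {}
        _mark_pure(root, purity)
        group_of_node = _true_groups(root, purity)

        # name leaves: fam_tax_serial, serial by preorder appearance per taxon
        serial: dict[str, int] = {}
        for leaf in leaves:
            taxon = leaf.taxa[0]
            serial[taxon] = serial.get(taxon, 0) + 1
            leaf.seq_id = f"{family_id}_{taxon}_{serial[taxon]}"

        # base branch lengths; an edge is short iff its parent node is pure
        short_edge: dict[int, bool] = {}
        for node in _collect(root):
            for c in node.children:
                short_edge[id(c)] = purity[id(node)]
                c.length = (
                    rng.uniform(0.02, 0.06) if short_edge[id(c)]
                    else rng.uniform(1.0, 2.0)
                )
        short_edge[id(root)] = False

        groups_members: dict[int, list[_SimNode]] = {}
        for leaf in leaves:
            groups_members.setdefault(group_of_node[id(leaf)], []).append(leaf)
        # every group needs at least two members so that holding one sequence
        # out always leaves a witness of its group in the tree
        if any(len(m) < 2 for m in groups_members.values()):
            continue

        def measure(s_short: float, s_long: float, eval_idx: int):
            ev_rng = np.random.default_rng(
                [config.seed % (2**31), family_index, attempt, eval_idx]
            )
            seqs = _evolve(
                root, config.seq_length, s_short, s_long, short_edge, ev_rng
            )
            within = 1.0
            for members in groups_members.values():
                for i, a in enumerate(members):
                    for b in members[i + 1:]:
                        within = min(within, _identity(seqs[id(a)], seqs[id(b)]))
            between = 0.0
            group_list = list(groups_members.values())
            for gi, ga in enumerate(group_list):
                for gb in group_list[gi + 1:]:
                    for a in ga:
                        for b in gb:
                            between = max(between, _identity(seqs[id(a)], seqs[id(b)]))
            return seqs, within, between

        # tune the within-group scale: min within identity into a band above
        # the floor so the constraint holds with margin
        target_lo = config.within_group_identity_min + 0.03
        target_hi = min(0.97, config.within_group_identity_min + 0.18)
        s_short, step = 1.0, 0
        ok_short = False
        for step in range(25):
            _, within, _ = measure(s_short, 1.0, step)
            if within < target_lo:
                s_short *= 0.6
            elif within > target_hi:
                s_short *= 1.5
            else:
                ok_short = True
                break
        if not ok_short:
            continue
        # tune the backbone scale: max between identity at or under the cap
        cap = config.between_group_identity_max - 0.03
        s_long = 1.0
        ok_long = len(groups_members) == 1
        final = None
        for step2 in range(25):
            seqs, within, between = measure(s_short, s_long, 100 + step2)
            if len(groups_members) == 1:
                final = seqs
                ok_long = within >= config.within_group_identity_min
                break
            if between > cap:
                s_long *= 1.6
            elif between < 0.05:
                s_long *= 0.7
            else:
                ok_long = (
                    within >= config.within_group_identity_min
                    and between <= config.between_group_identity_max
                )
                final = seqs
                break
        if not ok_long or final is None:
            continue

        return _assemble_family(
            config, family_id, root, leaves, group_of_node, final, rng
        )
    raise GenerationError(
        f"{family_id}: could not meet identity targets in "
        f"{config.max_retries} attempts"
    )


def _assemble_family(config, family_id, root, leaves, group_of_node, seqs, rng):
    row_ids, rows, sequences = [], [], {}
    truth: dict[str, str] = {}
    for leaf in leaves:
        seq = "".join(AMINO_ACIDS[i] for i in seqs[id(leaf)])
        row_ids.append(leaf.seq_id)
        rows.append(seq)
        tier = "curated" if rng.random() < config.curated_fraction else "automatic"
        sequences[leaf.seq_id] = SequenceRecord(
            seq_id=leaf.seq_id,
            residues=seq,
            taxon_id=leaf.taxa[0],
            curation_tier=tier,
        )
        truth[leaf.seq_id] = f"G{group_of_node[id(leaf)]}"
    alignment = FamilyAlignment(row_ids, rows)
    tree = PhyloTree(root)

    labelings = []
    for source in ("oma_sim", "orthomcl_sim"):
        assignments = {
            s: truth[s] for s in row_ids if rng.random() < config.label_coverage
        }
        labelings.append(OrthologyLabeling(source, assignments))

    tiers = sorted(config.tier_mix)
    tier_p = np.array([config.tier_mix[t] for t in tiers])
    tier_p = tier_p / tier_p.sum()
    annotations = []
    for seq_id in row_ids:
        group = truth[seq_id]
        if rng.random() < config.annotation_prob:
            evidence = tiers[int(rng.choice(len(tiers), p=tier_p))]
            annotations.append(
                AnnotationRecord(
                    seq_id,
                    "description",
                    f"{family_id} {group} family protein",
                    evidence,
                )
            )
        if rng.random() < 0.6:
            evidence = tiers[int(rng.choice(len(tiers), p=tier_p))]
            gid = 10000 + int(group[1:])
            annotations.append(
                AnnotationRecord(seq_id, "go_term", f"GO:{gid:07d}", evidence)
            )

    family = Family(
        family_id=family_id,
        alignment=alignment,
        tree=tree,
        family_type="mda",
        labelings=labelings,
        annotations=annotations,
        sequences=sequences,
    )
    return family, truth


def simulate_library(
    config: SimulationConfig,
) -> tuple[list[Family], dict[str, dict[str, str]]]:
    """All families of a benchmark library plus truth maps keyed by family id."""
    families, truth = [], {}
    for i in range(config.n_families):
        family, groups = simulate_family(config, i)
        families.append(family)
        truth[family.family_id] = groups
    return families, truth


def write_simulated_library(
    config: SimulationConfig, out_dir: str | Path
) -> tuple[list[Family], dict[str, dict[str, str]]]:
    """Simulate and persist a library; truth goes to ``<family>/truth.tsv``."""
    families, truth = simulate_library(config)
    out_dir = Path(out_dir)
    write_library(families, out_dir)
    for family in families:
        path = out_dir / family.family_id / "truth.tsv"
        with open(path, "w") as fh:
            fh.write("# seq_id\tgroup_id\n")
            for seq_id in sorted(truth[family.family_id]):
                fh.write(f"{seq_id}\t{truth[family.family_id][seq_id]}\n")
    return families, truth


def read_truth(library_dir: str | Path) -> dict[str, dict[str, str]]:
    out: dict[str, dict[str, str]] = {}
    for path in sorted(Path(library_dir).glob("*/truth.tsv")):
        groups: dict[str, str] = {}
        for line in path.read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            seq_id, group = line.split("\t")
            groups[seq_id] = group
        out[path.parent.name] = groups
    return out


def sanity_check_truth(family: Family, truth: dict[str, str]) -> bool:
    """Ground-truth groups must coincide with the super-ortholog groups of the
    true tree (a cross-module consistency oracle for the generator)."""
    dups = infer_duplication_nodes(family.tree, family.taxon_of)
    groups = phog_t0_groups(family.tree, family.taxon_of, dups)
    inferred = {frozenset(g.members) for g in groups}
    true_sets = {}
    for seq_id, g in truth.items():
        true_sets.setdefault(g, set()).add(seq_id)
    return inferred == {frozenset(s) for s in true_sets.values()}
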