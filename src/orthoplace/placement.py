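"""Stages 1-2: family-root profile scan and exhaustive subtree placement.

Stage 1 scores the query against the profile at the root of every family tree
and keeps families passing the E-value and coverage gates. Stage 2 then
scores the query against the profile of *every* node of a passing family's
tree — internal nodes and leaves alike, all sharing the family match mask —
and classifies the query to the top-scoring node. The placement is qualified
by E-value, alignment-coverage and (optionally) orthology-support criteria;
failures are recorded as reasons, not raised.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

from .config import PresetConfig
from .errors import ConfigurationError, FamilySkip
from .hmm import HMMScore, ProfileHMM, build_profile_hmm, calibrate_evalue, forward_bits, score_sequence
from .io import Family, OrthologyLabeling, SequenceRecord
from .msa import select_match_columns
from .trees import SupportedClade, family_supported_clades


@dataclass
class SubtreePlacement:
    family_id: str
    top_node_id: str
    score: HMMScore
    passes_stage2: bool
    failure_reasons: list[str] = field(default_factory=list)
    top_leaves: frozenset[str] = frozenset()
    n_nodes_scored: int = 0

    def __post_init__(self) -> None:
        assert self.passes_stage2 == (not self.failure_reasons)


def scoring_mode(family: Family) -> str:
    """Whole-protein families are scored glocally, domain families locally."""
    return "glocal" if family.family_type == "mda" else "local"


def _derived_seed(seed: int, *parts: str) -> int:
    h = zlib.crc32("|".join(parts).encode())
    return (int(seed) * 1_000_003 + h) % (2**31 - 1)


def ensure_match_mask(family: Family, config: PresetConfig) -> None:
    if family.alignment.match_mask is None:
        family.alignment.match_mask = select_match_columns(
            family.alignment, config.occupancy_min
        )


def build_node_hmms(
    family: Family, config: PresetConfig
) -> dict[str, ProfileHMM]:
    """One profile per tree node (leaves included), all on the family mask."""
    ensure_match_mask(family, config)
    out: dict[str, ProfileHMM] = {}
    for node in family.tree.preorder():
        rows = sorted(family.tree.leaves_under(node.node_id))
        out[node.node_id] = build_profile_hmm(
            family.alignment, rows, config.pseudocount_alpha
        )
    return out


def stage1_family_scan(
    query: SequenceRecord,
    library: list[Family],
    config: PresetConfig,
    seed: int = 0,
    root_hmms: dict[str, ProfileHMM] | None = None,
) -> list[tuple[str, HMMScore]]:
    """Families whose root profile clears the stage-1 gates, by E-value.

    Root profiles are calibrated against ``len(library)`` as the search-space
    size; pre-calibrated profiles (from a built library index) are reused.
    """
    if not library:
        raise ConfigurationError("empty family library")
    results = []
    for family in library:
        ensure_match_mask(family, config)
        if root_hmms is not None and family.family_id in root_hmms:
            hmm = root_hmms[family.family_id]
        else:
            hmm = build_profile_hmm(
                family.alignment, None, config.pseudocount_alpha
            )
        mode = scoring_mode(family)
        if not hmm.calibrated:
            calibrate_evalue(
                hmm,
                n_random=config.calib_n_random,
                seed=_derived_seed(seed, "stage1", family.family_id),
                db_size=len(library),
                mode=mode,
            )
        score = score_sequence(hmm, query.residues, mode, db_size=len(library))
        if (
            score.e_value <= config.stage1_evalue_max
            and score.query_coverage >= config.stage1_query_coverage_min
        ):
            results.append((family.family_id, score))
    results.sort(key=lambda fs: (fs[1].e_value, fs[0]))
    return results


def stage2_place(
    query: SequenceRecord,
    family: Family,
    config: PresetConfig,
    seed: int = 0,
    node_hmms: dict[str, ProfileHMM] | None = None,
    supports: list[SupportedClade] | None = None,
) -> SubtreePlacement:
    """Exhaustive subtree scoring and qualification of the top node.

    The top node maximizes the forward bit score; ties prefer the most
    specific placement (fewest leaves), then the smallest node id. Branch
    lengths play no role — only subtree memberships do.
    """
    if node_hmms is None:
        node_hmms = build_node_hmms(family, config)
    mode = scoring_mode(family)
    best_id = None
    best_key = None
    for node in family.tree.preorder():
        hmm = node_hmms[node.node_id]
        bits = forward_bits(hmm, query.residues, mode)
        leaves = family.tree.leaves_under(node.node_id)
        key = (-bits, len(leaves), node.node_id)
        if best_key is None or key < best_key:
            best_key = key
            best_id = node.node_id
    n_nodes = len(node_hmms)
    top_hmm = node_hmms[best_id]
    if not top_hmm.calibrated:
        calibrate_evalue(
            top_hmm,
            n_random=config.calib_n_random,
            seed=_derived_seed(seed, "stage2", family.family_id, best_id),
            db_size=n_nodes,
            mode=mode,
        )
    score = score_sequence(top_hmm, query.residues, mode, db_size=n_nodes)

    reasons = []
    if score.e_value > config.stage2_evalue_max:
        reasons.append("stage2_evalue")
    if score.query_coverage < config.stage2_query_coverage_min:
        reasons.append("stage2_query_coverage")
    if score.model_coverage < config.stage2_model_coverage_min:
        reasons.append("stage2_model_coverage")
    if config.require_orthology_support:
        if supports is None:
            supports = family_supported_clades(family, config)
        top_leaves = family.tree.leaves_under(best_id)
        if not any(top_leaves <= c.members for c in supports):
            reasons.append("orthology_support")
    return SubtreePlacement(
        family_id=family.family_id,
        top_node_id=best_id,
        score=score,
        passes_stage2=not reasons,
        failure_reasons=reasons,
        top_leaves=family.tree.leaves_under(best_id),
        n_nodes_scored=n_nodes,
    )


def prune_family(family: Family, held_out: str) -> Family:
    """The family without one sequence: leaf pruned, row dropped, labels filtered."""
    if held_out not in family.alignment.row_ids:
        raise KeyError(f"{held_out} not in family {family.family_id}")
    if len(family.alignment.row_ids) < 3:
        raise FamilySkip(
            f"family {family.family_id} too small to hold out a sequence"
        )
    keep = [r for r in family.alignment.row_ids if r != held_out]
    alignment = family.alignment.subset(keep)
    tree = family.tree.prune_leaf(held_out)
    labelings = [
        OrthologyLabeling(
            lab.source_name,
            {s: g for s, g in lab.assignments.items() if s != held_out},
        )
        for lab in family.labelings
    ]
    annotations = [a for a in family.annotations if a.seq_id != held_out]
    sequences = {s: r for s, r in family.sequences.items() if s != held_out}
    return Family(
        family_id=family.family_id,
        alignment=alignment,
        tree=tree,
        family_type=family.family_type,
        labelings=labelings,
        annotations=annotations,
        sequences=sequences,
    )


def leave_one_out_placement(
    family: Family,
    held_out: str,
    config: PresetConfig,
    truth_groups: dict[str, str] | None = None,
    seed: int = 0,
) -> tuple[SubtreePlacement, bool | None]:
    """Hold one sequence out, rebuild the subtree profiles, classify it back.

    The placement is correct when the top node's leaf set lies entirely inside
    the held-out sequence's true orthology group. Returns correctness ``None``
    when no ground truth is supplied.
    """
    pruned = prune_family(family, held_out)
    query = SequenceRecord(
        seq_id=held_out,
        residues=family.sequences[held_out].residues,
        taxon_id=family.sequences[held_out].taxon_id,
    )
    placement = stage2_place(query, pruned, config, seed=seed)
    correct = None
    if truth_groups is not None:
        group = truth_groups[held_out]
        members = {s for s, g in truth_groups.items() if g == group} - {held_out}
        correct = bool(placement.top_leaves) and placement.top_leaves <= members
    return placement, correct
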