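"""End-to-end orchestration: library building and the four-stage pipeline.

``build_library`` precomputes, per family, the shared match mask, the profile
at every tree node, the calibrated family-root profile, and the orthology
supports (identity cuts, super-ortholog groups, label brackets), keyed by a
content hash so an unchanged library rebuilds to bit-identical models.

``run_pipeline`` then takes a validated query through family scanning,
subtree placement, ortholog extraction (with the optional fast bypass) and
weighted consensus annotation, producing a :class:`PipelineResult`. Errors in
one family are captured and the remaining families still complete.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .annotate import consensus_annotations
from .config import PresetConfig
from .errors import OrthoplaceError
from .hmm import ProfileHMM, calibrate_evalue
from .io import Family, SequenceRecord
from .orthologs import (
    cluster_same_genome,
    designate_status,
    evaluate_candidates,
    fastcat_reduce,
)
from .placement import (
    _derived_seed,
    build_node_hmms,
    ensure_match_mask,
    scoring_mode,
    stage1_family_scan,
    stage2_place,
)
from .results import PipelineResult
from .trees import family_supported_clades, resolve_enclosing_clade

logger = logging.getLogger(__name__)


@dataclass
class FamilyIndex:
    family: Family
    node_hmms: dict[str, ProfileHMM]
    supports: list
    content_hash: str


@dataclass
class LibraryIndex:
    entries: dict[str, FamilyIndex] = field(default_factory=dict)

    @property
    def families(self) -> list[Family]:
        return [e.family for e in self.entries.values()]

    def n_models(self) -> int:
        return sum(len(e.node_hmms) for e in self.entries.values())


def _family_hash(family: Family) -> str:
    h = hashlib.sha256()
    h.update(family.tree.to_newick().encode())
    for rid, row in zip(family.alignment.row_ids, family.alignment.rows):
        rec = family.sequences[rid]
        h.update(f"{rid}|{rec.taxon_id}|{rec.curation_tier}|{row}".encode())
    return h.hexdigest()


def build_library(
    source: str | Path | list[Family],
    config: PresetConfig,
    seed: int = 0,
) -> LibraryIndex:
    """Validate families and precompute masks, node profiles and supports.

    A family that fails to build is skipped with a logged reason; the others
    are indexed. Root profiles are calibrated here so repeated pipeline runs
    reuse them.
    """
    if isinstance(source, list):
        families = source
    else:
        from .io import read_family

        families = []
        for sub in sorted(p for p in Path(source).iterdir() if p.is_dir()):
            if not (sub / "alignment.fasta").exists():
                continue
            try:
                families.append(read_family(sub))
            except (OrthoplaceError, ValueError) as exc:
                logger.warning("skipping family %s: %s", sub.name, exc)
    index = LibraryIndex()
    for family in families:
        try:
            ensure_match_mask(family, config)
            node_hmms = build_node_hmms(family, config)
            root_id = family.tree.root.node_id
            calibrate_evalue(
                node_hmms[root_id],
                n_random=config.calib_n_random,
                seed=_derived_seed(seed, "stage1", family.family_id),
                db_size=len(families),
                mode=scoring_mode(family),
            )
            supports = family_supported_clades(family, config)
            index.entries[family.family_id] = FamilyIndex(
                family=family,
                node_hmms=node_hmms,
                supports=supports,
                content_hash=_family_hash(family),
            )
        except (OrthoplaceError, ValueError) as exc:
            logger.warning("skipping family %s: %s", family.family_id, exc)
    return index


def _score_row(score) -> dict:
    return {
        "bit_score": score.bit_score,
        "e_value": score.e_value,
        "query_coverage": score.query_coverage,
        "model_coverage": score.model_coverage,
        "query_span": list(score.query_span) if score.query_span else None,
        "model_span": list(score.model_span) if score.model_span else None,
    }


def run_pipeline(
    query: SequenceRecord,
    library: LibraryIndex | list[Family] | str | Path,
    config: PresetConfig,
    seed: int = 0,
) -> PipelineResult:
    """Stages 1-4 for one query against one family library.

    Deterministic given (query, library, config, seed); per-family errors are
    recorded in the job summary and do not abort the run.
    """
    if len(query.residues) > config.max_query_length:
        from .errors import QueryValidationError

        raise QueryValidationError(
            f"query length {len(query.residues)} exceeds the maximum of "
            f"{config.max_query_length} residues"
        )
    if not isinstance(library, LibraryIndex):
        library = build_library(library, config, seed=seed)

    families = library.families
    root_hmms = {
        fid: e.node_hmms[e.family.tree.root.node_id]
        for fid, e in library.entries.items()
    }
    result = PipelineResult(
        job_summary={
            "query_id": query.seq_id,
            "query_length": len(query.residues),
            "query_residues": query.residues,
            "seed": seed,
            "n_families": len(families),
            "config": config.to_dict(),
            "family_errors": {},
        }
    )

    stage1 = stage1_family_scan(query, families, config, seed=seed, root_hmms=root_hmms)
    for family_id, score in stage1:
        result.family_matches.append({"family_id": family_id, **{
            k: v for k, v in _score_row(score).items()
            if k in ("bit_score", "e_value", "query_coverage")
        }})

    all_orthologs: list = []
    ortholog_family_of: dict[str, str] = {}
    for family_id, _ in stage1:
        entry = library.entries[family_id]
        family = entry.family
        try:
            placement = stage2_place(
                query, family, config, seed=seed,
                node_hmms=entry.node_hmms, supports=entry.supports,
            )
            placement_row = {
                "family_id": family_id,
                "top_node_id": placement.top_node_id,
                "top_leaves": sorted(placement.top_leaves),
                "passes_stage2": placement.passes_stage2,
                "failure_reasons": list(placement.failure_reasons),
                **_score_row(placement.score),
            }
            if not placement.passes_stage2:
                result.distant_matches.append(placement_row)
                continue
            result.placements.append(placement_row)

            clade = resolve_enclosing_clade(
                family.tree, placement.top_node_id, entry.supports
            )
            result.enclosing_clades.append(
                {
                    "family_id": family_id,
                    "node_id": clade.node_id,
                    "top_node_id": clade.top_node_id,
                    "sources": sorted(clade.sources),
                    "members": sorted(clade.members),
                }
            )
            members = sorted(clade.members)
            if config.fastcat:
                kept = fastcat_reduce(query, members, family, config)
                for seq_id in members:
                    if seq_id not in kept:
                        rec = family.sequences[seq_id]
                        result.other_sequence_matches.append(
                            {
                                "family_id": family_id,
                                "seq_id": seq_id,
                                "taxon_id": rec.taxon_id,
                                "percent_identity": None,
                                "query_coverage": None,
                                "subject_coverage": None,
                                "reasons": ["fastcat_filtered"],
                            }
                        )
                members = kept
            candidates = evaluate_candidates(query, members, family, config)
            cluster_same_genome(candidates, family, config.intra_identity_min)
            designate_status(candidates, family)
            for c in candidates:
                if c.status == "rejected":
                    result.other_sequence_matches.append(
                        {
                            "family_id": family_id,
                            "seq_id": c.seq_id,
                            "taxon_id": c.taxon_id,
                            "percent_identity": c.percent_identity,
                            "query_coverage": c.query_coverage,
                            "subject_coverage": c.subject_coverage,
                            "reasons": list(c.rejection_reasons),
                        }
                    )
                else:
                    result.candidate_orthologs.append(
                        {
                            "family_id": family_id,
                            "seq_id": c.seq_id,
                            "taxon_id": c.taxon_id,
                            "genome_cluster_id": c.genome_cluster_id,
                            "is_representative": c.is_representative,
                            "percent_identity": c.percent_identity,
                            "query_coverage": c.query_coverage,
                            "subject_coverage": c.subject_coverage,
                            "status": c.status,
                        }
                    )
                    if c.status == "ortholog":
                        prev = ortholog_family_of.get(c.seq_id)
                        if prev is None:
                            all_orthologs.append(c)
                            ortholog_family_of[c.seq_id] = family_id
        except (OrthoplaceError, ValueError) as exc:
            logger.warning("family %s failed: %s", family_id, exc)
            result.job_summary["family_errors"][family_id] = str(exc)

    # stage 4: consensus annotation over every accepted ortholog
    annotations = []
    for family_id in {f for f in ortholog_family_of.values()}:
        annotations.extend(library.entries[family_id].family.annotations)
    consensus = consensus_annotations(all_orthologs, annotations)
    for kind in sorted(consensus):
        for ann in consensus[kind]:
            result.consensus_annotations.append(
                {
                    "kind": ann.kind,
                    "value": ann.value,
                    "confidence": ann.confidence,
                    "contributing": [list(c) for c in ann.contributing],
                }
            )
    if not result.consensus_annotations:
        result.job_summary["annotation_status"] = "no annotation derived"
    else:
        result.job_summary["annotation_status"] = "ok"
    return result
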