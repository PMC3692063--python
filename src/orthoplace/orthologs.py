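"""Candidate-ortholog extraction from an enclosing clade.

Members of the enclosing clade are aligned pairwise to the query and filtered
on identity and mutual coverage; same-genome near-identical sequences
(isoforms, redundant gene models) are collapsed to a single representative;
and when one genome contributes several passing clusters, only the one most
similar to the query is called orthologous, the rest paralogous. A fast
k-tuple + guide-tree bypass can shrink large clades before the expensive
pairwise alignments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io import SequenceRecord
from .msa import pairwise_identity_matrix

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

ALIGN_MODES = ("global", "glocal_query", "local")


@dataclass
class CandidateOrtholog:
    seq_id: str
    taxon_id: str
    percent_identity: float
    query_coverage: float
    subject_coverage: float
    genome_cluster_id: str | None = None
    is_representative: bool = False
    status: str = "candidate"  # candidate -> ortholog | paralog | rejected
    rejection_reasons: list[str] = field(default_factory=list)


def make_aligner(mode: str) -> Align.PairwiseAligner:
    """Affine-gap protein aligner (BLOSUM62, gap open -11, extend -1).

    ``global`` penalizes end gaps on both sequences; ``glocal_query`` keeps the
    query global but leaves subject overhangs free; ``local`` is Smith-Waterman.
    The subject is always passed as the aligner's target sequence.
    """
    if mode not in ALIGN_MODES:
        raise ValueError(f"unknown alignment mode {mode!r}")
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    if mode == "local":
        aligner.mode = "local"
    else:
        aligner.mode = "global"
        if mode == "glocal_query":
            # unaligned subject ends are free (deletions from the target)
            aligner.end_deletion_score = 0.0
    return aligner


def alignment_score(query: str, subject: str, mode: str) -> float:
    """Optimal alignment score under the configured scheme (subject = target)."""
    return float(make_aligner(mode).score(subject, query))


def pairwise_align(
    query: SequenceRecord, subject: SequenceRecord, mode: str = "glocal_query"
) -> tuple[float, float, float]:
    """(percent identity, query coverage, subject coverage) of the optimal alignment.

    Identity is identical pairs over aligned residue pairs; each coverage is
    the fraction of that sequence's residues inside aligned (residue-residue)
    columns.
    """
    aligner = make_aligner(mode)
    aln = aligner.align(subject.residues, query.residues)[0]
    aligned_pairs = 0
    matches = 0
    q_aligned = 0
    s_aligned = 0
    for (ts, te), (qs, qe) in zip(*aln.aligned):
        aligned_pairs += te - ts
        q_aligned += qe - qs
        s_aligned += te - ts
        for a, b in zip(subject.residues[ts:te], query.residues[qs:qe]):
            if a == b:
                matches += 1
    if aligned_pairs == 0:
        return 0.0, 0.0, 0.0
    return (
        matches / aligned_pairs,
        q_aligned / len(query.residues),
        s_aligned / len(subject.residues),
    )


def evaluate_candidates(
    query: SequenceRecord,
    members: list[str],
    family,
    config,
) -> list[CandidateOrtholog]:
    """Align every clade member to the query and apply the stage-3 thresholds.

    Failing members get ``status='rejected'`` with the violated criteria named
    (they are routed to the other-sequence-matches report, not dropped).
    """
    out = []
    for seq_id in sorted(members):
        rec = family.sequences[seq_id]
        ident, qcov, scov = pairwise_align(query, rec, config.align_mode)
        reasons = []
        if ident < config.stage3_identity_min:
            reasons.append("identity")
        if qcov < config.stage3_query_coverage_min:
            reasons.append("query_coverage")
        if scov < config.stage3_subject_coverage_min:
            reasons.append("subject_coverage")
        out.append(
            CandidateOrtholog(
                seq_id=seq_id,
                taxon_id=rec.taxon_id,
                percent_identity=ident,
                query_coverage=qcov,
                subject_coverage=scov,
                status="rejected" if reasons else "candidate",
                rejection_reasons=reasons,
            )
        )
    return out


def cluster_same_genome(
    candidates: list[CandidateOrtholog],
    family,
    intra_identity_min: float = 0.97,
) -> list[CandidateOrtholog]:
    """Collapse near-identical same-genome candidates into clusters.

    Within each taxon, single-linkage clusters at pairwise identity (measured
    on the family alignment) >= ``intra_identity_min``; the representative is
    a curated-tier sequence when available, otherwise the member most similar
    to the query. Only non-rejected candidates are clustered.
    """
    passing = [c for c in candidates if c.status != "rejected"]
    if not passing:
        return candidates
    identities = pairwise_identity_matrix(
        family.alignment.subset([c.seq_id for c in sorted(
            passing, key=lambda c: c.seq_id)])
    )
    by_taxon: dict[str, list[CandidateOrtholog]] = {}
    for c in passing:
        by_taxon.setdefault(c.taxon_id, []).append(c)

    for taxon in sorted(by_taxon):
        group = sorted(by_taxon[taxon], key=lambda c: c.seq_id)
        parent = {c.seq_id: c.seq_id for c in group}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, a in enumerate(group):
            for b in group[i + 1:]:
                if identities.loc[a.seq_id, b.seq_id] >= intra_identity_min:
                    parent[find(a.seq_id)] = find(b.seq_id)
        clusters: dict[str, list[CandidateOrtholog]] = {}
        for c in group:
            clusters.setdefault(find(c.seq_id), []).append(c)
        ordered = sorted(clusters.values(), key=lambda cl: min(c.seq_id for c in cl))
        for idx, members in enumerate(ordered):
            cid = f"{taxon}.c{idx}"
            rep = _pick_representative(members, family)
            for c in members:
                c.genome_cluster_id = cid
                c.is_representative = c.seq_id == rep.seq_id
    return candidates


def _pick_representative(
    members: list[CandidateOrtholog], family
) -> CandidateOrtholog:
    def key(c: CandidateOrtholog):
        curated = family.sequences[c.seq_id].curation_tier == "curated"
        return (not curated, -c.percent_identity, c.seq_id)

    return min(members, key=key)


def designate_status(candidates: list[CandidateOrtholog], family) -> list[CandidateOrtholog]:
    """Per genome, call the most query-similar passing cluster orthologous.

    All other passing clusters of the same genome become paralogous. Ties on
    representative identity go to the cluster holding a curated sequence, then
    to the lexicographically smallest member id.
    """
    passing = [c for c in candidates if c.status != "rejected"]
    by_taxon: dict[str, dict[str, list[CandidateOrtholog]]] = {}
    for c in passing:
        by_taxon.setdefault(c.taxon_id, {}).setdefault(c.genome_cluster_id, []).append(c)
    for taxon in sorted(by_taxon):
        clusters = by_taxon[taxon]

        def cluster_key(cid: str):
            members = clusters[cid]
            rep = [c for c in members if c.is_representative][0]
            has_curated = any(
                family.sequences[c.seq_id].curation_tier == "curated" for c in members
            )
            return (-rep.percent_identity, not has_curated, min(c.seq_id for c in members))

        ranked = sorted(clusters, key=cluster_key)
        for rank, cid in enumerate(ranked):
            status = "ortholog" if rank == 0 else "paralog"
            for c in clusters[cid]:
                c.status = status
    return candidates


def shared_kmer_score(query: str, subject: str, k: int) -> float:
    """Distinct shared k-tuples, normalized by the subject's k-tuple count."""
    if len(query) < k or len(subject) < k:
        return 0.0
    qk = {query[i: i + k] for i in range(len(query) - k + 1)}
    sk = {subject[i: i + k] for i in range(len(subject) - k + 1)}
    return len(qk & sk) / max(1, len(subject) - k + 1)


def fastcat_reduce(
    query: SequenceRecord,
    members: list[str],
    family,
    config,
) -> list[str]:
    """Fast bypass: pre-select clade members before pairwise evaluation.

    Members are ranked by shared k-tuple content with the query and the top
    ``fastcat_top_n`` kept; a neighbor-joining guide tree over identity-derived
    distances (family alignment for member-member pairs, pairwise alignment for
    query-member pairs) then keeps the smallest query-containing subtree with
    at least ``fastcat_subtree_min`` members. When ``fastcat_top_n`` covers the
    whole clade the reduction is the identity on membership.
    """
    members = sorted(members)
    if config.fastcat_top_n >= len(members):
        return members
    ranked = sorted(
        members,
        key=lambda s: (
            -shared_kmer_score(query.residues, family.sequences[s].residues,
                               config.fastcat_k),
            s,
        ),
    )
    kept = sorted(ranked[: config.fastcat_top_n])
    if len(kept) < 2:
        return kept

    from skbio import DistanceMatrix
    from skbio.tree import nj

    ids = kept + ["__query__"]
    n = len(ids)
    ident = pairwise_identity_matrix(family.alignment.subset(kept))
    dm = np.zeros((n, n))
    cap = 5.0
    for i, a in enumerate(kept):
        for j in range(i + 1, len(kept)):
            b = kept[j]
            d = min(cap, -math.log(max(1e-3, ident.loc[a, b])))
            dm[i, j] = dm[j, i] = d
    for i, a in enumerate(kept):
        qid, _, _ = pairwise_align(query, family.sequences[a], "glocal_query")
        d = min(cap, -math.log(max(1e-3, qid)))
        dm[i, n - 1] = dm[n - 1, i] = d
    tree = nj(DistanceMatrix(dm, ids))
    tip = tree.find("__query__")
    want = min(config.fastcat_subtree_min, len(kept))
    node = tip.parent
    while node is not None:
        names = sorted(t.name for t in node.tips() if t.name != "__query__")
        if len(names) >= want:
            return names
        node = node.parent
    return kept
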