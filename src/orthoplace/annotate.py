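"""Weighted consensus functional annotation from accepted orthologs.

Each ortholog's annotation contributes a weight that grows with its sequence
identity to the query and with the provenance of the annotation (experimental
over curated over computational). Competing values of one annotation kind are
scored by their summed weights and normalized to confidences that sum to one,
so a confidence reads as "share of the weighted evidence behind this value".
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import AnnotationRecord

#: default provenance weights; identity sharpness exponent defaults to 2
DEFAULT_TIER_WEIGHTS = {"experimental": 1.0, "curated": 0.8, "computational": 0.3}
DEFAULT_SHARPNESS = 2.0


@dataclass(frozen=True)
class ConsensusAnnotation:
    kind: str
    value: str
    confidence: float
    contributing: tuple  # (seq_id, weight, evidence, identity) per supporter


def annotation_weight(
    identity: float,
    evidence: str,
    tier_weights: dict[str, float] | None = None,
    sharpness: float = DEFAULT_SHARPNESS,
) -> float:
    """Transfer weight of one annotation: ``tier_weight * identity ** sharpness``.

    Strictly increasing in identity and in evidence tier rank.
    """
    tw = tier_weights if tier_weights is not None else DEFAULT_TIER_WEIGHTS
    if evidence not in tw:
        raise ValueError(f"unknown evidence tier {evidence!r}")
    if not (0.0 <= identity <= 1.0):
        raise ValueError("identity must be in [0, 1]")
    if sharpness <= 0:
        raise ValueError("sharpness must be positive")
    return tw[evidence] * identity ** sharpness


def _normalize_value(kind: str, value: str) -> str:
    if kind == "description":
        return " ".join(value.lower().split())
    return value.strip()


def consensus_annotations(
    orthologs: list,
    annotations: list[AnnotationRecord],
    tier_weights: dict[str, float] | None = None,
    sharpness: float = DEFAULT_SHARPNESS,
) -> dict[str, list[ConsensusAnnotation]]:
    """Ranked consensus values per annotation kind from status-ortholog hits.

    Descriptions are compared after case folding and whitespace normalization.
    Returns an empty mapping when there are no orthologs or no transferable
    annotations (the caller reports "no annotation derived").
    """
    identity_of = {
        o.seq_id: o.percent_identity for o in orthologs if o.status == "ortholog"
    }
    by_kind: dict[str, dict[str, list]] = {}
    for ann in annotations:
        if ann.seq_id not in identity_of:
            continue
        ident = identity_of[ann.seq_id]
        w = annotation_weight(ident, ann.evidence, tier_weights, sharpness)
        if w <= 0:
            continue
        key = _normalize_value(ann.kind, ann.value)
        by_kind.setdefault(ann.kind, {}).setdefault(key, []).append(
            (ann.seq_id, w, ann.evidence, ident)
        )
    out: dict[str, list[ConsensusAnnotation]] = {}
    for kind in sorted(by_kind):
        values = by_kind[kind]
        totals = {v: sum(w for _, w, _, _ in sup) for v, sup in values.items()}
        grand = sum(totals.values())
        ranked = sorted(values, key=lambda v: (-totals[v], v))
        out[kind] = [
            ConsensusAnnotation(
                kind=kind,
                value=v,
                confidence=totals[v] / grand,
                contributing=tuple(sorted(values[v])),
            )
            for v in ranked
        ]
    return out
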