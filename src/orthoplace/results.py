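"""Structured pipeline results and their JSON/TSV report serialization.

The report mirrors the tabbed views a user of an orthology service would see:
family matches, candidate orthologs, other sequence matches (clade members
failing one or more criteria), derived annotations, and a job summary that
records the query and the effective value of every parameter. All sections
are stored as plain JSON-native rows so a report round-trips losslessly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

REPORT_COLUMNS = {
    "family_matches": ["family_id", "bit_score", "e_value", "query_coverage"],
    "candidate_orthologs": [
        "family_id", "seq_id", "taxon_id", "genome_cluster_id", "is_representative",
        "percent_identity", "query_coverage", "subject_coverage", "status",
    ],
    "other_sequence_matches": [
        "family_id", "seq_id", "taxon_id", "percent_identity", "query_coverage",
        "subject_coverage", "reasons",
    ],
    "annotations": ["kind", "value", "confidence", "n_supporting", "top_evidence"],
}


@dataclass
class PipelineResult:
    """Everything one pipeline invocation produced, as JSON-native rows."""

    job_summary: dict
    family_matches: list[dict] = field(default_factory=list)
    placements: list[dict] = field(default_factory=list)
    enclosing_clades: list[dict] = field(default_factory=list)
    candidate_orthologs: list[dict] = field(default_factory=list)
    other_sequence_matches: list[dict] = field(default_factory=list)
    consensus_annotations: list[dict] = field(default_factory=list)
    distant_matches: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineResult":
        return cls(**json.loads(text))


def _annotation_rows(result: PipelineResult) -> list[dict]:
    rows = []
    for ann in result.consensus_annotations:
        contributing = ann.get("contributing", [])
        top_evidence = ""
        if contributing:
            order = {"experimental": 0, "curated": 1, "computational": 2}
            top_evidence = min(
                (c[2] for c in contributing), key=lambda e: order.get(e, 9)
            )
        rows.append(
            {
                "kind": ann["kind"],
                "value": ann["value"],
                "confidence": ann["confidence"],
                "n_supporting": len(contributing),
                "top_evidence": top_evidence,
            }
        )
    return rows


def write_report(result: PipelineResult, out_dir: str | Path) -> Path:
    """Write ``report.json`` plus the per-tab TSV files.

    Empty sections still produce header-only TSVs. The JSON file re-parses to
    an equal ``PipelineResult``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(result.to_json() + "\n")

    sections = {
        "family_matches": result.family_matches,
        "candidate_orthologs": result.candidate_orthologs,
        "other_sequence_matches": result.other_sequence_matches,
        "annotations": _annotation_rows(result),
    }
    for name, rows in sections.items():
        cols = REPORT_COLUMNS[name]
        df = pd.DataFrame(rows, columns=cols)
        if name == "other_sequence_matches" and len(df):
            df["reasons"] = df["reasons"].map(
                lambda r: ",".join(r) if isinstance(r, (list, tuple)) else r
            )
        df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)

    summary = pd.DataFrame(
        sorted(result.job_summary.items()), columns=["parameter", "value"]
    )
    summary.to_csv(out_dir / "job_summary.tsv", sep="\t", index=False)
    return out_dir


def read_report(out_dir: str | Path) -> PipelineResult:
    return PipelineResult.from_json((Path(out_dir) / "report.json").read_text())
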