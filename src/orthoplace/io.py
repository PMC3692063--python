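"""On-disk formats: family library directories, query FASTA, label/annotation TSVs.

A family library is a directory of per-family subdirectories, each holding

* ``alignment.fasta`` — aligned rows; headers encode ``seq_id|taxon_id|tier``
  (missing fields default to taxon ``unknown`` and tier ``automatic``),
* ``tree.nwk`` — a rooted Newick tree whose leaf labels equal the row ids,
* optional ``labels_<source>.tsv`` — third-party orthology assignments with
  columns (seq_id, group_id),
* optional ``annotations.tsv`` — columns (seq_id, kind, value, evidence),
* optional ``meta.json`` — currently just the family type.

The flat layout is diff-able and trivially simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .errors import IntegrityError, LoadError, QueryValidationError
from .msa import ALPHABET, GAP_CHARS, FamilyAlignment

CURATION_TIERS = ("curated", "automatic")
ANNOTATION_KINDS = ("description", "go_term", "ec_number")
EVIDENCE_TIERS = ("experimental", "curated", "computational")


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence with its genome of origin and curation tier."""

    seq_id: str
    residues: str
    taxon_id: str = "unknown"
    curation_tier: str = "automatic"

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise ValueError("empty seq_id")
        if not self.residues:
            raise ValueError(f"{self.seq_id}: empty sequence")
        bad = sorted({c for c in self.residues if c not in ALPHABET})
        if bad:
            raise ValueError(f"{self.seq_id}: characters outside alphabet: {bad}")
        if self.curation_tier not in CURATION_TIERS:
            raise ValueError(f"unknown curation tier {self.curation_tier!r}")


@dataclass(frozen=True)
class AnnotationRecord:
    seq_id: str
    kind: str
    value: str
    evidence: str

    def __post_init__(self) -> None:
        if self.kind not in ANNOTATION_KINDS:
            raise ValueError(f"unknown annotation kind {self.kind!r}")
        if self.evidence not in EVIDENCE_TIERS:
            raise ValueError(f"unknown evidence tier {self.evidence!r}")


@dataclass
class OrthologyLabeling:
    """Partial assignment of sequences to one source's orthology groups."""

    source_name: str
    assignments: dict[str, str] = field(default_factory=dict)


@dataclass(eq=False)
class Family:
    """One library entry: alignment, rooted tree, labels, annotations."""

    family_id: str
    alignment: FamilyAlignment
    tree: "PhyloTree"
    family_type: str = "mda"  # mda (global homology) or domain (local matches)
    labelings: list[OrthologyLabeling] = field(default_factory=list)
    annotations: list[AnnotationRecord] = field(default_factory=list)
    sequences: dict[str, SequenceRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family_type not in ("mda", "domain"):
            raise ValueError(f"unknown family_type {self.family_type!r}")
        rows = set(self.alignment.row_ids)
        leaves = set(self.tree.leaf_ids)
        if rows != leaves:
            only_tree = sorted(leaves - rows)
            only_rows = sorted(rows - leaves)
            raise IntegrityError(
                f"family {self.family_id}: tree/alignment mismatch; "
                f"only in tree: {only_tree}; only in alignment: {only_rows}"
            )
        if not self.sequences:
            self.sequences = {
                rid: SequenceRecord(seq_id=rid, residues=self.alignment.ungapped(rid))
                for rid in self.alignment.row_ids
            }
        for labeling in self.labelings:
            stray = sorted(set(labeling.assignments) - rows)
            if stray:
                raise IntegrityError(
                    f"family {self.family_id}: labeling {labeling.source_name} "
                    f"references unknown sequences {stray}"
                )
        for ann in self.annotations:
            if ann.seq_id not in rows:
                raise IntegrityError(
                    f"family {self.family_id}: annotation for unknown sequence "
                    f"{ann.seq_id}"
                )

    @property
    def taxon_of(self) -> dict[str, str]:
        return {s.seq_id: s.taxon_id for s in self.sequences.values()}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Family):
            return NotImplemented
        return (
            self.family_id == other.family_id
            and self.family_type == other.family_type
            and self.alignment == other.alignment
            and self.tree == other.tree
            and self.labelings == other.labelings
            and sorted(self.annotations, key=lambda a: (a.seq_id, a.kind, a.value))
            == sorted(other.annotations, key=lambda a: (a.seq_id, a.kind, a.value))
            and self.sequences == other.sequences
        )


def _parse_header(header: str) -> tuple[str, str, str]:
    parts = header.split("|")
    seq_id = parts[0]
    taxon = parts[1] if len(parts) > 1 and parts[1] else "unknown"
    tier = parts[2] if len(parts) > 2 and parts[2] else "automatic"
    return seq_id, taxon, tier


def _read_tsv_rows(path: Path, n_fields: int) -> list[list[str]]:
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != n_fields:
            raise LoadError(f"{path}:{lineno}: expected {n_fields} fields, got {len(parts)}")
        rows.append(parts)
    return rows


def read_family(dir_path: str | Path) -> Family:
    """Load and validate one family directory."""
    from .trees import PhyloTree

    dir_path = Path(dir_path)
    fasta = dir_path / "alignment.fasta"
    nwk = dir_path / "tree.nwk"
    for mandatory in (fasta, nwk):
        if not mandatory.exists():
            raise LoadError(f"family {dir_path.name}: missing {mandatory.name}")

    row_ids, rows, sequences = [], [], {}
    for rec in SeqIO.parse(str(fasta), "fasta"):
        seq_id, taxon, tier = _parse_header(rec.id)
        gapped = str(rec.seq).upper()
        row_ids.append(seq_id)
        rows.append(gapped)
        ungapped = "".join(c for c in gapped if c not in GAP_CHARS)
        sequences[seq_id] = SequenceRecord(
            seq_id=seq_id, residues=ungapped, taxon_id=taxon, curation_tier=tier
        )
    if not row_ids:
        raise LoadError(f"family {dir_path.name}: empty alignment")
    if len(set(row_ids)) != len(row_ids):
        raise IntegrityError(f"family {dir_path.name}: duplicate sequence ids")
    alignment = FamilyAlignment(row_ids, rows)

    tree = PhyloTree.from_newick(nwk.read_text())

    labelings = []
    for labels_path in sorted(dir_path.glob("labels_*.tsv")):
        source = labels_path.stem[len("labels_"):]
        assignments: dict[str, str] = {}
        for seq_id, group_id in _read_tsv_rows(labels_path, 2):
            if seq_id in assignments:
                raise IntegrityError(
                    f"{labels_path}: sequence {seq_id} labeled twice"
                )
            assignments[seq_id] = group_id
        labelings.append(OrthologyLabeling(source, assignments))

    annotations = []
    ann_path = dir_path / "annotations.tsv"
    if ann_path.exists():
        for seq_id, kind, value, evidence in _read_tsv_rows(ann_path, 4):
            annotations.append(AnnotationRecord(seq_id, kind, value, evidence))

    family_type = "mda"
    meta_path = dir_path / "meta.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        family_type = meta.get("family_type", "mda")
        mask = meta.get("match_mask")
        if mask is not None:
            import numpy as np

            alignment.match_mask = np.array(mask, dtype=bool)

    return Family(
        family_id=dir_path.name,
        alignment=alignment,
        tree=tree,
        family_type=family_type,
        labelings=labelings,
        annotations=annotations,
        sequences=sequences,
    )


def write_family(family: Family, dir_path: str | Path) -> Path:
    """Write a family directory in the library layout (round-trips losslessly)."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    with open(dir_path / "alignment.fasta", "w") as fh:
        for rid, row in zip(family.alignment.row_ids, family.alignment.rows):
            rec = family.sequences[rid]
            fh.write(f">{rid}|{rec.taxon_id}|{rec.curation_tier}\n{row}\n")
    (dir_path / "tree.nwk").write_text(family.tree.to_newick() + "\n")
    for labeling in family.labelings:
        with open(dir_path / f"labels_{labeling.source_name}.tsv", "w") as fh:
            fh.write("# seq_id\tgroup_id\n")
            for seq_id in sorted(labeling.assignments):
                fh.write(f"{seq_id}\t{labeling.assignments[seq_id]}\n")
    if family.annotations:
        with open(dir_path / "annotations.tsv", "w") as fh:
            fh.write("# seq_id\tkind\tvalue\tevidence\n")
            for ann in sorted(
                family.annotations, key=lambda a: (a.seq_id, a.kind, a.value)
            ):
                fh.write(f"{ann.seq_id}\t{ann.kind}\t{ann.value}\t{ann.evidence}\n")
    meta: dict = {"family_type": family.family_type}
    if family.alignment.match_mask is not None:
        meta["match_mask"] = [int(v) for v in family.alignment.match_mask]
    (dir_path / "meta.json").write_text(json.dumps(meta) + "\n")
    return dir_path


def read_library(library_dir: str | Path) -> list[Family]:
    """All families below a library directory, sorted by family id."""
    library_dir = Path(library_dir)
    families = []
    for sub in sorted(p for p in library_dir.iterdir() if p.is_dir()):
        if (sub / "alignment.fasta").exists():
            families.append(read_family(sub))
    if not families:
        raise LoadError(f"no families found under {library_dir}")
    return families


def write_library(families: list[Family], library_dir: str | Path) -> Path:
    library_dir = Path(library_dir)
    library_dir.mkdir(parents=True, exist_ok=True)
    for family in families:
        write_family(family, library_dir / family.family_id)
    return library_dir


def read_query(fasta_path: str | Path, max_length: int = 2000) -> SequenceRecord:
    """Read and validate a single-record protein query FASTA.

    Residues are uppercased with gaps and whitespace stripped; the sequence is
    rejected when empty, longer than ``max_length`` or containing characters
    outside the amino-acid alphabet.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise QueryValidationError(
            f"{fasta_path}: expected exactly one FASTA record, found {len(records)}"
        )
    rec = records[0]
    seq_id, taxon, tier = _parse_header(rec.id)
    residues = "".join(
        c for c in str(rec.seq).upper() if c not in GAP_CHARS and not c.isspace()
    )
    if not residues:
        raise QueryValidationError(f"{fasta_path}: empty query sequence")
    if len(residues) > max_length:
        raise QueryValidationError(
            f"query length {len(residues)} exceeds the maximum of {max_length} residues"
        )
    bad = sorted({c for c in residues if c not in ALPHABET})
    if bad:
        raise QueryValidationError(f"query contains characters outside alphabet: {bad}")
    return SequenceRecord(
        seq_id=seq_id, residues=residues, taxon_id=taxon, curation_tier=tier
    )
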