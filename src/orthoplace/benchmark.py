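"""Leave-one-out placement benchmark over a simulated library.

Every sequence of every family is held out in turn, the subtree profiles are
rebuilt without it, and the sequence is classified back into the pruned tree.
Precision is the fraction of stage-2-passing classifications whose top node
falls entirely inside the held-out sequence's true orthology group; recall is
the fraction of held-out sequences that pass stage 2 at all. Precision over
zero passing placements is reported as undefined (``None``), not zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PresetConfig
from .errors import FamilySkip
from .io import Family
from .placement import leave_one_out_placement


@dataclass(frozen=True)
class LooRecord:
    family_id: str
    held_out: str
    top_node_id: str
    top_leaves: frozenset[str]
    passed: bool
    failure_reasons: tuple[str, ...]


@dataclass
class BenchmarkResult:
    precision: float | None
    n_passing: int
    n_correct: int
    n_total: int
    recall: float
    per_family: pd.DataFrame
    records: list[LooRecord] = field(repr=False, default_factory=list)


def record_correct(record: LooRecord, truth: dict[str, str]) -> bool:
    """A placement is correct iff its leaves all lie in the held-out true group."""
    group = truth[record.held_out]
    members = {s for s, g in truth.items() if g == group} - {record.held_out}
    return bool(record.top_leaves) and record.top_leaves <= members


def precision_from_records(
    records: list[LooRecord], truth_by_family: dict[str, dict[str, str]]
) -> tuple[float | None, int, int]:
    """(precision, n_correct, n_passing) over the stage-2-passing records."""
    passing = [r for r in records if r.passed]
    if not passing:
        return None, 0, 0
    n_correct = sum(
        record_correct(r, truth_by_family[r.family_id]) for r in passing
    )
    return n_correct / len(passing), n_correct, len(passing)


def run_loo_benchmark(
    families: list[Family],
    truth_by_family: dict[str, dict[str, str]],
    config: PresetConfig,
    seed: int = 0,
) -> BenchmarkResult:
    """Leave-one-out classification of every sequence of every family."""
    records: list[LooRecord] = []
    rows = []
    for family in families:
        truth = truth_by_family[family.family_id]
        fam_records = []
        for held_out in family.alignment.row_ids:
            try:
                placement, _ = leave_one_out_placement(
                    family, held_out, config, truth_groups=truth, seed=seed
                )
            except FamilySkip:
                continue
            rec = LooRecord(
                family_id=family.family_id,
                held_out=held_out,
                top_node_id=placement.top_node_id,
                top_leaves=placement.top_leaves,
                passed=placement.passes_stage2,
                failure_reasons=tuple(placement.failure_reasons),
            )
            fam_records.append(rec)
        precision, n_correct, n_passing = precision_from_records(
            fam_records, truth_by_family
        )
        rows.append(
            {
                "family_id": family.family_id,
                "n_held_out": len(fam_records),
                "n_passing": n_passing,
                "n_correct": n_correct,
                "precision": precision,
            }
        )
        records.extend(fam_records)
    precision, n_correct, n_passing = precision_from_records(records, truth_by_family)
    n_total = len(records)
    return BenchmarkResult(
        precision=precision,
        n_passing=n_passing,
        n_correct=n_correct,
        n_total=n_total,
        recall=n_passing / n_total if n_total else 0.0,
        per_family=pd.DataFrame(rows),
        records=records,
    )


def permute_truth(
    truth_by_family: dict[str, dict[str, str]], seed: int
) -> dict[str, dict[str, str]]:
    """Shuffle group labels among the sequences of each family (negative control)."""
    rng = np.random.default_rng(seed)
    out = {}
    for family_id in sorted(truth_by_family):
        truth = truth_by_family[family_id]
        seq_ids = sorted(truth)
        labels = [truth[s] for s in seq_ids]
        perm = rng.permutation(len(labels))
        out[family_id] = {s: labels[perm[i]] for i, s in enumerate(seq_ids)}
    return out
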