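"""Place a query protein into a family tree by exhaustive subtree-HMM scoring.

Builds a profile HMM at every node of a simulated family's tree (all sharing
one match-column mask, so bit scores are comparable), scores a held-out
member against each, and shows that the top-scoring node falls inside the
held-out sequence's true orthology group.
"""

import orthoplace as op
from orthoplace.placement import prune_family

cfg = op.SimulationConfig(n_families=1, seed=42)
family, truth = op.simulate_family(cfg, 0)
config = op.preset("high_recall")

held_out = family.alignment.row_ids[0]
query = op.SequenceRecord(seq_id=held_out, residues=family.sequences[held_out].residues)
pruned = prune_family(family, held_out)

placement = op.stage2_place(query, pruned, config, seed=7)
score = placement.score
print(f"query            : {held_out} (held out of the family)")
print(f"top-scoring node : {placement.top_node_id}")
print(f"  bit score      : {score.bit_score:.1f} bits (E = {score.e_value:.2e})")
print(f"  query coverage : {score.query_coverage:.2f}  "
      f"model coverage: {score.model_coverage:.2f}")
print(f"  passes stage 2 : {placement.passes_stage2}")
print(f"node leaf set    : {sorted(placement.top_leaves)}")

group = truth[held_out]
members = sorted(s for s, g in truth.items() if g == group and s != held_out)
inside = placement.top_leaves <= set(members)
print(f"true group {group}  : {members}")
print(f"placement inside the true orthology group: {inside}")
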