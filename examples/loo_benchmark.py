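"""Leave-one-out placement benchmark on a small simulated library.

Every sequence of every family is held out, the subtree profiles rebuilt,
and the sequence classified back into the pruned tree. Precision counts the
stage-2-passing placements whose top node lies inside the held-out
sequence's true orthology group; a permuted-labels control shows the metric
actually reads the ground truth. (The full 20-family benchmark is what
scripts/acceptance.py runs.)
"""

import orthoplace as op

cfg = op.SimulationConfig(n_families=4, seed=42)
families, truth = op.simulate_library(cfg)
config = op.preset("high_recall")

result = op.run_loo_benchmark(families, truth, config, seed=7)
print(result.per_family.to_string(index=False))
print(
    f"\noverall: precision {result.precision:.3f} "
    f"({result.n_correct}/{result.n_passing} passing placements correct), "
    f"recall {result.recall:.3f} of {result.n_total} held-out sequences"
)

permuted = op.permute_truth(truth, seed=99)
p_perm, _, _ = op.precision_from_records(result.records, permuted)
print(f"negative control (shuffled group labels): precision {p_perm:.3f}")
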