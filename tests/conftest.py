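import numpy as np
import pytest

import orthoplace as op


@pytest.fixture(scope="session")
def warm_kernels():
    """Compile the numba scoring kernels once per session."""
    aln = op.FamilyAlignment(["a", "b"], ["ACD", "ACD"])
    aln.match_mask = op.select_match_columns(aln)
    hmm = op.build_profile_hmm(aln)
    op.forward_bits(hmm, "ACD")
    op.viterbi_bits(hmm, "ACD")
    op.forward_bits(hmm, "ACD", "local")
    op.viterbi_bits(hmm, "ACD", "local")


@pytest.fixture()
def toy_alignment():
    aln = op.FamilyAlignment(
        ["s1", "s2", "s3", "s4"],
        ["ACDEF", "ACDEY", "ACDFY", "GCDFY"],
    )
    aln.match_mask = op.select_match_columns(aln)
    return aln


@pytest.fixture(scope="session")
def sim_small():
    """Three simulated families with ground truth (cheap, shared)."""
    cfg = op.SimulationConfig(n_families=3, seed=11)
    families, truth = op.simulate_library(cfg)
    return families, truth


@pytest.fixture(scope="session")
def sim_library_index(sim_small, warm_kernels):
    families, truth = sim_small
    config = op.preset("high_recall")
    index = op.build_library(families, config, seed=5)
    return index, truth, config


def member_query(family, seq_id, query_id="query"):
    return op.SequenceRecord(
        seq_id=query_id, residues=family.sequences[seq_id].residues
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260917)
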