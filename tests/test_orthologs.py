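import pytest
from Bio.Align import substitution_matrices

import orthoplace as op
from orthoplace.msa import AMINO_ACIDS
from orthoplace.orthologs import alignment_score, shared_kmer_score

from .oracles import enumerate_alignment_score, single_linkage_clusters

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _rec(seq_id, residues, taxon="t1", tier="automatic"):
    return op.SequenceRecord(
        seq_id=seq_id, residues=residues, taxon_id=taxon, curation_tier=tier
    )


class TestPairwiseAlign:
    def test_identical_sequences(self):
        q = _rec("q", "ACDEFGHIKL")
        for mode in ("global", "glocal_query", "local"):
            ident, qcov, scov = op.pairwise_align(q, q, mode)
            assert (ident, qcov, scov) == (1.0, 1.0, 1.0)

    @pytest.mark.parametrize("mode", ["global", "glocal_query", "local"])
    def test_score_matches_enumeration(self, rng, mode):
        """Optimal affine-gap score equals exhaustive enumeration (len <= 6)."""
        for _ in range(15):
            q = "".join(AMINO_ACIDS[i] for i in rng.choice(20, int(rng.integers(1, 7))))
            s = "".join(AMINO_ACIDS[i] for i in rng.choice(20, int(rng.integers(1, 7))))
            got = alignment_score(q, s, mode)
            want = enumerate_alignment_score(q, s, BLOSUM62, mode=mode)
            assert got == pytest.approx(want)

    def test_half_query_subject(self):
        """A subject equal to the query's left half is fully covered; the query
        is about half covered under the query-global mode."""
        full = "MKTLLVLAVCLGAHSEWQFEDKAT"
        q = _rec("q", full)
        s = _rec("s", full[: len(full) // 2])
        ident, qcov, scov = op.pairwise_align(q, s, "glocal_query")
        assert ident == 1.0
        assert scov == 1.0
        assert qcov == pytest.approx(0.5, abs=0.05)


class TestEvaluateCandidates:
    @pytest.fixture()
    def family(self, sim_small):
        return sim_small[0][0]

    def test_all_identical_pass(self, family):
        config = op.preset("high_recall")
        sid = family.alignment.row_ids[0]
        q = _rec("q", family.sequences[sid].residues)
        cands = op.evaluate_candidates(q, [sid], family, config)
        assert cands[0].status == "candidate"
        assert cands[0].percent_identity == 1.0

    def test_identity_failure_reason(self, family):
        config = op.preset("high_recall", stage3_identity_min=1.0)
        members = family.alignment.row_ids[:3]
        q = _rec("q", family.sequences[members[0]].residues)
        cands = op.evaluate_candidates(q, members, family, config)
        failing = [c for c in cands if c.percent_identity < 1.0]
        assert failing and all(
            c.status == "rejected" and "identity" in c.rejection_reasons
            for c in failing
        )

    def test_threshold_monotonicity(self, family):
        """Stricter presets pass a subset of what looser presets pass."""
        members = family.alignment.row_ids
        q = _rec("q", family.sequences[members[0]].residues)
        passing = {}
        for name in ("high_precision", "high_recall", "remote_homolog"):
            cands = op.evaluate_candidates(q, members, family, op.preset(name))
            passing[name] = {c.seq_id for c in cands if c.status != "rejected"}
        assert passing["high_precision"] <= passing["high_recall"]
        assert passing["high_recall"] <= passing["remote_homolog"]


class TestSameGenomeClustering:
    def _family(self, rows, taxa, tiers=None):
        ids = list(rows)
        aln = op.FamilyAlignment(ids, [rows[i] for i in ids])
        # caterpillar topology is fine for these tests
        core = ids[0] + ":1"
        for i in ids[1:]:
            core = f"({core},{i}:1):1"
        tree = op.PhyloTree.from_newick(core.rsplit(":", 1)[0] + ";")
        sequences = {
            i: _rec(i, rows[i].replace("-", ""), taxa[i], (tiers or {}).get(i, "automatic"))
            for i in ids
        }
        return op.Family(
            family_id="f", alignment=aln, tree=tree, sequences=sequences
        )

    def _candidates(self, family, idents):
        return [
            op.CandidateOrtholog(
                seq_id=s,
                taxon_id=family.sequences[s].taxon_id,
                percent_identity=idents.get(s, 0.9),
                query_coverage=1.0,
                subject_coverage=1.0,
            )
            for s in family.alignment.row_ids
        ]

    def test_curated_representative_wins(self):
        rows = {"iso1": "ACDEFGHIKL", "iso2": "ACDEFGHIKV"}
        family = self._family(rows, {"iso1": "tx", "iso2": "tx"}, {"iso2": "curated"})
        cands = self._candidates(family, {"iso1": 0.99, "iso2": 0.95})
        op.cluster_same_genome(cands, family, 0.9)
        by_id = {c.seq_id: c for c in cands}
        assert by_id["iso1"].genome_cluster_id == by_id["iso2"].genome_cluster_id
        assert by_id["iso2"].is_representative and not by_id["iso1"].is_representative

    def test_taxa_never_merge(self):
        rows = {"a": "ACDEFGHIKL", "b": "ACDEFGHIKL"}
        family = self._family(rows, {"a": "t1", "b": "t2"})
        cands = self._candidates(family, {})
        op.cluster_same_genome(cands, family, 0.5)
        ids = {c.genome_cluster_id for c in cands}
        assert len(ids) == 2

    def test_matches_single_linkage_closure(self, rng):
        """Clusters equal the brute-force transitive closure of the identity graph."""
        n = 8
        base = rng.choice(20, 30)
        rows = {}
        for i in range(n):
            seq = base.copy()
            flips = rng.choice(30, size=int(rng.integers(0, 18)), replace=False)
            seq[flips] = (seq[flips] + 1 + rng.integers(0, 19, size=len(flips))) % 20
            rows[f"s{i}"] = "".join(AMINO_ACIDS[j] for j in seq)
        family = self._family(rows, {f"s{i}": "tx" for i in range(n)})
        cands = self._candidates(family, {})
        threshold = 0.8
        op.cluster_same_genome(cands, family, threshold)
        got = {}
        for c in cands:
            got.setdefault(c.genome_cluster_id, set()).add(c.seq_id)
        ident = op.pairwise_identity_matrix(family.alignment)
        want = single_linkage_clusters(
            sorted(rows), lambda a, b: ident.loc[a, b] >= threshold
        )
        assert {frozenset(v) for v in got.values()} == want


class TestDesignateStatus:
    def _family_two_clusters(self, tie=False, curated_cluster=None):
        rows = {
            "a1": "ACDEFGHIKLMNPQRSTVWY",
            "a2": "ACDEFGHIKLMNPQRSTVWA",
            "b1": "AAAAFGHIKLMNPQRSTVWY",
        }
        taxa = {k: "tx" for k in rows}
        tiers = {}
        if curated_cluster:
            tiers[curated_cluster] = "curated"
        aln = op.FamilyAlignment(list(rows), list(rows.values()))
        tree = op.PhyloTree.from_newick("((a1:1,a2:1):1,b1:1);")
        sequences = {
            k: _rec(k, v, taxa[k], tiers.get(k, "automatic")) for k, v in rows.items()
        }
        return op.Family(family_id="f", alignment=aln, tree=tree, sequences=sequences)

    def _run(self, family, idents):
        cands = [
            op.CandidateOrtholog(
                seq_id=s, taxon_id="tx", percent_identity=idents[s],
                query_coverage=1.0, subject_coverage=1.0,
            )
            for s in idents
        ]
        op.cluster_same_genome(cands, family, 0.9)
        op.designate_status(cands, family)
        return {c.seq_id: c.status for c in cands}

    def test_higher_identity_cluster_is_ortholog(self):
        family = self._family_two_clusters()
        statuses = self._run(family, {"a1": 0.85, "a2": 0.84, "b1": 0.80})
        assert statuses["a1"] == statuses["a2"] == "ortholog"
        assert statuses["b1"] == "paralog"

    def test_single_cluster_is_ortholog(self):
        family = self._family_two_clusters()
        statuses = self._run(family, {"a1": 0.85, "a2": 0.84})
        assert set(statuses.values()) == {"ortholog"}

    def test_identity_tie_curated_wins(self):
        family = self._family_two_clusters(curated_cluster="b1")
        statuses = self._run(family, {"a1": 0.85, "a2": 0.85, "b1": 0.85})
        assert statuses["b1"] == "ortholog"
        assert statuses["a1"] == "paralog"

    def test_one_ortholog_cluster_per_taxon(self, rng):
        family = self._family_two_clusters()
        statuses = self._run(family, {"a1": 0.9, "a2": 0.6, "b1": 0.7})
        # a1/a2 share one cluster (0.95 row identity); that cluster wins
        orthologs = {s for s, st in statuses.items() if st == "ortholog"}
        assert orthologs == {"a1", "a2"} and statuses["b1"] == "paralog"


class TestFastBypass:
    def test_kmer_counts_equal_double_loop(self, rng):
        for _ in range(10):
            q = "".join(AMINO_ACIDS[i] for i in rng.choice(6, 20))
            s = "".join(AMINO_ACIDS[i] for i in rng.choice(6, 15))
            k = 3
            got = shared_kmer_score(q, s, k)
            qk = {q[i: i + k] for i in range(len(q) - k + 1)}
            shared = set()
            for i in range(len(q) - k + 1):
                for j in range(len(s) - k + 1):
                    if q[i: i + k] == s[j: j + k]:
                        shared.add(s[j: j + k])
            assert got == pytest.approx(len(qk & shared) / (len(s) - k + 1))

    def test_top_n_covering_clade_is_identity(self, sim_small):
        families, _ = sim_small
        family = families[0]
        members = family.alignment.row_ids
        q = _rec("q", family.sequences[members[0]].residues)
        config = op.preset("high_recall", fastcat=True, fastcat_top_n=10**6)
        assert op.fastcat_reduce(q, members, family, config) == sorted(members)

    def test_identical_member_ranked_first(self, sim_small):
        families, truth = sim_small
        family = families[0]
        members = family.alignment.row_ids
        target = members[0]
        q = _rec("q", family.sequences[target].residues)
        config = op.preset("high_recall", fastcat=True, fastcat_top_n=3,
                           fastcat_subtree_min=2)
        kept = op.fastcat_reduce(q, members, family, config)
        assert target in kept
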