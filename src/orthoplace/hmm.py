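"""Profile hidden Markov models over a shared family match-column mask.

Every subtree of a family tree gets its own profile, built from the alignment
rows under that subtree but always on the family's single match-column mask.
Because all models of a family therefore share the same coordinate system and
null model, their bit scores for one query are mutually comparable, which is
the premise behind classifying a query to the top-scoring subtree model.

Scores are log2-odds against a fixed amino-acid background. Two scoring modes
are provided: ``glocal`` (the full model must be traversed; the query flanks
are free) for families representing whole-protein homology, and ``local``
(free entry/exit at any match state) for domain families that match only a
region of a protein.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gumbel_r

from ._kernels import forward_logodds, viterbi_logodds
from .errors import CalibrationError
from .msa import BACKGROUND, FamilyAlignment, encode_residues

LN2 = math.log(2.0)

#: order of the nine transition types stored per model layer
TRANSITION_TYPES = ("MM", "MI", "MD", "IM", "II", "ID", "DM", "DD", "DI")


@dataclass(frozen=True)
class HMMScore:
    """Score of one query against one profile."""

    bit_score: float
    e_value: float | None
    query_span: tuple[int, int] | None  # 1-based inclusive, match-state emissions
    model_span: tuple[int, int] | None  # 1-based inclusive match columns
    query_coverage: float
    model_coverage: float


@dataclass(eq=False)
class ProfileHMM:
    n_match: int
    match_emissions: np.ndarray  # (k, 20)
    insert_emissions: np.ndarray  # (20,)
    transitions: np.ndarray  # (k, 9) probabilities, order TRANSITION_TYPES
    null_model: np.ndarray  # (20,)
    mean_train_len: float
    evd_mu: float | None = None
    evd_lambda: float | None = None
    db_size: int | None = None
    _em_lo: np.ndarray | None = field(default=None, repr=False)
    _tr_lo: np.ndarray | None = field(default=None, repr=False)

    @property
    def calibrated(self) -> bool:
        return self.evd_mu is not None and self.evd_lambda is not None

    def _log_tables(self) -> tuple[np.ndarray, np.ndarray]:
        if self._em_lo is None:
            k = self.n_match
            em = np.full((k + 1, 21), -np.inf)
            with np.errstate(divide="ignore"):
                em[1:, :20] = np.log(self.match_emissions) - np.log(self.null_model)
            em[1:, 20] = 0.0  # unknown residue X scores as background
            tr = np.full((k, 9), -np.inf)
            with np.errstate(divide="ignore"):
                np.log(self.transitions, out=tr, where=self.transitions > 0)
            tr[self.transitions <= 0] = -np.inf
            self._em_lo = em
            self._tr_lo = tr
        return self._em_lo, self._tr_lo

    def to_dict(self) -> dict:
        d = {
            "n_match": self.n_match,
            "match_emissions": self.match_emissions.tolist(),
            "insert_emissions": self.insert_emissions.tolist(),
            "transitions": self.transitions.tolist(),
            "null_model": self.null_model.tolist(),
            "mean_train_len": self.mean_train_len,
            "evd_mu": self.evd_mu,
            "evd_lambda": self.evd_lambda,
            "db_size": self.db_size,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProfileHMM":
        return cls(
            n_match=d["n_match"],
            match_emissions=np.array(d["match_emissions"]),
            insert_emissions=np.array(d["insert_emissions"]),
            transitions=np.array(d["transitions"]),
            null_model=np.array(d["null_model"]),
            mean_train_len=d["mean_train_len"],
            evd_mu=d.get("evd_mu"),
            evd_lambda=d.get("evd_lambda"),
            db_size=d.get("db_size"),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "ProfileHMM":
        return cls.from_dict(json.loads(s))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProfileHMM):
            return NotImplemented
        return (
            self.n_match == other.n_match
            and np.array_equal(self.match_emissions, other.match_emissions)
            and np.array_equal(self.transitions, other.transitions)
            and np.array_equal(self.null_model, other.null_model)
            and self.evd_mu == other.evd_mu
            and self.evd_lambda == other.evd_lambda
        )


def position_weights(enc: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Position-based (Henikoff) sequence weights over the match columns.

    Each match column distributes one unit of weight: a row holding residue
    ``a`` in a column with ``r`` distinct residues, ``n_a`` of them equal to
    ``a``, receives 1/(r * n_a). Weights are normalized to sum to one, so a
    duplicated row simply splits the weight of the original.
    """
    n = enc.shape[0]
    w = np.zeros(n)
    for col in np.flatnonzero(mask):
        residues = enc[:, col]
        present = residues >= 0
        vals = residues[present]
        if vals.size == 0:
            continue
        unique, counts = np.unique(vals, return_counts=True)
        r = len(unique)
        per_residue = {int(a): 1.0 / (r * int(c)) for a, c in zip(unique, counts)}
        for row in np.flatnonzero(present):
            w[row] += per_residue[int(residues[row])]
    if not (w > 0).any():
        w[:] = 1.0
    elif (w == 0).any():
        w[w == 0] = w[w > 0].min()
    return w / w.sum()


def _row_transition_counts(
    enc: np.ndarray, match_cols: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Weighted match/insert/delete path counts, one path per alignment row.

    Residues before the first and after the last match column belong to the
    free flanks and are not counted.
    """
    k = len(match_cols)
    counts = np.zeros((k, 9))
    n_cols = enc.shape[1]
    occupied = enc >= 0
    # residues strictly between consecutive match columns -> insert runs
    for row in range(enc.shape[0]):
        w = weights[row]
        present = occupied[row]
        state = 0  # 0 = M (B at layer 0), 2 = D
        for j in range(1, k + 1):
            nxt = 0 if present[match_cols[j - 1]] else 2
            if j >= 2:
                lo, hi = match_cols[j - 2] + 1, match_cols[j - 1]
                n_ins = int(present[lo:hi].sum()) if hi > lo else 0
            else:
                n_ins = 0  # leading flank
            row_idx = j - 1
            if n_ins > 0:
                counts[row_idx, 1 if state == 0 else 8] += w  # M->I or D->I
                counts[row_idx, 4] += w * (n_ins - 1)  # I->I
                counts[row_idx, 3 if nxt == 0 else 5] += w  # I->M or I->D
            else:
                if state == 0:
                    counts[row_idx, 0 if nxt == 0 else 2] += w
                else:
                    counts[row_idx, 6 if nxt == 0 else 7] += w
            state = nxt
    return counts


def build_profile_hmm(
    alignment: FamilyAlignment,
    row_subset: list[str] | None = None,
    pseudocount_alpha: float = 0.5,
) -> ProfileHMM:
    """Build a profile from the given alignment rows on the shared match mask.

    Match emissions are background-mixture pseudocounted weighted residue
    counts; transition probabilities come from the weighted match/insert/
    delete paths of the rows under the same pseudocount scheme. A single-row
    subset yields a pseudocounted point-mass model (leaf profiles are valid).
    """
    if alignment.match_mask is None:
        raise ValueError("alignment has no match_mask; run select_match_columns first")
    if pseudocount_alpha <= 0:
        raise ValueError("pseudocount_alpha must be positive")
    ids = alignment.row_ids if row_subset is None else list(row_subset)
    if not ids:
        raise ValueError("row_subset is empty")
    unknown = [r for r in ids if r not in alignment.row_ids]
    if unknown:
        raise ValueError(f"unknown row ids: {unknown}")
    idx = [alignment.row_index(r) for r in ids]
    enc = alignment.encoded[idx]
    mask = alignment.match_mask
    match_cols = np.flatnonzero(mask)
    k = len(match_cols)

    weights = position_weights(enc, mask)

    # match emissions: weighted counts mixed with the background
    emissions = np.empty((k, 20))
    for jj, col in enumerate(match_cols):
        residues = enc[:, col]
        counts = np.zeros(20)
        for row in np.flatnonzero((residues >= 0) & (residues < 20)):
            counts[residues[row]] += weights[row]
        total = counts.sum()
        emissions[jj] = (counts + pseudocount_alpha * BACKGROUND) / (
            total + pseudocount_alpha
        )

    t_counts = _row_transition_counts(enc, match_cols, weights)
    transitions = np.zeros((k, 9))
    for j in range(k):
        has_insert = 1 <= j <= k - 1  # I_j exists between layers j and j+1
        groups = [(0, 1, 2), (3, 4, 5), (6, 7, 8)]  # from M, I, D
        exists = [True, has_insert and j >= 1, j >= 1]
        for (a, b, c), src_ok in zip(groups, exists):
            if not src_ok:
                continue
            allowed = [a, c] + ([b] if has_insert else [])
            prior = pseudocount_alpha / len(allowed)
            row = np.zeros(3)
            vals = []
            for t in (a, b, c):
                if t in allowed:
                    vals.append(t_counts[j, t] + prior)
                else:
                    vals.append(0.0)
            vals = np.array(vals)
            transitions[j, [a, b, c]] = vals / vals.sum()

    mean_len = float((enc >= 0).sum(axis=1).mean())
    return ProfileHMM(
        n_match=k,
        match_emissions=emissions,
        insert_emissions=BACKGROUND.copy(),
        transitions=transitions,
        null_model=BACKGROUND.copy(),
        mean_train_len=mean_len,
    )


def _encode_query(residues: str) -> np.ndarray:
    enc = encode_residues(residues)
    if (enc < 0).any():
        raise ValueError("query residues must be ungapped")
    return enc.astype(np.int64)


def _query_emissions(hmm: ProfileHMM, enc: np.ndarray) -> np.ndarray:
    em_lo, _ = hmm._log_tables()
    out = np.empty((len(enc) + 1, hmm.n_match + 1))
    out[0] = -np.inf
    out[1:] = em_lo[:, enc].T
    return out


def forward_bits(hmm: ProfileHMM, residues: str, mode: str = "glocal") -> float:
    """Forward (all-path) log2-odds score of a query."""
    enc = _encode_query(residues)
    em = _query_emissions(hmm, enc)
    _, tr = hmm._log_tables()
    return float(forward_logodds(em, tr, mode == "local")) / LN2


def viterbi_bits(
    hmm: ProfileHMM, residues: str, mode: str = "glocal"
) -> tuple[float, tuple[int, int] | None, tuple[int, int] | None]:
    """Best-path log2-odds score plus 1-based query/model spans of match states."""
    enc = _encode_query(residues)
    em = _query_emissions(hmm, enc)
    _, tr = hmm._log_tables()
    score, q0, q1, m0, m1 = viterbi_logodds(em, tr, mode == "local")
    qspan = (int(q0), int(q1)) if q0 > 0 else None
    mspan = (int(m0), int(m1)) if m0 > 0 else None
    return float(score) / LN2, qspan, mspan


def evalue_from_bits(hmm: ProfileHMM, bits: float, db_size: int | None = None) -> float:
    """Expected number of hits at or above ``bits`` under the fitted Gumbel null."""
    if not hmm.calibrated:
        raise CalibrationError("profile is not calibrated")
    db = db_size if db_size is not None else (hmm.db_size or 1)
    return float(db * gumbel_r.sf(bits, loc=hmm.evd_mu, scale=1.0 / hmm.evd_lambda))


def random_null_sequence(rng: np.random.Generator, length: int) -> str:
    from .msa import AMINO_ACIDS

    idx = rng.choice(20, size=length, p=BACKGROUND)
    return "".join(AMINO_ACIDS[i] for i in idx)


def calibrate_evalue(
    hmm: ProfileHMM,
    n_random: int = 200,
    seed: int = 0,
    db_size: int = 1,
    mode: str = "glocal",
    length: int | None = None,
) -> ProfileHMM:
    """Fit a Gumbel null-score distribution by maximum likelihood.

    Scores ``n_random`` i.i.d. background sequences of the mean training
    length and stores the fitted location/scale on the profile. E-values are
    then ``db_size * P(S >= s)`` under the fit.
    """
    if n_random < 100:
        raise ValueError("n_random must be at least 100")
    rng = np.random.default_rng(seed)
    n = length if length is not None else max(1, round(hmm.mean_train_len))
    scores = np.array(
        [forward_bits(hmm, random_null_sequence(rng, n), mode) for _ in range(n_random)]
    )
    if not np.isfinite(scores).all() or scores.std() < 1e-9:
        raise CalibrationError("degenerate null score distribution")
    loc, scale = gumbel_r.fit(scores)
    if not np.isfinite(loc) or not np.isfinite(scale) or scale < 1e-9:
        raise CalibrationError("Gumbel fit failed")
    hmm.evd_mu = float(loc)
    hmm.evd_lambda = float(1.0 / scale)
    hmm.db_size = int(db_size)
    return hmm


def score_sequence(
    hmm: ProfileHMM,
    residues: str,
    mode: str = "glocal",
    db_size: int | None = None,
) -> HMMScore:
    """Score a query: forward bit score, Viterbi alignment spans, E-value.

    The bit score is the forward log2-odds (sums over all alignments); spans
    and coverages come from the single best (Viterbi) path. The E-value is
    present only on calibrated profiles.
    """
    if mode not in ("glocal", "local"):
        raise ValueError(f"unknown scoring mode {mode!r}")
    if not residues:
        raise ValueError("empty query")
    bits = forward_bits(hmm, residues, mode)
    _, qspan, mspan = viterbi_bits(hmm, residues, mode)
    L = len(residues)
    qcov = (qspan[1] - qspan[0] + 1) / L if qspan else 0.0
    mcov = (mspan[1] - mspan[0] + 1) / hmm.n_match if mspan else 0.0
    ev = evalue_from_bits(hmm, bits, db_size) if hmm.calibrated else None
    return HMMScore(
        bit_score=bits,
        e_value=ev,
        query_span=qspan,
        model_span=mspan,
        query_coverage=qcov,
        model_coverage=mcov,
    )
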