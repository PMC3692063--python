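"""Numba dynamic-programming kernels for profile-HMM scoring.

All arithmetic is natural-log odds against the background (null) model, so
insert-state emissions and the free query flanks contribute zero. The model is
a match/insert/delete chain: layer 0 is the begin state B (reachable at any
query offset because the N-flank is free and unpenalized), layers 1..k are the
match columns, I_j lives between layers j and j+1 (1 <= j <= k-1), and exit to
the free C-flank happens from layer k (glocal) or from any match state (local,
with entry probability 1/k spread over the k match states).

Transition array ``tr`` has shape (k, 9); row j holds the natural-log
probabilities of the nine transition types out of layer j, in the order
MM, MI, MD, IM, II, ID, DM, DD, DI. Emission array ``em`` has shape
(L+1, k+1); ``em[i, j]`` is the log-odds of query residue i (1-based) under
match state j.
"""

import numpy as np
from numba import njit

MM, MI, MD, IM, II, ID, DM, DD, DI = range(9)

_NEG = -np.inf


@njit(cache=False)
def _lse3(a, b, c):
    return np.logaddexp(np.logaddexp(a, b), c)


@njit(cache=False)
def forward_logodds(em, tr, local):
    """Forward (sum over all paths) natural-log odds score."""
    L = em.shape[0] - 1
    k = em.shape[1] - 1
    M = np.full((L + 1, k + 1), _NEG)
    I = np.full((L + 1, k + 1), _NEG)
    D = np.full((L + 1, k + 1), _NEG)
    entry = -np.log(k) if local else _NEG

    for i in range(L + 1):
        if i > 0:
            for j in range(1, k + 1):
                if j == 1:
                    a = _NEG if local else tr[0, MM]  # from B at offset i-1
                    b = _NEG
                    c = _NEG
                else:
                    a = M[i - 1, j - 1] + tr[j - 1, MM]
                    b = I[i - 1, j - 1] + tr[j - 1, IM]
                    c = D[i - 1, j - 1] + tr[j - 1, DM]
                best = _lse3(a, b, c)
                if local:
                    best = np.logaddexp(best, entry)
                M[i, j] = em[i, j] + best
            for j in range(1, k):
                I[i, j] = _lse3(
                    M[i - 1, j] + tr[j, MI],
                    I[i - 1, j] + tr[j, II],
                    D[i - 1, j] + tr[j, DI],
                )
        # delete chain at offset i (deletes are silent); local mode enters
        # only through match states, so B -> D1 exists only in glocal mode
        D[i, 1] = _NEG if local else tr[0, MD]
        for j in range(2, k + 1):
            D[i, j] = _lse3(
                M[i, j - 1] + tr[j - 1, MD],
                I[i, j - 1] + tr[j - 1, ID],
                D[i, j - 1] + tr[j - 1, DD],
            )

    total = _NEG
    if local:
        for i in range(1, L + 1):
            for j in range(1, k + 1):
                total = np.logaddexp(total, M[i, j])
    else:
        for i in range(L + 1):
            total = np.logaddexp(total, np.logaddexp(M[i, k], D[i, k]))
    return total


@njit(cache=False)
def viterbi_logodds(em, tr, local):
    """Best single path. Returns (score, q_start, q_end, m_start, m_end).

    Spans are 1-based inclusive over positions/columns emitted by match
    states; all four are 0 when the best path uses no match state. Ties are
    broken toward match-state predecessors (M before I before D before B).
    """
    L = em.shape[0] - 1
    k = em.shape[1] - 1
    M = np.full((L + 1, k + 1), _NEG)
    I = np.full((L + 1, k + 1), _NEG)
    D = np.full((L + 1, k + 1), _NEG)
    # predecessor codes: 0 = B (path starts), 1 = M, 2 = I, 3 = D
    pM = np.zeros((L + 1, k + 1), dtype=np.int8)
    pI = np.zeros((L + 1, k + 1), dtype=np.int8)
    pD = np.zeros((L + 1, k + 1), dtype=np.int8)
    entry = -np.log(k) if local else _NEG

    for i in range(L + 1):
        if i > 0:
            for j in range(1, k + 1):
                best = _NEG
                code = 0
                if j > 1:
                    best = M[i - 1, j - 1] + tr[j - 1, MM]
                    code = 1
                    v = I[i - 1, j - 1] + tr[j - 1, IM]
                    if v > best:
                        best = v
                        code = 2
                    v = D[i - 1, j - 1] + tr[j - 1, DM]
                    if v > best:
                        best = v
                        code = 3
                    if local and entry > best:
                        best = entry
                        code = 0
                else:
                    best = entry if local else tr[0, MM]
                    code = 0
                M[i, j] = em[i, j] + best
                pM[i, j] = code
            for j in range(1, k):
                best = M[i - 1, j] + tr[j, MI]
                code = 1
                v = I[i - 1, j] + tr[j, II]
                if v > best:
                    best = v
                    code = 2
                v = D[i - 1, j] + tr[j, DI]
                if v > best:
                    best = v
                    code = 3
                I[i, j] = best
                pI[i, j] = code
        D[i, 1] = _NEG if local else tr[0, MD]
        pD[i, 1] = 0
        for j in range(2, k + 1):
            best = M[i, j - 1] + tr[j - 1, MD]
            code = 1
            v = I[i, j - 1] + tr[j - 1, ID]
            if v > best:
                best = v
                code = 2
            v = D[i, j - 1] + tr[j - 1, DD]
            if v > best:
                best = v
                code = 3
            D[i, j] = best
            pD[i, j] = code

    # pick the best end point (prefer M over D, earliest offset on ties)
    best = _NEG
    ei = 0
    ej = 0
    estate = 1
    if local:
        for i in range(1, L + 1):
            for j in range(1, k + 1):
                if M[i, j] > best:
                    best = M[i, j]
                    ei, ej, estate = i, j, 1
    else:
        for i in range(L + 1):
            if M[i, k] > best:
                best = M[i, k]
                ei, ej, estate = i, k, 1
            if D[i, k] > best:
                best = D[i, k]
                ei, ej, estate = i, k, 3

    q0 = 0
    q1 = 0
    m0 = 0
    m1 = 0
    i, j, st = ei, ej, estate
    while True:
        if st == 1:
            if q1 == 0:
                q1 = i
                m1 = j
            q0 = i
            m0 = j
            code = pM[i, j]
            if code == 0:
                break
            i, j, st = i - 1, j - 1, code
        elif st == 2:
            code = pI[i, j]
            i, st = i - 1, code
        else:
            code = pD[i, j]
            if code == 0:
                break
            j, st = j - 1, code
    return best, q0, q1, m0, m1
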