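"""Numba dynamic-programming kernels.

Three hot loops live here: the hairpin fold fill (Nussinov-style with a
stacking bonus), the intermolecular duplex fill, and the affine-gap global
alignment used for pairwise similarity.  Tracebacks are done in Python in
the calling modules; the kernels only fill matrices.

Score scheme shared by fold and duplex (kcal/mol-like arbitrary units):
Watson-Crick pairs (A:T, G:C) contribute -1.0, wobble pairs (G:T) -0.5,
and every pair directly stacked on another pair earns a further -1.0.
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = 1e18

# Base codes: A=0, C=1, G=2, T=3
_CODE = np.full(128, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

PAIR_ENERGY = np.zeros((4, 4), dtype=np.float64)
PAIR_LEGAL = np.zeros((4, 4), dtype=np.bool_)
for _x, _y, _e in [(0, 3, -1.0), (3, 0, -1.0), (2, 1, -1.0), (1, 2, -1.0),
                   (2, 3, -0.5), (3, 2, -0.5)]:
    PAIR_ENERGY[_x, _y] = _e
    PAIR_LEGAL[_x, _y] = True

STACK_BONUS = -1.0
GAP_COLUMN_PENALTY = 0.5
MIN_HAIRPIN_LOOP = 3  # unpaired nt required inside the innermost loop

# Similarity scoring (EDNAFULL-style, pinned): match +5, mismatch -4,
# first gap column -10, each further gap column -0.5, end gaps free.
SIM_MATCH = 5.0
SIM_MISMATCH = -4.0
SIM_GAP_OPEN = -10.0
SIM_GAP_EXTEND = -0.5


def encode(residues: str) -> np.ndarray:
    codes = _CODE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        raise ValueError("non-ACGT residue in sequence")
    return codes


@njit(cache=True)
def fold_fill(codes, energy, legal):
    """Fill W/V/U for the hairpin fold.

    W[i,j]: minimum energy of any structure on codes[i..j].
    V[i,j]: minimum energy given (i,j) form a pair (INF if illegal).
    U[i,j]: minimum energy with i and j NOT mutually paired.
    Pairs require at least MIN_HAIRPIN_LOOP unpaired nt between them.
    """
    n = codes.shape[0]
    W = np.zeros((n, n))
    V = np.full((n, n), INF)
    U = np.zeros((n, n))
    for L in range(1, n):
        for i in range(0, n - L):
            j = i + L
            ci = codes[i]
            cj = codes[j]
            # V: i pairs j
            v = INF
            if L > MIN_HAIRPIN_LOOP and legal[ci, cj]:
                inner = U[i + 1, j - 1]
                if legal[codes[i + 1], codes[j - 1]] and V[i + 1, j - 1] < INF / 2:
                    stacked = V[i + 1, j - 1] + STACK_BONUS
                    if stacked < inner:
                        inner = stacked
                v = energy[ci, cj] + inner
            V[i, j] = v
            # U: i unpaired, or i pairs some k < j
            u = W[i + 1, j]
            for k in range(i + MIN_HAIRPIN_LOOP + 1, j):
                if legal[ci, codes[k]] and V[i, k] < INF / 2:
                    cand = V[i, k] + W[k + 1, j]
                    if cand < u:
                        u = cand
            U[i, j] = u
            W[i, j] = u if u < v else v
    return W, V, U


@njit(cache=True)
def duplex_fill(q, r, energy, legal):
    """Fill the intermolecular hybridization DP.

    q is the candidate 5'->3'; r is the *reversed* search region, so that
    consuming q and r in step models antiparallel pairing.  State axis:
    0 = previous column unpaired, 1 = previous column paired (stacking).
    D[s, i, j]: best energy consuming q[:i] and r[:j], region prefix free.
    Gap columns (a base on one strand bulged out) cost +GAP_COLUMN_PENALTY.
    """
    m = q.shape[0]
    n = r.shape[0]
    D = np.full((2, m + 1, n + 1), INF)
    for j in range(n + 1):
        D[0, 0, j] = 0.0  # alignment may start anywhere in the region
    for i in range(m + 1):
        for j in range(n + 1):
            for s in range(2):
                d = D[s, i, j]
                if d >= INF / 2:
                    continue
                if i < m and j < n:
                    qi = q[i]
                    rj = r[j]
                    if legal[qi, rj]:
                        val = d + energy[qi, rj]
                        if s == 1:
                            val += STACK_BONUS
                        if val < D[1, i + 1, j + 1]:
                            D[1, i + 1, j + 1] = val
                    else:
                        if d < D[0, i + 1, j + 1]:
                            D[0, i + 1, j + 1] = d
                if i < m:
                    val = d + GAP_COLUMN_PENALTY
                    if val < D[0, i + 1, j]:
                        D[0, i + 1, j] = val
                if j < n:
                    val = d + GAP_COLUMN_PENALTY
                    if val < D[0, i, j + 1]:
                        D[0, i, j + 1] = val
    return D


@njit(cache=True)
def _binary_entropy(p):
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return -(p * np.log(p) + (1.0 - p) * np.log(1.0 - p)) / np.log(2.0)


@njit(cache=True)
def best_split_kernel(X, y, w, orders, mask, min_cases):
    """Best gain-ratio threshold split over all attribute columns.

    X: (n, A) float64 full matrix (NaN = missing); y: int8 in {0,1};
    w: case weights; orders: (A, n) presorted row indices per column
    (NaN rows last); mask: bool row membership of the current node.
    Presorting is shared across nodes, trees and cross-validation folds,
    so each node costs one linear scan per attribute.

    Candidate thresholds are midpoints between consecutive distinct known
    values; a split qualifies if both branches carry >= min_cases weight
    and the information gain is positive.  Ties: higher gain, then lower
    attribute index, then lower threshold.  Returns (attr, threshold,
    ratio, gain); attr = -1 when no admissible split exists.
    """
    n, A = X.shape
    best_attr = -1
    best_thr = 0.0
    best_ratio = -INF
    best_gain = -INF
    buf = np.empty(n, dtype=np.int64)
    for a in range(A):
        cnt = 0
        W = 0.0
        W1 = 0.0
        for k in range(n):
            i = orders[a, k]
            if not mask[i]:
                continue
            if np.isnan(X[i, a]):
                break  # NaN rows sort last; nothing known remains
            buf[cnt] = i
            cnt += 1
            W += w[i]
            if y[i] == 1:
                W1 += w[i]
        if cnt < 2:
            continue
        h_node = _binary_entropy(W1 / W)
        wl = 0.0
        wl1 = 0.0
        for k in range(cnt - 1):
            i = buf[k]
            wl += w[i]
            if y[i] == 1:
                wl1 += w[i]
            xk = X[i, a]
            xk1 = X[buf[k + 1], a]
            if xk >= xk1:
                continue  # not a boundary between distinct values
            wr = W - wl
            if wl < min_cases or wr < min_cases:
                continue
            gain = h_node - (
                wl * _binary_entropy(wl1 / wl) + wr * _binary_entropy((W1 - wl1) / wr)
            ) / W
            if gain <= 1e-12:
                continue
            split_info = _binary_entropy(wl / W)
            if split_info <= 1e-12:
                continue
            ratio = gain / split_info
            if ratio > best_ratio + 1e-12 or (
                ratio > best_ratio - 1e-12 and gain > best_gain + 1e-12
            ):
                best_ratio = ratio
                best_gain = gain
                best_attr = a
                best_thr = (xk + xk1) / 2.0
    return best_attr, best_thr, best_ratio, best_gain


@njit(cache=True)
def _sim_better(s1, i1, l1, s2, i2, l2):
    """Lexicographic alignment preference: score, then identities, then
    shorter alignment.  Scores are multiples of 0.5 so exact comparison
    with a small epsilon is safe."""
    if s1 > s2 + 1e-9:
        return True
    if s1 < s2 - 1e-9:
        return False
    if i1 != i2:
        return i1 > i2
    return l1 < l2


@njit(cache=True)
def similarity_pair(a, b):
    """Global affine-gap alignment similarity of two coded sequences.

    Returns 100 * identities / alignment_length for the alignment that
    maximizes (score, identities, -length) lexicographically.  End gaps
    are free (needle's endweight=false behaviour) but still count toward
    the alignment length.
    States: 0 = diagonal, 1 = gap in b (consumes a), 2 = gap in a.
    """
    m = a.shape[0]
    n = b.shape[0]
    S = np.full((3, m + 1, n + 1), -INF)
    ID = np.zeros((3, m + 1, n + 1), dtype=np.int64)
    AL = np.zeros((3, m + 1, n + 1), dtype=np.int64)
    S[0, 0, 0] = 0.0
    for i in range(m + 1):
        for j in range(n + 1):
            if i == 0 and j == 0:
                continue
            # state 0: consume a[i-1], b[j-1]
            if i > 0 and j > 0:
                sub = SIM_MATCH if a[i - 1] == b[j - 1] else SIM_MISMATCH
                ident = 1 if a[i - 1] == b[j - 1] else 0
                for p in range(3):
                    sp = S[p, i - 1, j - 1]
                    if sp <= -INF / 2:
                        continue
                    ns = sp + sub
                    ni = ID[p, i - 1, j - 1] + ident
                    nl = AL[p, i - 1, j - 1] + 1
                    if _sim_better(ns, ni, nl, S[0, i, j], ID[0, i, j], AL[0, i, j]):
                        S[0, i, j] = ns
                        ID[0, i, j] = ni
                        AL[0, i, j] = nl
            # state 1: gap in b, consume a[i-1]; free when b untouched/spent
            if i > 0:
                free = j == 0 or j == n
                for p in range(3):
                    sp = S[p, i - 1, j]
                    if sp <= -INF / 2:
                        continue
                    if free:
                        cost = 0.0
                    elif p == 1:
                        cost = SIM_GAP_EXTEND
                    else:
                        cost = SIM_GAP_OPEN
                    ns = sp + cost
                    ni = ID[p, i - 1, j]
                    nl = AL[p, i - 1, j] + 1
                    if _sim_better(ns, ni, nl, S[1, i, j], ID[1, i, j], AL[1, i, j]):
                        S[1, i, j] = ns
                        ID[1, i, j] = ni
                        AL[1, i, j] = nl
            # state 2: gap in a, consume b[j-1]; free when a untouched/spent
            if j > 0:
                free = i == 0 or i == m
                for p in range(3):
                    sp = S[p, i, j - 1]
                    if sp <= -INF / 2:
                        continue
                    if free:
                        cost = 0.0
                    elif p == 2:
                        cost = SIM_GAP_EXTEND
                    else:
                        cost = SIM_GAP_OPEN
                    ns = sp + cost
                    ni = ID[p, i, j - 1]
                    nl = AL[p, i, j - 1] + 1
                    if _sim_better(ns, ni, nl, S[2, i, j], ID[2, i, j], AL[2, i, j]):
                        S[2, i, j] = ns
                        ID[2, i, j] = ni
                        AL[2, i, j] = nl
    bs = S[0, m, n]
    bi = ID[0, m, n]
    bl = AL[0, m, n]
    for p in range(1, 3):
        if _sim_better(S[p, m, n], ID[p, m, n], AL[p, m, n], bs, bi, bl):
            bs = S[p, m, n]
            bi = ID[p, m, n]
            bl = AL[p, m, n]
    if bl == 0:
        return 0.0
    return 100.0 * bi / bl


@njit(cache=True)
def similarity_matrix_kernel(codes, lengths):
    """All-pairs similarity for a pool of coded sequences.

    codes: (n, maxlen) int8 matrix, right-padded; lengths: (n,) int64.
    Returns a symmetric float64 matrix with exact 100.0 on the diagonal.
    """
    n = codes.shape[0]
    out = np.empty((n, n))
    for i in range(n):
        out[i, i] = 100.0
        for j in range(i + 1, n):
            s = similarity_pair(codes[i, : lengths[i]], codes[j, : lengths[j]])
            out[i, j] = s
            out[j, i] = s
    return out
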