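"""Independent brute-force oracles for the dynamic-programming routines.

Everything here is written from the score definitions alone -- exhaustive
enumeration (or plain top-down recursion) rather than the production
bottom-up matrices -- so agreement is a real check on both sides.
"""

from __future__ import annotations

from functools import lru_cache

PAIR_E = {
    ("A", "T"): -1.0,
    ("T", "A"): -1.0,
    ("G", "C"): -1.0,
    ("C", "G"): -1.0,
    ("G", "T"): -0.5,
    ("T", "G"): -0.5,
}
STACK = -1.0
GAP = 0.5
MIN_LOOP = 3


def _legal(a: str, b: str) -> bool:
    return (a, b) in PAIR_E


# ---------------------------------------------------------------------------
# Hairpin fold: enumerate every legal structure, score it, take the minimum.


def enumerate_structures(seq: str):
    """Yield every non-crossing pair set with hairpin loops >= MIN_LOOP."""

    def enum(i: int, j: int):
        if i >= j:
            yield frozenset()
            return
        for rest in enum(i + 1, j):
            yield rest
        for k in range(i + MIN_LOOP + 1, j + 1):
            if _legal(seq[i], seq[k]):
                for left in enum(i + 1, k - 1):
                    for right in enum(k + 1, j):
                        yield left | right | {(i, k)}

    yield from enum(0, len(seq) - 1)


def score_structure(seq: str, pairs: frozenset) -> float:
    total = 0.0
    for i, j in pairs:
        total += PAIR_E[(seq[i], seq[j])]
        if (i + 1, j - 1) in pairs:
            total += STACK
    return total


def fold_oracle(seq: str) -> float:
    """Minimum energy over all legal structures (0 = unpaired)."""
    return min(score_structure(seq, s) for s in enumerate_structures(seq))


# ---------------------------------------------------------------------------
# Duplex: top-down recursion over all alignments of the query against the
# reversed region, free region prefix/suffix, antiparallel pairing.


def duplex_oracle(query: str, region: str, memo: bool = True) -> float:
    """Minimum hybridization energy of query against any part of region."""
    r = region[::-1]
    m, n = len(query), len(r)

    def rec(i: int, j: int, prev_paired: bool) -> float:
        if i == m:
            return 0.0  # remaining region is free
        best = GAP + rec(i + 1, j, False)  # query base bulged
        if j < n:
            if _legal(query[i], r[j]):
                e = PAIR_E[(query[i], r[j])] + (STACK if prev_paired else 0.0)
                best = min(best, e + rec(i + 1, j + 1, True))
            else:
                best = min(best, rec(i + 1, j + 1, False))
            best = min(best, GAP + rec(i, j + 1, False))  # region base bulged
        return best

    if memo:
        rec = lru_cache(maxsize=None)(rec)
    return min(rec(0, j0, False) for j0 in range(n + 1))


# ---------------------------------------------------------------------------
# Similarity: enumerate every global alignment under the pinned scoring
# (match +5, mismatch -4, gap 10 + 0.5/extra column, end gaps free) and
# report identities/length of the lexicographically best alignment.


def similarity_oracle(a: str, b: str) -> float:
    best = None
    la, lb = len(a), len(b)

    def rec(i, j, state, score, ident, length):
        nonlocal best
        if i == la and j == lb:
            cand = (score, ident, -length)
            if best is None or cand > best:
                best = cand
            return
        if i < la and j < lb:
            match = a[i] == b[j]
            rec(
                i + 1,
                j + 1,
                0,
                score + (5.0 if match else -4.0),
                ident + int(match),
                length + 1,
            )
        if i < la:  # gap in b
            free = j == 0 or j == lb
            cost = 0.0 if free else (-0.5 if state == 1 else -10.0)
            rec(i + 1, j, 1, score + cost, ident, length + 1)
        if j < lb:  # gap in a
            free = i == 0 or i == la
            cost = 0.0 if free else (-0.5 if state == 2 else -10.0)
            rec(i, j + 1, 2, score + cost, ident, length + 1)

    rec(0, 0, None, 0.0, 0, 0)
    _score, ident, neg_len = best
    return 100.0 * ident / (-neg_len)


# ---------------------------------------------------------------------------
# Gain ratio: exhaustive re-scan of every candidate threshold split.


def gain_ratio_oracle(values, labels, weights=None, min_cases=2.0):
    """All admissible (threshold, gain_ratio, gain) splits of one numeric
    attribute, brute force.  ``values`` may not contain missing entries."""
    import math

    if weights is None:
        weights = [1.0] * len(values)

    def entropy(pairs):
        total = sum(w for w, _ in pairs)
        w1 = sum(w for w, yy in pairs if yy == 1)
        p = w1 / total
        if p <= 0 or p >= 1:
            return 0.0
        return -(p * math.log2(p) + (1 - p) * math.log2(1 - p))

    data = sorted(zip(values, labels, weights))
    xs = sorted(set(values))
    out = []
    full = [(w, yy) for _v, yy, w in data]
    h = entropy(full)
    W = sum(w for w, _ in full)
    for lo, hi in zip(xs, xs[1:]):
        thr = (lo + hi) / 2.0
        left = [(w, yy) for v, yy, w in data if v <= thr]
        right = [(w, yy) for v, yy, w in data if v > thr]
        wl = sum(w for w, _ in left)
        wr = sum(w for w, _ in right)
        if wl < min_cases or wr < min_cases:
            continue
        gain = h - (wl * entropy(left) + wr * entropy(right)) / W
        if gain <= 1e-12:
            continue
        fl = wl / W
        split_info = -(fl * math.log2(fl) + (1 - fl) * math.log2(1 - fl))
        out.append((thr, gain / split_info, gain))
    return out
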