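"""Pairwise global-alignment similarity and exclusion sets.

Leave-one-out validation is only honest if sequences nearly identical to
the held-out case are also kept out of training.  Similarity here is the
percent identity of a global Needleman-Wunsch alignment over its full
length (gaps included), with pinned scoring: match +5, mismatch -4
(EDNAFULL diagonal/off-diagonal), gap open 10 for the first gap column and
0.5 for each further column, end gaps free.  Among score-optimal
alignments, the one with the most identities (then the shortest) defines
the reported value; this makes the measure deterministic and exactly
invariant under argument swap and joint reverse complementation.

Exclusion is pairwise, deliberately NOT transitive clustering: if A~B and
B~C but A and C are dissimilar, A's exclusion set is {A, B} only.  Single-
linkage clusters do not guarantee that members of different clusters are
dissimilar, which is exactly the failure mode this design avoids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import _dp
from .seqio import reverse_complement


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric percent-similarity matrix over a pool of sequences."""

    ids: tuple[str, ...]
    values: np.ndarray  # (n, n) float64 percentages

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")


def global_similarity(a: str, b: str) -> float:
    """Percent similarity of two sequences (see module docstring)."""
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    return float(_dp.similarity_pair(_dp.encode(a), _dp.encode(b)))


def _code_matrix(seqs: Sequence[str]):
    n = len(seqs)
    maxlen = max(len(s) for s in seqs)
    codes = np.zeros((n, maxlen), dtype=np.int8)
    lengths = np.zeros(n, dtype=np.int64)
    for i, s in enumerate(seqs):
        codes[i, : len(s)] = _dp.encode(s)
        lengths[i] = len(s)
    return codes, lengths


def similarity_matrix(seqs: Mapping[str, str]) -> SimilarityMatrix:
    """All-pairs similarity for a pool (each pair computed once)."""
    ids = tuple(seqs)
    if not ids:
        raise ValueError("at least one sequence required")
    codes, lengths = _code_matrix([seqs[i] for i in ids])
    values = _dp.similarity_matrix_kernel(codes, lengths)
    return SimilarityMatrix(ids=ids, values=values)


def exclusion_sets(
    matrix: SimilarityMatrix, threshold: float = 70.0
) -> dict[str, set[str]]:
    """Per-id exclusion sets: every id whose similarity exceeds the
    threshold, plus the id itself (reflexive, symmetric, non-transitive)."""
    if not 0.0 < threshold < 100.0:
        raise ValueError("threshold must be in (0, 100)")
    out: dict[str, set[str]] = {i: {i} for i in matrix.ids}
    over = np.argwhere(matrix.values > threshold)
    for i, j in over:
        if i != j:
            out[matrix.ids[i]].add(matrix.ids[j])
    return out


def build_exclusion(
    pools: Sequence[Mapping[str, str]], threshold: float = 70.0
) -> dict[str, set[str]]:
    """Exclusion sets over several pools aligned separately.

    Positive and negative controls are pooled separately for pairwise
    alignment, matching how the control sets are screened; pass e.g.
    ``[positive_seqs, negative_seqs]``.
    """
    exclusion: dict[str, set[str]] = {}
    for pool in pools:
        if pool:
            exclusion.update(exclusion_sets(similarity_matrix(pool), threshold))
    return exclusion


def write_similarity_tsv(matrix: SimilarityMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(matrix.ids) + "\n")
        for i, sid in enumerate(matrix.ids):
            row = "\t".join(repr(float(v)) for v in matrix.values[i])
            fh.write(f"{sid}\t{row}\n")


def write_exclusion_edges(exclusion: Mapping[str, set[str]], path) -> None:
    """Two-column edge list of mutually exclusive pairs (self-edges omitted)."""
    with open(path, "w") as fh:
        for a in sorted(exclusion):
            for b in sorted(exclusion[a]):
                if a < b:
                    fh.write(f"{a}\t{b}\n")
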