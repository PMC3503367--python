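"""RNA energetics: folding, duplex scanning and operative precursor regions.

The pipeline needs two thermodynamic primitives: folding a putative
precursor into a stem-loop (dot-bracket structure + minimum free energy)
and hybridizing a short candidate against a genomic window to locate its
best-binding star partner.  Both are defined here behind the
:class:`EnergyModel` contract with two implementations:

* :class:`BuiltinEnergyModel` -- a deterministic base-pair-maximization
  model (Nussinov-style dynamic programming with a stacking bonus, pinned
  scores in :mod:`plantmir._dp`).  It is self-contained, fast and exactly
  reproducible, and is what the test-suite and the synthetic benchmark use.
* :class:`ViennaEnergyModel` -- an optional adapter shelling out to the
  ViennaRNA ``RNAfold``/``RNAduplex`` binaries for full nearest-neighbour
  energetics when they are on PATH.  Column strings from this adapter are
  reconstructed from the query-side structure only.

The operative precursor region (OPR) is the span between and including the
candidate and its best-binding star, plus a fixed flank (default 15 nt) on
both sides, clipped at the context boundaries.  It stands in for the real
precursor so that positives, negatives and unknowns are treated alike.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from dataclasses import dataclass, field

import numpy as np

from . import _dp
from .errors import NoDuplexError, StructureError, WindowError
from .seqio import normalize_rna

log = logging.getLogger(__name__)

UPSTREAM_STAR = "upstream_star"
DOWNSTREAM_STAR = "downstream_star"
SIDES = (UPSTREAM_STAR, DOWNSTREAM_STAR)

_TOL = 1e-9


@dataclass(frozen=True)
class DuplexHit:
    """Best candidate:star hybridization found in a searched region.

    ``star_start``/``star_end`` are 0-based half-open coordinates (within
    the region for raw duplex calls, within the full context for
    :func:`find_best_star` results).  ``columns`` records the per-column
    state of the duplex alignment along the candidate: ``|`` for a paired
    column, ``.`` for a mismatch or a bulged base (gaps are not
    distinguished from mismatches).
    """

    star_start: int
    star_end: int
    energy: float
    columns: str
    query_len: int
    star_len: int
    side: str | None = None

    def __post_init__(self) -> None:
        if self.star_end <= self.star_start:
            raise ValueError("empty star span")
        if self.energy > 0:
            raise ValueError("duplex energy must be <= 0")
        if self.columns.count("|") > min(self.query_len, self.star_len):
            raise ValueError("more paired columns than the shorter strand")


@dataclass(frozen=True)
class HairpinStructure:
    """An OPR with its fold: sequence, dot-bracket and minimum free energy."""

    sequence: str
    dot_bracket: str
    mfe: float
    candidate_span: tuple[int, int]
    star_span: tuple[int, int]
    flank: int = 15

    def __post_init__(self) -> None:
        if len(self.dot_bracket) != len(self.sequence):
            raise ValueError("structure/sequence length mismatch")
        cs, ce = self.candidate_span
        ss, se = self.star_span
        if not (ce <= ss or se <= cs):
            raise ValueError("candidate and star spans overlap")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable geometry and training knobs for the whole pipeline.

    ``search_window`` bounds the candidate-plus-star span (300 nt covers
    95.8% of known plant precursors); ``flank`` pads the OPR on both sides;
    ``min_loop_gap`` keeps the star at least one minimal hairpin loop away
    from the candidate; ``similarity_threshold`` (percent) marks sequences
    as mutually exclusive for cross-validation.
    """

    search_window: int = 300
    flank: int = 15
    min_loop_gap: int = 3
    similarity_threshold: float = 70.0
    scan_lengths: tuple[int, ...] = (20, 21, 22, 23, 24)
    boosting_trials: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.flank < 0:
            raise ValueError("flank must be >= 0")
        if self.search_window < 2 * max(self.scan_lengths) + self.min_loop_gap:
            raise ValueError(
                "search_window too small to host candidate, loop and star"
            )


# ---------------------------------------------------------------------------
# Built-in energy model


def _check_balanced(db: str) -> None:
    depth = 0
    for ch in db:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise StructureError("unbalanced dot-bracket")
        elif ch != ".":
            raise StructureError(f"bad structure character {ch!r}")
    if depth != 0:
        raise StructureError("unbalanced dot-bracket")


def _fold_traceback(codes, W, V, U) -> str:
    n = len(codes)
    E, LEGAL = _dp.PAIR_ENERGY, _dp.PAIR_LEGAL
    db = ["."] * n
    stack = [("W", 0, n - 1)]
    while stack:
        kind, i, j = stack.pop()
        if i >= j:
            continue
        if kind == "W":
            if (
                j - i > _dp.MIN_HAIRPIN_LOOP
                and LEGAL[codes[i], codes[j]]
                and abs(W[i, j] - V[i, j]) < _TOL
            ):
                stack.append(("V", i, j))
            else:
                stack.append(("U", i, j))
        elif kind == "U":
            target = U[i, j]
            placed = False
            for k in range(i + _dp.MIN_HAIRPIN_LOOP + 1, j):
                if LEGAL[codes[i], codes[k]] and V[i, k] < _dp.INF / 2:
                    if abs(V[i, k] + W[k + 1, j] - target) < _TOL:
                        stack.append(("V", i, k))
                        stack.append(("W", k + 1, j))
                        placed = True
                        break
            if not placed:
                stack.append(("W", i + 1, j))
        else:  # V: i pairs j
            db[i] = "("
            db[j] = ")"
            e = E[codes[i], codes[j]]
            ii, jj = i + 1, j - 1
            if (
                jj - ii > _dp.MIN_HAIRPIN_LOOP
                and LEGAL[codes[ii], codes[jj]]
                and V[ii, jj] < _dp.INF / 2
                and abs(V[i, j] - (e + V[ii, jj] + _dp.STACK_BONUS)) < _TOL
            ):
                stack.append(("V", ii, jj))
            elif ii < jj:
                stack.append(("U", ii, jj))
    return "".join(db)


def _duplex_traceback(q, r, D, end_state, end_j):
    """Walk back from (end_state, m, end_j); return (columns, j_start)."""
    E, LEGAL = _dp.PAIR_ENERGY, _dp.PAIR_LEGAL
    i = len(q)
    j = end_j
    s = end_state
    cols: list[str] = []
    while i > 0:
        d = D[s, i, j]
        if s == 1:
            e = E[q[i - 1], r[j - 1]]
            moved = False
            for p in (1, 0):
                stackpart = _dp.STACK_BONUS if p == 1 else 0.0
                if abs(D[p, i - 1, j - 1] + e + stackpart - d) < _TOL:
                    cols.append("|")
                    i, j, s = i - 1, j - 1, p
                    moved = True
                    break
            if not moved:  # pragma: no cover - defensive
                raise AssertionError("duplex traceback failed (paired state)")
            continue
        moved = False
        if i > 0 and j > 0 and not LEGAL[q[i - 1], r[j - 1]]:
            for p in (1, 0):
                if abs(D[p, i - 1, j - 1] - d) < _TOL:
                    cols.append(".")
                    i, j, s = i - 1, j - 1, p
                    moved = True
                    break
        if moved:
            continue
        for p in (1, 0):  # query base bulged
            if abs(D[p, i - 1, j] + _dp.GAP_COLUMN_PENALTY - d) < _TOL:
                cols.append(".")
                i, s = i - 1, p
                moved = True
                break
        if moved:
            continue
        for p in (1, 0):  # star base bulged
            if j > 0 and abs(D[p, i, j - 1] + _dp.GAP_COLUMN_PENALTY - d) < _TOL:
                cols.append(".")
                j, s = j - 1, p
                moved = True
                break
        if not moved:  # pragma: no cover - defensive
            raise AssertionError("duplex traceback failed")
    return "".join(reversed(cols)), j


class BuiltinEnergyModel:
    """Deterministic base-pair maximization energetics (see module docs)."""

    model_name = "builtin-stacked-nussinov"

    def fold(self, seq: str) -> tuple[str, float]:
        """Fold a sequence; returns (dot_bracket, mfe).  mfe <= 0, with 0
        for the fully unpaired structure."""
        codes = _dp.encode(seq)
        n = len(codes)
        if n <= _dp.MIN_HAIRPIN_LOOP + 1:
            return "." * n, 0.0
        W, V, U = _dp.fold_fill(codes, _dp.PAIR_ENERGY, _dp.PAIR_LEGAL)
        db = _fold_traceback(codes, W, V, U)
        _check_balanced(db)
        return db, float(W[0, n - 1])

    def duplex_hits(self, query: str, region: str) -> list[DuplexHit]:
        """All co-optimal duplex hits of query against region.

        Coordinates are region-local, 0-based half-open; hits are sorted by
        (star_start, star_end).  Raises :class:`NoDuplexError` when no
        alignment with energy < 0 exists.
        """
        if len(region) < len(query):
            raise WindowError("region shorter than query")
        q = _dp.encode(query)
        rrev = _dp.encode(region)[::-1].copy()
        D = _dp.duplex_fill(q, rrev, _dp.PAIR_ENERGY, _dp.PAIR_LEGAL)
        m, n = len(q), len(rrev)
        best = float(D[:, m, :].min())
        if best >= -_TOL:
            raise NoDuplexError("no hybridization with negative energy")
        hits = []
        for end_j in range(n + 1):
            for s in (1, 0):
                if abs(D[s, m, end_j] - best) < _TOL:
                    cols, j_start = _duplex_traceback(q, rrev, D, s, end_j)
                    star_start = n - end_j
                    star_end = n - j_start
                    if star_end <= star_start:
                        continue
                    hits.append(
                        DuplexHit(
                            star_start=star_start,
                            star_end=star_end,
                            energy=best,
                            columns=cols,
                            query_len=m,
                            star_len=star_end - star_start,
                        )
                    )
                    break  # one traceback per end column
        hits.sort(key=lambda h: (h.star_start, h.star_end))
        return hits

    def duplex(self, query: str, region: str) -> DuplexHit:
        """Minimum-energy hit; ties broken by smaller star_start, then
        smaller star_end."""
        return self.duplex_hits(query, region)[0]


# ---------------------------------------------------------------------------
# Optional ViennaRNA adapter


class ViennaEnergyModel:
    """Adapter to the ViennaRNA ``RNAfold``/``RNAduplex`` executables.

    Provides full nearest-neighbour thermodynamics when the binaries are on
    PATH; intended for real-data runs, not used by the synthetic benchmark.
    """

    model_name = "viennarna"

    def __init__(self) -> None:
        if not self.available():
            raise RuntimeError("RNAfold/RNAduplex not found on PATH")

    @staticmethod
    def available() -> bool:
        return bool(shutil.which("RNAfold")) and bool(shutil.which("RNAduplex"))

    def fold(self, seq: str) -> tuple[str, float]:
        out = subprocess.run(
            ["RNAfold", "--noPS"],
            input=seq + "\n",
            capture_output=True,
            text=True,
            check=True,
        ).stdout.splitlines()
        structure_line = out[1]
        db = structure_line.split(" ", 1)[0].strip()
        mfe = float(structure_line.rsplit("(", 1)[1].rstrip(")").strip())
        return db, min(mfe, 0.0)

    def duplex(self, query: str, region: str) -> DuplexHit:
        out = subprocess.run(
            ["RNAduplex"],
            input=f"{query}\n{region}\n",
            capture_output=True,
            text=True,
            check=True,
        ).stdout.strip().splitlines()[-1]
        # e.g. ".((((&)))).  1,5  :  3,7  (-5.40)"
        parts = out.split()
        struct_q = parts[0].split("&")[0]
        t_from, t_to = (int(x) for x in parts[3].split(","))
        energy = float(parts[-1].strip("()"))
        if energy >= 0:
            raise NoDuplexError("RNAduplex found no stable duplex")
        cols = "".join("|" if ch in "()" else "." for ch in struct_q)
        return DuplexHit(
            star_start=t_from - 1,
            star_end=t_to,
            energy=energy,
            columns=cols,
            query_len=len(query),
            star_len=t_to - t_from + 1,
        )

    def duplex_hits(self, query: str, region: str) -> list[DuplexHit]:
        return [self.duplex(query, region)]


DEFAULT_MODEL = BuiltinEnergyModel()


def builtin_fold(seq: str) -> tuple[str, float]:
    return DEFAULT_MODEL.fold(seq)


def builtin_duplex(query: str, region: str) -> DuplexHit:
    return DEFAULT_MODEL.duplex(query, region)


# ---------------------------------------------------------------------------
# Star discovery and OPR construction


def find_best_star(
    candidate: str,
    context: str,
    candidate_offset: int,
    side: str,
    config: PipelineConfig = PipelineConfig(),
    model=DEFAULT_MODEL,
) -> DuplexHit:
    """Locate the star partner with the strongest duplex binding.

    The search window is anchored at the candidate's far edge and extends
    ``config.search_window`` nt in the star's direction, so candidate, loop
    and star together fit inside the window.  Positions closer than
    ``min_loop_gap`` to the candidate are excluded.  Ties in energy are
    broken by the smaller candidate-star gap, then the smaller star start.
    Returned coordinates are context-local.
    """
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}")
    cs = candidate_offset
    ce = cs + len(candidate)
    if context[cs:ce] != candidate:
        raise ValueError("candidate does not occur at the stated offset")
    need = len(candidate) + config.min_loop_gap
    if side == DOWNSTREAM_STAR:
        if len(context) - ce < need:
            raise WindowError("not enough context downstream of candidate")
        region_start = ce + config.min_loop_gap
        region_end = min(len(context), cs + config.search_window)
    else:
        if cs < need:
            raise WindowError("not enough context upstream of candidate")
        region_start = max(0, ce - config.search_window)
        region_end = cs - config.min_loop_gap
    region = context[region_start:region_end]
    if len(region) < len(candidate):
        raise WindowError("search region shorter than candidate")
    hits = model.duplex_hits(candidate, region)

    def keyfun(h: DuplexHit):
        start = h.star_start + region_start
        end = h.star_end + region_start
        gap = (start - ce) if side == DOWNSTREAM_STAR else (cs - end)
        return (gap, start)

    best = min(hits, key=keyfun)
    return DuplexHit(
        star_start=best.star_start + region_start,
        star_end=best.star_end + region_start,
        energy=best.energy,
        columns=best.columns,
        query_len=best.query_len,
        star_len=best.star_len,
        side=side,
    )


def build_opr(
    candidate: str,
    candidate_offset: int,
    hit: DuplexHit,
    context: str,
    config: PipelineConfig = PipelineConfig(),
    model=DEFAULT_MODEL,
) -> HairpinStructure:
    """Extract and fold the operative precursor region around candidate+star."""
    cs = candidate_offset
    ce = cs + len(candidate)
    start = min(cs, hit.star_start) - config.flank
    end = max(ce, hit.star_end) + config.flank
    if start < 0 or end > len(context):
        log.debug("OPR clipped at context boundary (%d..%d)", start, end)
    start = max(0, start)
    end = min(len(context), end)
    opr_seq = context[start:end]
    db, mfe = model.fold(opr_seq)
    return HairpinStructure(
        sequence=opr_seq,
        dot_bracket=db,
        mfe=mfe,
        candidate_span=(cs - start, ce - start),
        star_span=(hit.star_start - start, hit.star_end - start),
        flank=config.flank,
    )


# ---------------------------------------------------------------------------
# Structure and duplex statistics


def structure_runs(dot_bracket: str) -> tuple[int, int, int]:
    """(longest '.' run, longest same-bracket run, hairpin loop head count).

    A loop head is a maximal run of dots immediately flanked by ``(`` on the
    left and ``)`` on the right.  The caller normalizes all three by OPR
    length to obtain longestDotSet, longestBracketSet and loopCountNorm.
    """
    _check_balanced(dot_bracket)
    longest_dot = longest_bracket = 0
    heads = 0
    i = 0
    n = len(dot_bracket)
    while i < n:
        ch = dot_bracket[i]
        j = i
        while j < n and dot_bracket[j] == ch:
            j += 1
        run = j - i
        if ch == ".":
            longest_dot = max(longest_dot, run)
            if i > 0 and j < n and dot_bracket[i - 1] == "(" and dot_bracket[j] == ")":
                heads += 1
        else:
            longest_bracket = max(longest_bracket, run)
        i = j
    return longest_dot, longest_bracket, heads


def duplex_metrics(hit: DuplexHit) -> tuple[int, float, float]:
    """(MaxMismatch, minMatchPercent, DuplexEnergyNorm) for a duplex hit.

    MaxMismatch is the longest run of unpaired columns (bulges included);
    minMatchPercent relates the paired-column count to the longer strand;
    DuplexEnergyNorm divides the energy by the number of alignment columns.
    """
    cols = hit.columns
    max_mismatch = max((len(r) for r in cols.split("|")), default=0)
    matches = cols.count("|")
    min_match_percent = 100.0 * matches / max(hit.query_len, hit.star_len)
    energy_norm = hit.energy / len(cols)
    return max_mismatch, min_match_percent, energy_norm


def write_structure_file(structures, path) -> None:
    """Write OPRs in RNAfold's output dialect: header, sequence line, then
    the dot-bracket with the energy in parentheses."""
    with open(path, "w") as fh:
        for sid, hp in structures:
            fh.write(f">{sid}\n{hp.sequence}\n{hp.dot_bracket} ({hp.mfe:.1f})\n")
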