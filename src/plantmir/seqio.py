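"""Sequence ingestion, alphabet normalization and compositional attributes.

All sequences are handled on the DNA alphabet {A, C, G, T}: RNA input is
accepted and U is mapped to T on the way in, mirroring how mature miRNAs
(reported as RNA) are matched against genomic and EST sequence.  IUPAC
ambiguity codes disqualify a sequence outright (see :class:`AmbiguityError`).

Attribute values that cannot be computed (zero denominators, unknown
genomic position) carry the module-wide missing marker ``MISSING`` (``None``),
serialized as ``"?"`` in attribute tables -- the same convention used by
C4.5/C5.0 data files.  Zero is a legal attribute value and is never used to
stand in for "missing".
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AmbiguityError, ParseError

log = logging.getLogger(__name__)

#: Missing-value marker.  Distinct from every number; written as "?" in TSV.
MISSING = None
MISSING_TOKEN = "?"

_ALPHABET = frozenset("ACGT")
_NORMALIZE = str.maketrans("acgtuACGTU", "ACGTTACGTT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def normalize_rna(raw: str) -> str:
    """Uppercase a raw sequence and convert U to T.

    Any character outside {A, C, G, T, U} (case-insensitive) raises
    :class:`AmbiguityError`: ambiguity codes disqualify the sequence.
    """
    if not raw:
        raise ValueError("empty sequence")
    out = raw.translate(_NORMALIZE)
    if not _ALPHABET.issuperset(out):
        bad = sorted(set(out) - _ALPHABET)
        raise AmbiguityError(f"ambiguity codes in sequence: {''.join(bad)}")
    return out


def reverse_complement(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class NucleotideSequence:
    """A normalized nucleotide sequence with its source bookkeeping.

    ``position`` is the 1-based start coordinate of this record on its
    source (0 means unknown); ``source_length`` is the length of the source
    record, used for the chromLen/position attribute.
    """

    id: str
    residues: str
    source_kind: str = "synthetic"  # genome | est | synthetic
    source_id: str = ""
    position: int = 0
    source_length: int = 0

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")
        if not _ALPHABET.issuperset(self.residues):
            raise AmbiguityError(f"{self.id}: non-ACGT residues")
        if self.source_kind not in ("genome", "est", "synthetic"):
            raise ValueError(f"{self.id}: bad source_kind {self.source_kind!r}")
        if self.source_length == 0:
            object.__setattr__(self, "source_length", len(self.residues))
        if self.position > 0 and self.position > self.source_length:
            raise ValueError(f"{self.id}: position beyond source length")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CompositionProfile:
    """Base percentages and length-normalized Shannon entropy (bits/nt)."""

    a_pct: float
    c_pct: float
    g_pct: float
    t_pct: float
    entropy_norm: float

    def __post_init__(self) -> None:
        total = self.a_pct + self.c_pct + self.g_pct + self.t_pct
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"composition percentages sum to {total}, not 100")


def shannon_entropy_norm(seq: NucleotideSequence | str) -> float:
    """Shannon entropy of the base composition, divided by sequence length.

    H = -sum p_b log2 p_b over the four bases (0 log 0 := 0), in bits; the
    returned value is H / length, i.e. bits per nucleotide of sequence.  A
    homopolymer scores exactly 0.
    """
    residues = seq.residues if isinstance(seq, NucleotideSequence) else seq
    n = len(residues)
    h = 0.0
    for b in "ACGT":
        c = residues.count(b)
        if c:
            p = c / n
            h -= p * math.log2(p)
    return h / n


def base_composition(seq: NucleotideSequence | str) -> CompositionProfile:
    """Percent composition of each base plus normalized Shannon entropy."""
    residues = seq.residues if isinstance(seq, NucleotideSequence) else seq
    n = len(residues)
    return CompositionProfile(
        a_pct=100.0 * residues.count("A") / n,
        c_pct=100.0 * residues.count("C") / n,
        g_pct=100.0 * residues.count("G") / n,
        t_pct=100.0 * residues.count("T") / n,
        entropy_norm=shannon_entropy_norm(residues),
    )


def _ratio(num: float, den: float) -> float | None:
    return MISSING if den == 0 else num / den


def extended_ratios(profile: CompositionProfile, energy_fields: dict) -> dict:
    """The 14 extended attributes combining base composition and energies.

    ``energy_fields`` must supply ``DeltaGnorm``, ``DuplexEnergyNorm``,
    ``longestDotSet`` and ``longestBracketSet`` (each may itself be the
    missing marker).  Any ratio with a zero denominator -- or a missing
    operand -- yields the missing marker, never an exception.
    """
    g, c = profile.g_pct, profile.c_pct
    a, t = profile.a_pct, profile.t_pct
    se = profile.entropy_norm
    dgn = energy_fields.get("DeltaGnorm", MISSING)
    den = energy_fields.get("DuplexEnergyNorm", MISSING)
    dot = energy_fields.get("longestDotSet", MISSING)
    bracket = energy_fields.get("longestBracketSet", MISSING)

    def maybe_ratio(num, d):
        if num is MISSING or d is MISSING:
            return MISSING
        return _ratio(num, d)

    return {
        "G+T": g + t,
        "G/T": _ratio(g, t),
        "G+C": g + c,
        "G/C": _ratio(g, c),
        "A+C": a + c,
        "A/C": _ratio(a, c),
        "T+A": t + a,
        "T/A": _ratio(t, a),
        "G%/ShannonEntropyNorm": _ratio(g, se),
        "C%/ShannonEntropyNorm": _ratio(c, se),
        "T%/ShannonEntropyNorm": _ratio(t, se),
        "A%/ShannonEntropyNorm": _ratio(a, se),
        "NormEnergyRatio": maybe_ratio(dgn, den),
        "longestBracket/longestDot": maybe_ratio(bracket, dot),
    }


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(
    path,
    source_kind: str = "genome",
    on_ambiguous: str = "raise",
) -> list[NucleotideSequence]:
    """Read a (plain or gzipped) FASTA file into normalized records.

    ``on_ambiguous``: ``"raise"`` propagates :class:`AmbiguityError`;
    ``"skip"`` drops offending records with a logged warning (the policy
    used for user scan input, where ambiguous stretches are simply not
    scannable).
    """
    if on_ambiguous not in ("raise", "skip"):
        raise ValueError("on_ambiguous must be 'raise' or 'skip'")
    records: list[NucleotideSequence] = []
    with _open_text(path) as handle:
        # Reject text before the first header; Bio.SeqIO silently returns
        # nothing for some malformed inputs.
        head = handle.read(1)
        if head and head not in (">", ";"):
            raise ParseError(f"{path}: not a FASTA file (first char {head!r})")
        handle.seek(0)
        try:
            parsed = list(SeqIO.parse(handle, "fasta"))
        except ValueError as exc:  # pragma: no cover - biopython internals
            raise ParseError(f"{path}: {exc}") from exc
    for rec in parsed:
        if not rec.id:
            raise ParseError(f"{path}: record with empty header")
        try:
            residues = normalize_rna(str(rec.seq))
        except AmbiguityError:
            if on_ambiguous == "skip":
                log.warning("skipping %s: ambiguity codes", rec.id)
                continue
            raise
        except ValueError as exc:
            raise ParseError(f"{path}: record {rec.id}: {exc}") from exc
        records.append(
            NucleotideSequence(id=rec.id, residues=residues, source_kind=source_kind)
        )
    return records


def write_fasta(records: Iterable[NucleotideSequence], path) -> None:
    """Write records as single-line-per-sequence FASTA."""
    seqrecords = [
        SeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    with _open_text(path, "wt") as handle:
        SeqIO.write(seqrecords, handle, "fasta-2line")
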