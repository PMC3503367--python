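"""Assembly of the 29-attribute vector and control-dataset construction.

One attribute vector describes one candidate-orientation pair: the short
sequence itself (composition, entropy), its best-binding star partner
(duplex energy and match statistics), the folded operative precursor
region (stem-loop energy and structure runs), its genomic position, and
the 14 derived ratios.  Positive controls are known miRNAs collected on
their declared side; negative controls are entropy- and length-matched
segments sampled from the central regions of ESTs, each scored on one
randomly chosen side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    AmbiguityError,
    NoDuplexError,
    PoolExhaustedError,
    WindowError,
)
from .fold import (
    DOWNSTREAM_STAR,
    SIDES,
    UPSTREAM_STAR,
    DEFAULT_MODEL,
    HairpinStructure,
    PipelineConfig,
    build_opr,
    duplex_metrics,
    find_best_star,
    structure_runs,
)
from .seqio import (
    MISSING,
    MISSING_TOKEN,
    NucleotideSequence,
    base_composition,
    extended_ratios,
    reverse_complement,
)

log = logging.getLogger(__name__)

LABEL_MIRNA = "miRNA"
LABEL_NOT_MIRNA = "not_miRNA"
LABEL_UNKNOWN = "unknown"

#: The 15 base attributes followed by the 14 extended attributes, in the
#: fixed serialization order used by every attribute table.
ATTRIBUTE_NAMES: tuple[str, ...] = (
    "chromLen/position",
    "ShannonEntropyNorm",
    "G%",
    "C%",
    "T%",
    "A%",
    "DuplexEnergy",
    "DuplexEnergyNorm",
    "MaxMismatch",
    "minMatchPercent",
    "DeltaG",
    "DeltaGnorm",
    "longestDotSet",
    "longestBracketSet",
    "loopCountNorm",
    "G+T",
    "G/T",
    "G+C",
    "G/C",
    "A+C",
    "A/C",
    "T+A",
    "T/A",
    "G%/ShannonEntropyNorm",
    "C%/ShannonEntropyNorm",
    "T%/ShannonEntropyNorm",
    "A%/ShannonEntropyNorm",
    "NormEnergyRatio",
    "longestBracket/longestDot",
)

_META_COLUMNS = ("id", "sequence", "label", "side", "species", "taxon_group")


@dataclass(frozen=True)
class CandidateContext:
    """A short candidate embedded in its hosting window.

    ``chrom_length`` / ``chrom_position`` describe where the *context* (or
    the candidate within it) sits on the original chromosome or EST; for an
    EST-hosted candidate the EST's own length and in-EST position are used.
    ``chrom_position`` is 1-based; 0 means unknown.
    """

    candidate: str
    context: str
    candidate_offset: int
    chrom_length: int = 0
    chrom_position: int = 0

    def __post_init__(self) -> None:
        got = self.context[
            self.candidate_offset : self.candidate_offset + len(self.candidate)
        ]
        if got != self.candidate:
            raise ValueError("candidate does not match context at offset")


@dataclass
class AttributeVector:
    """The 29 named attributes plus label and provenance for one
    candidate-orientation pair.  ``values`` maps attribute name to a float
    or the missing marker.  The folded OPR and candidate sequence are kept
    alongside for downstream reporting but are not attributes."""

    id: str
    values: dict
    label: str = LABEL_UNKNOWN
    side: str = DOWNSTREAM_STAR
    species: str = ""
    taxon_group: str = ""
    sequence: str = ""
    opr: HairpinStructure | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if set(self.values) != set(ATTRIBUTE_NAMES):
            missing = set(ATTRIBUTE_NAMES) - set(self.values)
            extra = set(self.values) - set(ATTRIBUTE_NAMES)
            raise ValueError(f"bad attribute set: missing={missing} extra={extra}")
        if self.label not in (LABEL_MIRNA, LABEL_NOT_MIRNA, LABEL_UNKNOWN):
            raise ValueError(f"bad label {self.label!r}")


@dataclass
class ControlDataset:
    """Labeled attribute vectors ready for training/validation."""

    vectors: list[AttributeVector]
    provenance: str = ""

    @property
    def positives_count(self) -> int:
        return sum(1 for v in self.vectors if v.label == LABEL_MIRNA)

    @property
    def negatives_count(self) -> int:
        return sum(1 for v in self.vectors if v.label == LABEL_NOT_MIRNA)

    def __len__(self) -> int:
        return len(self.vectors)


def collect_attributes(
    ctx: CandidateContext,
    side: str,
    config: PipelineConfig = PipelineConfig(),
    model=DEFAULT_MODEL,
    vector_id: str = "",
) -> AttributeVector:
    """Run the full attribute pipeline for one candidate-orientation pair.

    Chains star discovery, OPR construction, folding, structure statistics,
    duplex metrics, candidate composition and the extended ratios.  Raises
    :class:`NoDuplexError` or :class:`WindowError` when the side cannot be
    evaluated; the candidate is then unclassifiable on that side.
    """
    hit = find_best_star(
        ctx.candidate, ctx.context, ctx.candidate_offset, side, config, model
    )
    opr = build_opr(ctx.candidate, ctx.candidate_offset, hit, ctx.context, config, model)
    longest_dot, longest_bracket, heads = structure_runs(opr.dot_bracket)
    max_mismatch, min_match_pct, duplex_energy_norm = duplex_metrics(hit)
    profile = base_composition(ctx.candidate)
    opr_len = len(opr)
    delta_g_norm = opr.mfe / opr_len
    values = {
        "chromLen/position": (
            ctx.chrom_length / ctx.chrom_position if ctx.chrom_position > 0 else MISSING
        ),
        "ShannonEntropyNorm": profile.entropy_norm,
        "G%": profile.g_pct,
        "C%": profile.c_pct,
        "T%": profile.t_pct,
        "A%": profile.a_pct,
        "DuplexEnergy": hit.energy,
        "DuplexEnergyNorm": duplex_energy_norm,
        "MaxMismatch": float(max_mismatch),
        "minMatchPercent": min_match_pct,
        "DeltaG": opr.mfe,
        "DeltaGnorm": delta_g_norm,
        "longestDotSet": longest_dot / opr_len,
        "longestBracketSet": longest_bracket / opr_len,
        "loopCountNorm": heads / opr_len,
    }
    values.update(
        extended_ratios(
            profile,
            {
                "DeltaGnorm": delta_g_norm,
                "DuplexEnergyNorm": duplex_energy_norm,
                "longestDotSet": values["longestDotSet"],
                "longestBracketSet": values["longestBracketSet"],
            },
        )
    )
    return AttributeVector(
        id=vector_id or f"cand@{ctx.candidate_offset}",
        values=values,
        side=side,
        sequence=ctx.candidate,
        opr=opr,
    )


def collect_both_sides(
    ctx: CandidateContext,
    config: PipelineConfig = PipelineConfig(),
    model=DEFAULT_MODEL,
    vector_id: str = "",
):
    """Collect attribute vectors for both orientations of an unknown.

    Returns ``(upstream_vector, downstream_vector, errors)`` where either
    vector may be ``None`` with the reason recorded in ``errors`` (a map
    side -> exception).  Both sides failing is not fatal here; the caller
    decides what an empty result means.
    """
    vectors: dict[str, AttributeVector | None] = {}
    errors: dict[str, Exception] = {}
    for side in (UPSTREAM_STAR, DOWNSTREAM_STAR):
        try:
            vec = collect_attributes(ctx, side, config, model, vector_id=vector_id)
        except (NoDuplexError, WindowError) as exc:
            vectors[side] = None
            errors[side] = exc
        else:
            vectors[side] = vec
    return vectors[UPSTREAM_STAR], vectors[DOWNSTREAM_STAR], errors


def locate_exact(short_seq: str, source: NucleotideSequence) -> list[tuple[int, str]]:
    """All exact occurrences of a short sequence on both strands.

    Returns sorted (1-based position on the forward strand, strand) pairs;
    an empty list means not found.  Replaces gapped read alignment with an
    exact-match search, which suffices for sequences drawn from the source.
    """
    if len(short_seq) < 15:
        raise ValueError("query shorter than 15 nt")
    hits: list[tuple[int, str]] = []
    for probe, strand in ((short_seq, "+"), (reverse_complement(short_seq), "-")):
        start = source.residues.find(probe)
        while start != -1:
            hits.append((start + 1, strand))
            start = source.residues.find(probe, start + 1)
    hits.sort()
    return hits


@dataclass(frozen=True)
class MiRNARecord:
    """A known miRNA with its provenance and declared precursor side."""

    id: str
    sequence: str
    species: str = ""
    taxon_group: str = ""
    side: str = DOWNSTREAM_STAR
    source_id: str = ""


def infer_side(candidate_start0: int, candidate_len: int, precursor_len: int) -> str:
    """Declare the candidate upstream of its star when its 5' end lies in
    the 5' half of the precursor.  This positional rule can be wrong for
    asymmetric precursors (a documented failure mode of location picking),
    which is why unknowns are always evaluated on both sides."""
    return (
        UPSTREAM_STAR
        if candidate_start0 < (precursor_len - candidate_len) / 2
        else DOWNSTREAM_STAR
    )


def build_positive_controls(
    mirna_records: Sequence[MiRNARecord],
    sources: dict[str, NucleotideSequence],
    config: PipelineConfig = PipelineConfig(),
    model=DEFAULT_MODEL,
) -> ControlDataset:
    """Collect positive-control vectors for known miRNAs.

    Each record is located exactly on its source (or on all sources when no
    source_id is given) and its attributes are collected on the declared
    side only.  Records not found anywhere, or lacking a duplex on their
    declared side, are skipped with a log entry.
    """
    vectors: list[AttributeVector] = []
    skipped = 0
    for rec in mirna_records:
        pool = (
            [sources[rec.source_id]]
            if rec.source_id and rec.source_id in sources
            else list(sources.values())
        )
        placed = False
        for src in pool:
            hits = locate_exact(rec.sequence, src)
            forward = [p for p, strand in hits if strand == "+"]
            if forward:
                context = src.residues
                offset = forward[0] - 1
            else:
                minus = [p for p, strand in hits if strand == "-"]
                if not minus:
                    continue
                # collect on the reverse-complement strand
                context = reverse_complement(src.residues)
                offset = len(src.residues) - (minus[0] - 1) - len(rec.sequence)
            ctx = CandidateContext(
                candidate=rec.sequence,
                context=context,
                candidate_offset=offset,
                chrom_length=src.source_length,
                chrom_position=offset + 1,
            )
            try:
                vec = collect_attributes(ctx, rec.side, config, model, vector_id=rec.id)
            except (NoDuplexError, WindowError) as exc:
                log.info("skipping %s: %s", rec.id, exc)
                skipped += 1
                placed = True  # located but unclassifiable; do not retry elsewhere
                break
            vec.label = LABEL_MIRNA
            vec.species = rec.species
            vec.taxon_group = rec.taxon_group
            vectors.append(vec)
            placed = True
            break
        if not placed:
            log.info("skipping %s: not found on any source", rec.id)
            skipped += 1
    return ControlDataset(
        vectors=vectors,
        provenance=f"positives: {len(vectors)} collected, {skipped} skipped",
    )


def sample_negative_controls(
    ests: Sequence[NucleotideSequence],
    positives: ControlDataset,
    config: PipelineConfig,
    rng: np.random.Generator,
    count: int,
    est_metadata: dict[str, tuple[str, str]] | None = None,
) -> ControlDataset:
    """Sample qualified negative controls from the central regions of ESTs.

    Segment lengths follow the positives' empirical length distribution;
    the segment plus half the search window must fit on both sides of it
    (the central-region rule); segments with ambiguity codes or with a
    length-normalized Shannon entropy outside the positives' [min, max]
    are rejected; one orientation is chosen by fair coin per accepted
    segment.  Raises :class:`PoolExhaustedError` if the pool cannot supply
    ``count`` qualified segments.
    """
    pos_vecs = [v for v in positives.vectors if v.label == LABEL_MIRNA]
    if not pos_vecs:
        raise ValueError("positives required as the sampling template")
    lengths = np.array([len(v.sequence) for v in pos_vecs])
    entropies = [v.values["ShannonEntropyNorm"] for v in pos_vecs]
    ent_lo, ent_hi = min(entropies), max(entropies)
    margin = config.search_window // 2
    est_metadata = est_metadata or {}

    vectors: list[AttributeVector] = []
    attempts = 0
    max_attempts = max(1000, 200 * count)
    from .seqio import shannon_entropy_norm  # local import avoids cycle noise

    while len(vectors) < count:
        if attempts >= max_attempts:
            raise PoolExhaustedError(
                f"collected {len(vectors)}/{count} after {attempts} attempts"
            )
        attempts += 1
        est = ests[int(rng.integers(len(ests)))]
        seglen = int(lengths[int(rng.integers(len(lengths)))])
        lo = margin
        hi = len(est.residues) - margin - seglen
        if hi < lo:
            continue
        start = int(rng.integers(lo, hi + 1))
        segment = est.residues[start : start + seglen]
        if set(segment) - set("ACGT"):
            continue  # ambiguity disqualifies
        ent = shannon_entropy_norm(segment)
        if not (ent_lo <= ent <= ent_hi):
            continue
        side = UPSTREAM_STAR if int(rng.integers(2)) == 0 else DOWNSTREAM_STAR
        ctx = CandidateContext(
            candidate=segment,
            context=est.residues,
            candidate_offset=start,
            chrom_length=len(est.residues),
            chrom_position=start + 1,
        )
        try:
            vec = collect_attributes(
                ctx, side, config, vector_id=f"neg{len(vectors):05d}|{est.id}"
            )
        except (NoDuplexError, WindowError):
            continue
        vec.label = LABEL_NOT_MIRNA
        species, group = est_metadata.get(est.id, ("", ""))
        vec.species = species
        vec.taxon_group = group
        vectors.append(vec)
    return ControlDataset(
        vectors=vectors,
        provenance=f"negatives: {count} sampled in {attempts} attempts",
    )


# ---------------------------------------------------------------------------
# Attribute-table serialization (TSV with "?" for missing + .names sidecar)


def _fmt(value) -> str:
    if value is MISSING:
        return MISSING_TOKEN
    return repr(float(value))


def write_attribute_tsv(vectors: Iterable[AttributeVector], path) -> None:
    """Write vectors as TSV: metadata columns then the 29 attributes in
    fixed order, missing values as '?'.  Byte-deterministic."""
    with open(path, "w") as fh:
        fh.write("\t".join(_META_COLUMNS + ATTRIBUTE_NAMES) + "\n")
        for v in vectors:
            meta = [v.id, v.sequence, v.label, v.side, v.species, v.taxon_group]
            row = meta + [_fmt(v.values[name]) for name in ATTRIBUTE_NAMES]
            fh.write("\t".join(row) + "\n")


def read_attribute_tsv(path) -> ControlDataset:
    vectors: list[AttributeVector] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _META_COLUMNS + ATTRIBUTE_NAMES:
            raise ValueError(f"{path}: unexpected attribute-table header")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            meta = dict(zip(_META_COLUMNS, parts[: len(_META_COLUMNS)]))
            values = {
                name: (MISSING if tok == MISSING_TOKEN else float(tok))
                for name, tok in zip(ATTRIBUTE_NAMES, parts[len(_META_COLUMNS) :])
            }
            vectors.append(
                AttributeVector(
                    id=meta["id"],
                    values=values,
                    label=meta["label"],
                    side=meta["side"],
                    species=meta["species"],
                    taxon_group=meta["taxon_group"],
                    sequence=meta["sequence"],
                )
            )
    return ControlDataset(vectors=vectors, provenance=f"read from {path}")


def write_names(path) -> None:
    """Write a C4.5/C5.0-style .names sidecar for the attribute table."""
    with open(path, "w") as fh:
        fh.write("label.\n\n")
        for name in _META_COLUMNS:
            if name != "label":
                fh.write(f"{name}: ignore.\n")
        for name in ATTRIBUTE_NAMES:
            fh.write(f"{name}: continuous.\n")
        fh.write(f"label: {LABEL_MIRNA}, {LABEL_NOT_MIRNA}.\n")
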