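"""De novo sliding-window scanning of long sequences.

Every 20-24 nt window of an input sequence is a candidate: attributes are
collected for both orientations (upstream and downstream star), each
orientation is classified, and the window is called a miRNA if either side
is positive -- an unknown carries no prior about which half of its
precursor it sits in.  Identical window sequences within one source are
deduplicated before attribute collection and re-expanded to all their
positions in the report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from .attributes import CandidateContext, LABEL_MIRNA, collect_both_sides
from .classifier import BoostedModel, Prediction, predict
from .fold import DEFAULT_MODEL, HairpinStructure, PipelineConfig
from .seqio import NucleotideSequence, normalize_rna

log = logging.getLogger(__name__)

_ALPHABET = frozenset("ACGT")


@dataclass(frozen=True)
class ScanHit:
    """One evaluated window with its best-side prediction and OPR."""

    window: str
    source_id: str
    start: int  # 1-based on the source
    length: int
    side: str
    prediction: Prediction
    opr: HairpinStructure = field(repr=False)


def sliding_windows(
    seq: str, scan_lengths: Sequence[int] = (20, 21, 22, 23, 24)
) -> Iterator[tuple[int, int, str]]:
    """Yield (1-based start, length, subsequence) for every window.

    Lengths are scanned in ascending order; for each length w the starts
    run 1..L-w+1.  Windows containing non-ACGT characters are skipped.
    """
    L = len(seq)
    for w in sorted(scan_lengths):
        for start0 in range(0, L - w + 1):
            sub = seq[start0 : start0 + w]
            if not _ALPHABET.issuperset(sub):
                continue
            yield start0 + 1, w, sub


def count_windows(length: int, scan_lengths: Sequence[int]) -> int:
    return sum(max(0, length - w + 1) for w in scan_lengths)


def scan_and_predict(
    sources: Iterable[NucleotideSequence],
    model: BoostedModel,
    config: PipelineConfig = PipelineConfig(),
    energy_model=DEFAULT_MODEL,
) -> list[ScanHit]:
    """Scan sources and classify every window (deterministic; no RNG).

    For each unique window sequence per source, attributes are collected
    once (at its first occurrence) on both sides; a window is called miRNA
    if either side's prediction is miRNA, and the reported side is the
    positive side with the higher confidence (or the higher-confidence
    side overall for negative calls).  Windows on which neither side
    yields an attribute vector produce no hit.
    """
    hits: list[ScanHit] = []
    for src in sources:
        seq = src.residues
        occurrences: dict[str, list[tuple[int, int]]] = {}
        order: list[str] = []
        for start, w, sub in sliding_windows(seq, config.scan_lengths):
            if sub not in occurrences:
                occurrences[sub] = []
                order.append(sub)
            occurrences[sub].append((start, w))
        evaluated = 0
        for sub in order:
            positions = occurrences[sub]
            first_start = positions[0][0]
            ctx = CandidateContext(
                candidate=sub,
                context=seq,
                candidate_offset=first_start - 1,
                chrom_length=src.source_length,
                chrom_position=first_start,
            )
            up, down, errors = collect_both_sides(ctx, config, energy_model)
            sided: list[tuple[str, Prediction, HairpinStructure]] = []
            for side_vec in (up, down):
                if side_vec is None:
                    continue
                pred = predict(model, side_vec)
                sided.append((side_vec.side, pred, side_vec.opr))
            if not sided:
                log.debug("window %s@%d: no side evaluable (%s)", sub, first_start, errors)
                continue
            evaluated += 1
            positive = [s for s in sided if s[1].label == LABEL_MIRNA]
            pool = positive if positive else sided
            side, pred, opr = max(pool, key=lambda s: s[1].confidence)
            for start, w in positions:
                hits.append(
                    ScanHit(
                        window=sub,
                        source_id=src.id,
                        start=start,
                        length=w,
                        side=side,
                        prediction=pred,
                        opr=opr,
                    )
                )
        log.info(
            "%s: %d unique windows evaluated, %d hit records", src.id, evaluated, len(hits)
        )
    return hits


def positive_hits(hits: Iterable[ScanHit]) -> list[ScanHit]:
    return [h for h in hits if h.prediction.label == LABEL_MIRNA]


def unique_recovery_rate(known_mirnas: Iterable[str], hits: Iterable[ScanHit]) -> float:
    """Percent of unique known miRNA sequences exactly matched by at least
    one positively classified window."""
    known = {normalize_rna(s) for s in known_mirnas}
    if not known:
        raise ValueError("no known miRNAs supplied")
    called = {h.window for h in hits if h.prediction.label == LABEL_MIRNA}
    recovered = sum(1 for s in known if s in called)
    return 100.0 * recovered / len(known)


def write_hits_tsv(hits: Sequence[ScanHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("source_id\tstart\tlength\twindow\tside\tlabel\tconfidence\n")
        for h in hits:
            fh.write(
                f"{h.source_id}\t{h.start}\t{h.length}\t{h.window}\t{h.side}\t"
                f"{h.prediction.label}\t{h.prediction.confidence:.4f}\n"
            )
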