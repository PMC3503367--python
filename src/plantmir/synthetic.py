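"""Seeded simulation of miRNA-like hairpins and EST-like negatives.

The generator makes every other module testable without downloads.  A
positive record embeds a planted miRNA:miRNA* duplex -- the star is the
reverse complement of the mature sequence with a controllable number of
substitutions -- separated by a random loop and surrounded by random
flanks.  Negatives are plain i.i.d. sequence at the same GC fraction, long
enough for the central-region sampling rule; using unstructured random
sequence (rather than shuffled positives) mirrors training against broad,
unbiased non-miRNA sequence instead of hard negatives.

All randomness flows through a single numpy Generator with a documented
draw order, so a fixed seed reproduces every fixture bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .attributes import (
    ControlDataset,
    MiRNARecord,
    build_positive_controls,
    sample_negative_controls,
    write_attribute_tsv,
    write_names,
)
from .fold import DOWNSTREAM_STAR, UPSTREAM_STAR, DEFAULT_MODEL, PipelineConfig
from .seqio import NucleotideSequence, reverse_complement, write_fasta

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulatorConfig:
    """Knobs of the hairpin/EST simulator.

    Defaults emulate the composition of plant miRNA training data: mature
    lengths 20-24 nt, up to 4 duplex mismatches, loops 4-30 nt, flanks
    long enough that the star search is non-trivial, GC fraction 0.45
    (plant transcript-like), ESTs 400-1200 nt so the central-region rule
    leaves room for the 300-nt search window.
    """

    seed: int = 0
    n_positives: int = 100
    n_negatives: int = 200
    mirna_len_range: tuple[int, int] = (20, 24)
    star_mismatch_count_range: tuple[int, int] = (0, 4)
    loop_len_range: tuple[int, int] = (4, 30)
    flank_len_range: tuple[int, int] = (40, 120)
    gc_fraction: float = 0.45
    est_len_range: tuple[int, int] = (400, 1200)
    n_species: int = 6
    n_groups: int = 3

    def __post_init__(self) -> None:
        for name in (
            "mirna_len_range",
            "star_mismatch_count_range",
            "loop_len_range",
            "flank_len_range",
            "est_len_range",
        ):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} empty")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must be in (0,1)")


@dataclass(frozen=True)
class SyntheticRecord:
    """One simulated hairpin with its ground truth."""

    context: NucleotideSequence
    candidate: str
    candidate_offset: int
    star_span: tuple[int, int]
    side: str
    mismatches: int
    loop_len: int
    species: str
    taxon_group: str
    label: str = "miRNA"


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def _mutate(rng: np.random.Generator, seq: str, k: int) -> str:
    """Plant k substitutions at k distinct positions."""
    if k == 0:
        return seq
    out = list(seq)
    positions = rng.choice(len(seq), size=k, replace=False)
    for pos in positions:
        choices = [b for b in "ACGT" if b != out[pos]]
        out[pos] = choices[int(rng.integers(3))]
    return "".join(out)


def simulate_hairpin(
    config: SimulatorConfig, rng: np.random.Generator, index: int = 0
) -> SyntheticRecord:
    """Draw one hairpin record.

    Draw order (fixed for reproducibility): miRNA length, miRNA sequence,
    mismatch count, mutation positions/bases, loop length+sequence, flank
    lengths+sequences, side.
    """
    mlo, mhi = config.mirna_len_range
    mlen = int(rng.integers(mlo, mhi + 1))
    mirna = _random_seq(rng, mlen, config.gc_fraction)
    klo, khi = config.star_mismatch_count_range
    k = int(rng.integers(klo, khi + 1))
    star = _mutate(rng, reverse_complement(mirna), k)
    llo, lhi = config.loop_len_range
    loop_len = int(rng.integers(llo, lhi + 1))
    loop = _random_seq(rng, loop_len, config.gc_fraction)
    flo, fhi = config.flank_len_range
    f5 = _random_seq(rng, int(rng.integers(flo, fhi + 1)), config.gc_fraction)
    f3 = _random_seq(rng, int(rng.integers(flo, fhi + 1)), config.gc_fraction)
    side = UPSTREAM_STAR if int(rng.integers(2)) == 0 else DOWNSTREAM_STAR
    if side == DOWNSTREAM_STAR:
        # candidate 5' of the star: flank-miRNA-loop-star-flank
        residues = f5 + mirna + loop + star + f3
        offset = len(f5)
        star_span = (offset + mlen + loop_len, offset + mlen + loop_len + len(star))
    else:
        residues = f5 + star + loop + mirna + f3
        star_span = (len(f5), len(f5) + len(star))
        offset = star_span[1] + loop_len
    species = f"species{index % config.n_species + 1:02d}"
    group = f"clade{chr(ord('A') + index % config.n_groups)}"
    context = NucleotideSequence(
        id=f"hairpin{index:05d}", residues=residues, source_kind="synthetic"
    )
    return SyntheticRecord(
        context=context,
        candidate=mirna,
        candidate_offset=offset,
        star_span=star_span,
        side=side,
        mismatches=k,
        loop_len=loop_len,
        species=species,
        taxon_group=group,
    )


def simulate_est(
    config: SimulatorConfig, rng: np.random.Generator, index: int = 0
) -> NucleotideSequence:
    """One EST-like negative context: i.i.d. sequence, no planted hairpin."""
    lo, hi = config.est_len_range
    length = int(rng.integers(lo, hi + 1))
    return NucleotideSequence(
        id=f"est{index:05d}",
        residues=_random_seq(rng, length, config.gc_fraction),
        source_kind="est",
    )


def generate_benchmark(
    config: SimulatorConfig,
    pipeline: PipelineConfig | None = None,
    model=DEFAULT_MODEL,
    outdir=None,
):
    """Build the full labeled benchmark.

    Returns ``(dataset, records, ests)`` where ``dataset`` holds
    ``n_positives`` + ``n_negatives`` attribute vectors, ``records`` the
    hairpin ground truth and ``ests`` the negative contexts.  When
    ``outdir`` is given, FASTA fixtures, a truth TSV and the attribute
    table (+ .names sidecar) are written there.
    """
    pipeline = pipeline or PipelineConfig(seed=config.seed)
    rng = np.random.default_rng(config.seed)
    records = [
        simulate_hairpin(config, rng, index=i) for i in range(config.n_positives)
    ]
    mirna_records = [
        MiRNARecord(
            id=f"mir{i:05d}",
            sequence=rec.candidate,
            species=rec.species,
            taxon_group=rec.taxon_group,
            side=rec.side,
            source_id=rec.context.id,
        )
        for i, rec in enumerate(records)
    ]
    sources = {rec.context.id: rec.context for rec in records}
    positives = build_positive_controls(mirna_records, sources, pipeline, model)

    n_ests = max(config.n_negatives, 50)
    ests = [simulate_est(config, rng, index=i) for i in range(n_ests)]
    est_metadata = {
        est.id: (
            f"species{i % config.n_species + 1:02d}",
            f"clade{chr(ord('A') + i % config.n_groups)}",
        )
        for i, est in enumerate(ests)
    }
    negatives = sample_negative_controls(
        ests, positives, pipeline, rng, count=config.n_negatives, est_metadata=est_metadata
    )
    dataset = ControlDataset(
        vectors=positives.vectors + negatives.vectors,
        provenance=(
            f"synthetic benchmark seed={config.seed} "
            f"({positives.provenance}; {negatives.provenance})"
        ),
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta([rec.context for rec in records], outdir / "hairpins.fasta")
        write_fasta(ests, outdir / "ests.fasta")
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write(
                "id\tcontext_id\tsequence\toffset\tstar_start\tstar_end\t"
                "side\tmismatches\tloop_len\tspecies\ttaxon_group\n"
            )
            for i, rec in enumerate(records):
                fh.write(
                    f"mir{i:05d}\t{rec.context.id}\t{rec.candidate}\t"
                    f"{rec.candidate_offset}\t{rec.star_span[0]}\t{rec.star_span[1]}\t"
                    f"{rec.side}\t{rec.mismatches}\t{rec.loop_len}\t"
                    f"{rec.species}\t{rec.taxon_group}\n"
                )
        write_attribute_tsv(dataset.vectors, outdir / "attributes.tsv")
        write_names(outdir / "attributes.names")
    return dataset, records, ests
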