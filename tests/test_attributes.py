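import numpy as np
import pytest
from scipy import stats

from plantmir import (
    ATTRIBUTE_NAMES,
    CandidateContext,
    MISSING,
    MiRNARecord,
    NoDuplexError,
    PoolExhaustedError,
    build_positive_controls,
    collect_attributes,
    collect_both_sides,
    locate_exact,
    read_attribute_tsv,
    reverse_complement,
    sample_negative_controls,
    write_attribute_tsv,
)
from plantmir.fold import DOWNSTREAM_STAR, UPSTREAM_STAR, PipelineConfig
from plantmir.seqio import NucleotideSequence
from plantmir.synthetic import SimulatorConfig, simulate_est, simulate_hairpin
from tests.conftest import random_seq


def _perfect_hairpin(rng, mlen=21, loop=10, flank=50):
    mir = random_seq(rng, mlen)
    ctx = (
        random_seq(rng, flank)
        + mir
        + random_seq(rng, loop)
        + reverse_complement(mir)
        + random_seq(rng, flank)
    )
    return mir, ctx, flank


class TestCollectAttributes:
    def test_perfect_hairpin_populates_all_29_attributes(self):
        rng = np.random.default_rng(101)
        mir, ctx, offset = _perfect_hairpin(rng)
        vec = collect_attributes(
            CandidateContext(mir, ctx, offset, chrom_length=len(ctx),
                             chrom_position=offset + 1),
            DOWNSTREAM_STAR,
        )
        assert set(vec.values) == set(ATTRIBUTE_NAMES)
        assert vec.values["MaxMismatch"] == 0
        assert vec.values["minMatchPercent"] == 100.0
        assert vec.values["DuplexEnergy"] < -30
        assert vec.values["DeltaG"] <= vec.values["DuplexEnergy"]
        # DeltaGnorm and the run statistics are normalized by OPR length
        opr_len = len(vec.opr)
        assert vec.values["DeltaGnorm"] == pytest.approx(vec.values["DeltaG"] / opr_len)
        assert 0 < vec.values["longestBracketSet"] <= 1

    def test_chrom_ratio_and_unknown_position(self):
        rng = np.random.default_rng(103)
        mir, ctx, offset = _perfect_hairpin(rng)
        vec = collect_attributes(
            CandidateContext(mir, ctx, offset, chrom_length=10_000_000,
                             chrom_position=2_500_000),
            DOWNSTREAM_STAR,
        )
        assert vec.values["chromLen/position"] == pytest.approx(4.0)
        vec2 = collect_attributes(
            CandidateContext(mir, ctx, offset), DOWNSTREAM_STAR
        )
        assert vec2.values["chromLen/position"] is MISSING

    def test_no_pairing_partner_raises(self):
        ctx = "A" * 200
        with pytest.raises(NoDuplexError):
            collect_attributes(
                CandidateContext("A" * 21, ctx, 90), DOWNSTREAM_STAR
            )


class TestCollectBothSides:
    def test_planted_downstream_star_binds_stronger_downstream(self):
        rng = np.random.default_rng(107)
        mir, ctx, offset = _perfect_hairpin(rng)
        up, down, errors = collect_both_sides(CandidateContext(mir, ctx, offset))
        assert down is not None
        if up is not None:  # random upstream flank may lack any duplex
            assert down.values["DuplexEnergy"] < up.values["DuplexEnergy"]

    def test_candidate_at_5prime_edge_loses_upstream_side_only(self):
        rng = np.random.default_rng(109)
        mir = random_seq(rng, 21)
        ctx = mir + random_seq(rng, 20) + reverse_complement(mir) + random_seq(rng, 30)
        up, down, errors = collect_both_sides(CandidateContext(mir, ctx, 0))
        assert up is None and UPSTREAM_STAR in errors
        assert down is not None

    def test_palindromic_context_yields_both_sides(self):
        rng = np.random.default_rng(113)
        mir = random_seq(rng, 20)
        wing = random_seq(rng, 30)
        ctx = wing + reverse_complement(mir) + random_seq(rng, 10) + mir \
            + random_seq(rng, 10) + reverse_complement(mir) + wing
        offset = len(wing) + 20 + 10
        up, down, _ = collect_both_sides(CandidateContext(mir, ctx, offset))
        assert up is not None and down is not None


class TestLocateExact:
    def test_planted_sequence_found_at_position(self):
        rng = np.random.default_rng(127)
        contig = random_seq(rng, 5000)
        probe = contig[1234:1255]
        src = NucleotideSequence(id="contig", residues=contig, source_kind="genome")
        hits = locate_exact(probe, src)
        assert (1235, "+") in hits

    def test_absent_query_returns_empty(self):
        rng = np.random.default_rng(131)
        src = NucleotideSequence(id="c", residues="ACGT" * 100)
        assert locate_exact(random_seq(rng, 21), src) in ([], )

    def test_palindrome_hits_both_strands_at_same_position(self):
        probe = "ACGTACGTACGTACGTACGT"  # wait: must equal its own revcomp
        probe = "ACGTGCGCATATGCGCACGT"
        assert reverse_complement(probe) == probe
        ctx = "TTTTTTTTTT" + probe + "TTTTTTTTTT"
        src = NucleotideSequence(id="c", residues=ctx)
        hits = locate_exact(probe, src)
        assert hits == [(11, "+"), (11, "-")]


class TestBuildPositiveControls:
    def _records_and_sources(self, rng, n=6):
        cfg = SimulatorConfig(seed=0)
        records, sources, mirnas = [], {}, []
        for i in range(n):
            rec = simulate_hairpin(cfg, rng, index=i)
            records.append(rec)
            sources[rec.context.id] = rec.context
            mirnas.append(
                MiRNARecord(id=f"m{i}", sequence=rec.candidate, side=rec.side,
                            source_id=rec.context.id, species=rec.species,
                            taxon_group=rec.taxon_group)
            )
        return mirnas, sources

    def test_all_planted_mirnas_collected(self):
        rng = np.random.default_rng(137)
        mirnas, sources = self._records_and_sources(rng)
        ds = build_positive_controls(mirnas, sources)
        assert ds.positives_count == len(mirnas)
        assert all(v.label == "miRNA" for v in ds.vectors)

    def test_record_absent_from_sources_is_skipped(self):
        rng = np.random.default_rng(139)
        mirnas, sources = self._records_and_sources(rng)
        mirnas.append(MiRNARecord(id="ghost", sequence="ACGTACGTACGTACGTACGTA"))
        ds = build_positive_controls(mirnas, sources)
        assert ds.positives_count == len(mirnas) - 1

    def test_record_without_duplex_on_declared_side_is_skipped(self):
        mir = "G" * 10 + "A" * 11  # only partner would be upstream; none exists
        ctx = "A" * 150 + mir + "A" * 150
        src = NucleotideSequence(id="flat", residues=ctx)
        rec = MiRNARecord(id="m", sequence=mir, side=DOWNSTREAM_STAR, source_id="flat")
        ds = build_positive_controls([rec], {"flat": src})
        assert len(ds.vectors) == 0


@pytest.fixture(scope="module")
def positives():
    rng = np.random.default_rng(149)
    cfg = SimulatorConfig(seed=0)
    mirnas, sources = [], {}
    for i in range(25):
        rec = simulate_hairpin(cfg, rng, index=i)
        sources[rec.context.id] = rec.context
        mirnas.append(MiRNARecord(id=f"m{i}", sequence=rec.candidate,
                                  side=rec.side, source_id=rec.context.id))
    return build_positive_controls(mirnas, sources)


class TestNegativeSampling:

    def test_sampled_negatives_match_template(self, positives):
        rng = np.random.default_rng(151)
        cfg = SimulatorConfig(seed=0)
        ests = [simulate_est(cfg, rng, index=i) for i in range(60)]
        ds = sample_negative_controls(ests, positives, PipelineConfig(), rng, count=60)
        assert ds.negatives_count == 60
        ents = [v.values["ShannonEntropyNorm"] for v in positives.vectors]
        lo, hi = min(ents), max(ents)
        pos_lengths = {len(v.sequence) for v in positives.vectors}
        for v in ds.vectors:
            assert lo <= v.values["ShannonEntropyNorm"] <= hi
            assert len(v.sequence) in pos_lengths
            assert v.label == "not_miRNA"

    def test_negative_lengths_track_positive_distribution(self, positives):
        rng = np.random.default_rng(157)
        cfg = SimulatorConfig(seed=0)
        ests = [simulate_est(cfg, rng, index=i) for i in range(80)]
        ds = sample_negative_controls(ests, positives, PipelineConfig(), rng, count=120)
        pos_lengths = [len(v.sequence) for v in positives.vectors]
        neg_lengths = [len(v.sequence) for v in ds.vectors]
        ks = stats.ks_2samp(pos_lengths, neg_lengths).statistic
        assert ks < 0.25  # small-n bound; the full benchmark asserts < 0.1

    def test_short_ests_cannot_host_central_segments(self, positives):
        rng = np.random.default_rng(163)
        short = [
            NucleotideSequence(id=f"e{i}", residues=random_seq(rng, 200),
                               source_kind="est")
            for i in range(5)
        ]
        with pytest.raises(PoolExhaustedError):
            sample_negative_controls(short, positives, PipelineConfig(), rng, count=5)

    def test_fixed_seed_reproduces_identical_vectors(self, positives):
        cfg = SimulatorConfig(seed=0)
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(9)
            ests = [simulate_est(cfg, rng, index=i) for i in range(40)]
            ds = sample_negative_controls(ests, positives, PipelineConfig(), rng, count=20)
            outs.append([(v.id, v.side, tuple(sorted(
                (k, val) for k, val in v.values.items() if val is not MISSING)))
                for v in ds.vectors])
        assert outs[0] == outs[1]


class TestAttributeTable:
    def test_tsv_round_trip(self, tmp_path, small_benchmark):
        dataset, _records, _ests = small_benchmark
        path = tmp_path / "attrs.tsv"
        write_attribute_tsv(dataset.vectors, path)
        back = read_attribute_tsv(path)
        assert len(back) == len(dataset)
        for a, b in zip(dataset.vectors, back.vectors):
            assert a.id == b.id and a.label == b.label and a.side == b.side
            for name in ATTRIBUTE_NAMES:
                va, vb = a.values[name], b.values[name]
                if va is MISSING:
                    assert vb is MISSING
                else:
                    assert vb == pytest.approx(va)

    def test_header_names_the_29_attributes_exactly(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_attribute_tsv([], path)
        header = path.read_text().splitlines()[0].split("\t")
        assert header[-29:] == list(ATTRIBUTE_NAMES)
        assert "DuplexEnergyNorm" in header and "longestBracketSet" in header
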