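"""UTR extraction, uAUG counting, AUG score and conservation mapping."""

import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from erpartition.partitioning import PartitionGroups
from erpartition.tracks import ConservationTrack
from erpartition.utr_features import (
    TranscriptModel,
    UTRTooShortError,
    aug_score,
    count_uaugs,
    extract_utrs,
    group_summary,
    map_conservation,
    summarize_features,
)

REVCOMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s):
    return s.translate(REVCOMP)[::-1]


class TestExtractUtrs:
    def test_plus_strand_single_exon(self, plus_model, toy_genome):
        r5, r3 = extract_utrs(plus_model, toy_genome)
        assert r5.sequence == toy_genome["chr1"][100:130].upper()
        assert r3.sequence == toy_genome["chr1"][190:200].upper()

    def test_minus_strand_is_reverse_complement(self, minus_model, toy_genome):
        r5, r3 = extract_utrs(minus_model, toy_genome)
        assert r5.sequence == revcomp(toy_genome["chr1"][190:200].upper())
        assert r3.sequence == revcomp(toy_genome["chr1"][100:130].upper())

    def test_cds_at_transcript_start_gives_empty_5p(self, toy_genome):
        model = TranscriptModel(
            transcript_id="tx",
            contig="chr1",
            strand="+",
            exons=((100, 200),),
            cds_start=100,
            cds_end=190,
        )
        r5, r3 = extract_utrs(model, toy_genome)
        assert r5.length == 0 and not r5.admissible

    def test_strand_symmetry_of_uaug_count(self, toy_genome):
        # the minus-strand mRNA equals an independently reverse-complemented
        # construction of the same transcript
        model = TranscriptModel(
            transcript_id="tx",
            contig="chr1",
            strand="-",
            exons=((50, 120), (160, 260)),
            cds_start=100,
            cds_end=200,
        )
        r5, _ = extract_utrs(model, toy_genome)
        # manual: 5'UTR of a minus transcript = revcomp of genomic right part
        manual = revcomp(
            (toy_genome["chr1"][200:260]).upper()
        )
        assert r5.sequence == manual
        assert r5.uaug_count == count_uaugs(manual)

    def test_base_conservation_identity(self, toy_genome):
        model = TranscriptModel(
            transcript_id="tx",
            contig="chr1",
            strand="+",
            exons=((50, 120), (160, 260)),
            cds_start=100,
            cds_end=200,
        )
        r5, r3 = extract_utrs(model, toy_genome)
        assert r5.length + model.cds_length + r3.length == model.spliced_length

    def test_unknown_contig_raises(self, plus_model):
        with pytest.raises(KeyError):
            extract_utrs(plus_model, {"chr2": "ACGT"})

    def test_cds_in_intron_rejected(self):
        with pytest.raises(ValueError, match="inside exons"):
            TranscriptModel(
                transcript_id="tx",
                contig="chr1",
                strand="+",
                exons=((0, 10), (20, 30)),
                cds_start=12,
                cds_end=25,
            )


class TestCountUaugs:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ATGGATGC", 2), ("CCCCCC", 0), ("ATGATG", 2), ("", 0), ("ATN", 0), ("aTgATG", 2)],
    )
    def test_examples(self, seq, expected):
        assert count_uaugs(seq) == expected

    @settings(max_examples=200, derandomize=True)
    @given(st.text(alphabet="ACGTN", max_size=300))
    def test_matches_overlap_aware_regex(self, seq):
        assert count_uaugs(seq) == len(re.findall("(?=ATG)", seq))


class TestAugScore:
    def test_ratio(self):
        assert aug_score(2, 100) == pytest.approx(0.02)
        assert aug_score(0, 50) == 0.0

    def test_short_utr_is_excluded_not_zero(self):
        with pytest.raises(UTRTooShortError):
            aug_score(3, 29)

    def test_scales_inversely_with_length(self):
        lengths = [50, 100, 200, 400]
        scores = [aug_score(4, n) for n in lengths]
        assert all(a > b for a, b in zip(scores, scores[1:]))


def brute_force_mean(model, side, track):
    """Per-base loop oracle for conservation mapping."""
    total, n = 0.0, 0
    for s, e in model.utr_intervals(side):
        for pos in range(s, e):
            score, covered = track.scores_at(model.contig, np.array([pos]))
            if covered[0]:
                total += float(score[0])
                n += 1
    return (total / n if n else None), n


class TestMapConservation:
    def test_constant_track(self, plus_model, constant_track):
        mean, covered = map_conservation(plus_model, "5p", constant_track)
        assert mean == pytest.approx(1.0) and covered == 30

    def test_two_exon_utr_skips_intron(self):
        model = TranscriptModel(
            transcript_id="tx",
            contig="c",
            strand="+",
            exons=((100, 110), (150, 165)),
            cds_start=155,
            cds_end=165,
        )
        track = ConservationTrack()
        track.add_interval("c", 100, 110, 0.0)
        track.add_interval("c", 110, 160, 2.0)  # covers intron too; ignored
        mean, covered = map_conservation(model, "5p", track)
        # 5'UTR = [100,110) at 0.0 and [150,155) at 2.0: mean 10/15
        assert covered == 15
        assert mean == pytest.approx((10 * 0.0 + 5 * 2.0) / 15)
        assert (mean, covered) == pytest.approx(brute_force_mean(model, "5p", track))

    def test_missing_positions_skipped(self):
        model = TranscriptModel(
            transcript_id="tx",
            contig="c",
            strand="+",
            exons=((0, 40),),
            cds_start=30,
            cds_end=40,
        )
        track = ConservationTrack()
        track.add_interval("c", 0, 15, 0.5)  # only half the 30-base 5'UTR
        mean, covered = map_conservation(model, "5p", track)
        assert mean == pytest.approx(0.5) and covered == 15

    def test_minus_strand_value_equals_plus(self, toy_genome):
        kw = dict(contig="chr1", exons=((100, 200),), cds_start=130, cds_end=190)
        plus = TranscriptModel(transcript_id="p", strand="+", **kw)
        minus = TranscriptModel(transcript_id="m", strand="-", **kw)
        track = ConservationTrack()
        rng = np.random.default_rng(0)
        track.add_values("chr1", 90, rng.normal(size=120))
        # strand flips which end is 5', but scores per genomic interval agree
        m_plus, _ = map_conservation(plus, "5p", track)
        m_minus, _ = map_conservation(minus, "3p", track)
        assert m_plus == pytest.approx(m_minus)

    def test_zero_coverage_raises(self, plus_model):
        with pytest.raises(ValueError, match="no conservation coverage"):
            map_conservation(plus_model, "5p", ConservationTrack())


class TestSummarize:
    def _records(self, toy_genome):
        models = [
            TranscriptModel(
                transcript_id=f"t{i}", gene_id=f"g{i}", contig="chr1", strand="+",
                exons=((0, 120),), cds_start=40, cds_end=80,
            )
            for i in range(4)
        ]
        recs = []
        for m in models:
            r5, r3 = extract_utrs(m, toy_genome)
            recs += [r5, r3]
        return recs

    def test_row_count_two_sides_per_gene(self, toy_genome):
        groups = PartitionGroups(
            up_intersect=frozenset({"g0", "g1"}),
            down_er_only=frozenset({"g2", "g3"}),
        )
        df = summarize_features(self._records(toy_genome), groups)
        assert len(df) == 8
        assert set(df["group"]) == {"up_intersect", "down_er_only"}

    def test_gene_in_two_groups_rejected(self, toy_genome):
        groups = PartitionGroups(
            up_intersect=frozenset({"g0"}), down_er_only=frozenset({"g0"})
        )
        with pytest.raises(ValueError, match="more than one group"):
            summarize_features(self._records(toy_genome), groups)

    def test_group_summary_quartiles(self, toy_genome):
        groups = PartitionGroups(up_intersect=frozenset({"g0", "g1", "g2", "g3"}))
        df = summarize_features(self._records(toy_genome), groups)
        summ = group_summary(df)
        row = summ[(summ["side"] == "5p") & (summ["feature"] == "length")].iloc[0]
        assert row["median"] == 40 and row["n"] == 4
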