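"""Exon-aware UTR extraction and per-UTR features.

From a transcript model (exon blocks + CDS on genomic coordinates) and a
genome sequence store this module derives the 5' and 3' untranslated regions
in mRNA orientation, counts upstream AUG trinucleotides, computes the AUG
score (uAUG count per nucleotide of 5'UTR), and maps a basewise conservation
track onto the exonic UTR positions of each transcript.

Coordinates are 0-based half-open throughout, matching BED conventions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .partitioning import PartitionGroups
from .tracks import ConservationTrack

__all__ = [
    "TranscriptModel",
    "UTRRecord",
    "MIN_UTR_LENGTH",
    "UTRTooShortError",
    "extract_utrs",
    "count_uaugs",
    "aug_score",
    "map_conservation",
    "summarize_features",
    "group_summary",
]

#: UTRs shorter than this are excluded from feature analysis
MIN_UTR_LENGTH = 30


class UTRTooShortError(ValueError):
    """Raised when a UTR is below the admissible length for scoring."""


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript's exon/CDS structure on genomic coordinates.

    ``exons`` are sorted, non-overlapping (start, end) blocks, 0-based
    half-open; ``cds_start``/``cds_end`` delimit the coding span on the
    genome (strand-independent, like BED thickStart/thickEnd).
    """

    transcript_id: str
    contig: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]
    cds_start: int
    cds_end: int
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-': {self.strand!r}")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = -1
        for s, e in exons:
            if e <= s:
                raise ValueError(f"empty exon block [{s}, {e})")
            if s < prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = e
        if not (exons[0][0] <= self.cds_start <= self.cds_end <= exons[-1][1]):
            raise ValueError("CDS must lie within the exon span")
        if self.cds_start < self.cds_end:
            start_ok = any(s <= self.cds_start < e for s, e in exons)
            end_ok = any(s < self.cds_end <= e for s, e in exons)
            if not (start_ok and end_ok):
                raise ValueError("CDS boundaries must fall inside exons")
        if self.gene_id is None:
            object.__setattr__(self, "gene_id", self.transcript_id)

    def _exonic_length(self, start: int, end: int) -> int:
        return sum(max(0, min(e, end) - max(s, start)) for s, e in self.exons)

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return self._exonic_length(self.cds_start, self.cds_end)

    def utr_intervals(self, side: str) -> Tuple[Tuple[int, int], ...]:
        """Genomic (start, end) blocks of one UTR, in genomic order.

        The 5'UTR is upstream of the CDS in mRNA orientation: genomically
        left of cds_start on '+', right of cds_end on '-'.
        """
        if side not in ("5p", "3p"):
            raise ValueError(f"side must be '5p' or '3p': {side!r}")
        left = tuple(
            (s, min(e, self.cds_start)) for s, e in self.exons if s < self.cds_start
        )
        right = tuple(
            (max(s, self.cds_end), e) for s, e in self.exons if e > self.cds_end
        )
        if self.strand == "+":
            return left if side == "5p" else right
        return right if side == "5p" else left


@dataclass
class UTRRecord:
    """One UTR of one transcript, with its analysis features.

    ``sequence`` is mRNA-sense DNA (minus-strand transcripts are
    reverse-complemented).  ``uaug_count`` is populated for 5'UTRs only,
    ``aug_score`` only when the UTR reaches the minimum analysable length.
    """

    transcript_id: str
    side: str
    sequence: str
    uaug_count: Optional[int] = None
    aug_score: Optional[float] = None
    mean_conservation: Optional[float] = None
    covered_bases: int = 0
    gene_id: Optional[str] = None

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def admissible(self) -> bool:
        return self.length >= MIN_UTR_LENGTH


def _fetch(genome: Mapping[str, object], contig: str, start: int, end: int) -> str:
    try:
        ref = genome[contig]
    except KeyError as exc:
        raise KeyError(f"unknown contig {contig!r}") from exc
    return str(ref[start:end]).upper()


def extract_utrs(
    model: TranscriptModel, genome: Mapping[str, object]
) -> Tuple[UTRRecord, UTRRecord]:
    """Extract (5'UTR, 3'UTR) records in mRNA orientation.

    ``genome`` may be any mapping from contig name to a sliceable sequence
    (a plain string dict or an indexed FASTA handle).
    """
    records = []
    for side in ("5p", "3p"):
        blocks = model.utr_intervals(side)
        seq = "".join(_fetch(genome, model.contig, s, e) for s, e in blocks)
        if model.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        uaug = count_uaugs(seq) if side == "5p" else None
        score = None
        if side == "5p" and len(seq) >= MIN_UTR_LENGTH:
            score = aug_score(uaug, len(seq))
        records.append(
            UTRRecord(
                transcript_id=model.transcript_id,
                side=side,
                sequence=seq,
                uaug_count=uaug,
                aug_score=score,
                gene_id=model.gene_id,
            )
        )
    return records[0], records[1]


def count_uaugs(seq: str) -> int:
    """Number of ATG trinucleotides in a 5'UTR, overlapping occurrences counted.

    Any ATG upstream of the main start codon counts regardless of reading
    frame or a downstream stop: the raw count is the feature, not uORF
    structure.  N matches nothing.
    """
    seq = seq.upper()
    count = 0
    i = seq.find("ATG")
    while i != -1:
        count += 1
        i = seq.find("ATG", i + 1)
    return count


def aug_score(count: int, length: int) -> float:
    """uAUG count per nucleotide of 5'UTR.

    UTRs shorter than the minimum analysable length are excluded rather than
    scored as zero, since a very short UTR carries no information about AUG
    density.
    """
    if length < MIN_UTR_LENGTH:
        raise UTRTooShortError(
            f"UTR length {length} below minimum {MIN_UTR_LENGTH}; excluded from scoring"
        )
    if count < 0:
        raise ValueError("negative uAUG count")
    return count / length


def map_conservation(
    model: TranscriptModel, side: str, track: ConservationTrack
) -> Tuple[float, int]:
    """Mean basewise conservation over the exonic UTR positions.

    Intronic bases are never included; track positions with no data are
    skipped and do not enter the denominator.  The value is
    strand-independent (conservation is a property of the genomic base).
    Raises ``ValueError`` when no UTR position is covered.
    """
    blocks = model.utr_intervals(side)
    if not blocks:
        raise ValueError(f"transcript {model.transcript_id} has an empty {side} UTR")
    positions = np.concatenate([np.arange(s, e) for s, e in blocks])
    scores, covered = track.scores_at(model.contig, positions)
    n_cov = int(covered.sum())
    if n_cov == 0:
        raise ValueError(
            f"no conservation coverage for {model.transcript_id} {side} UTR"
        )
    return float(np.mean(scores[covered])), n_cov


def summarize_features(
    records: Sequence[UTRRecord],
    groups: PartitionGroups,
    gene_centered: bool = False,
    min_length: int = MIN_UTR_LENGTH,
) -> pd.DataFrame:
    """Assemble the per-transcript (or per-gene) feature table by group.

    Rows: (gene, transcript, group, side, length, uaug_count, aug_score,
    mean_conservation).  UTRs shorter than ``min_length`` are dropped.  With
    ``gene_centered=True`` feature values are averaged over a gene's
    transcripts.  A gene assigned to more than one regulated group is an
    error (can arise when a gene moves in opposite directions in the two
    fractions).
    """
    group_map = groups.group_of()
    for gene, names in group_map.items():
        if len(names) > 1:
            raise ValueError(f"gene {gene} present in more than one group: {names}")
    rows = []
    for rec in records:
        if rec.length < min_length:
            continue
        gene = rec.gene_id or rec.transcript_id
        if gene in group_map:
            group = group_map[gene][0]
        elif gene in groups.unchanged:
            group = "unchanged"
        else:
            continue
        rows.append(
            {
                "gene_id": gene,
                "transcript_id": rec.transcript_id,
                "group": group,
                "side": rec.side,
                "length": rec.length,
                "uaug_count": rec.uaug_count if rec.side == "5p" else np.nan,
                "aug_score": rec.aug_score if rec.side == "5p" else np.nan,
                "mean_conservation": (
                    rec.mean_conservation if rec.mean_conservation is not None else np.nan
                ),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "transcript_id",
            "group",
            "side",
            "length",
            "uaug_count",
            "aug_score",
            "mean_conservation",
        ],
    )
    if gene_centered and not df.empty:
        df = (
            df.groupby(["gene_id", "group", "side"], as_index=False)
            .agg(
                length=("length", "mean"),
                uaug_count=("uaug_count", "mean"),
                aug_score=("aug_score", "mean"),
                mean_conservation=("mean_conservation", "mean"),
            )
            .assign(transcript_id=lambda d: d["gene_id"])
        )
    return df


def group_summary(features: pd.DataFrame) -> pd.DataFrame:
    """Median and quartiles of each feature per (group, side), boxplot-style."""
    value_cols = ["length", "uaug_count", "aug_score", "mean_conservation"]
    out = []
    for (group, side), sub in features.groupby(["group", "side"]):
        for col in value_cols:
            vals = sub[col].dropna()
            if vals.empty:
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            out.append(
                {
                    "group": group,
                    "side": side,
                    "feature": col,
                    "n": int(vals.size),
                    "q1": q1,
                    "median": med,
                    "q3": q3,
                }
            )
    return pd.DataFrame(out, columns=["group", "side", "feature", "n", "q1", "median", "q3"])
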