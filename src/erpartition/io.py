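"""Readers and writers for the pipeline's plain-text formats.

Expression tables use a TSV with a two-line header (sample id, then
``fraction:condition``); transcript models are BED12 (0-based half-open,
thickStart/thickEnd as the CDS span); conservation tracks are fixedStep
wiggle (1-based starts, converted on read) or bedGraph (0-based half-open);
gene-set annotations are GMT-style TSV.  Genome FASTA is read through
pyfaidx for indexed access.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Set, Union

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .partitioning import ExpressionTable, PartitionGroups
from .tracks import ConservationTrack
from .utr_features import TranscriptModel

__all__ = [
    "read_expression",
    "write_expression",
    "read_bed12",
    "write_bed12",
    "read_track",
    "write_wig",
    "read_fasta",
    "load_genome",
    "write_fasta",
    "read_gmt",
    "write_groups",
    "read_groups",
]

PathLike = Union[str, os.PathLike]


# ----------------------------------------------------------------- expression

def read_expression(path: PathLike) -> ExpressionTable:
    """Read the two-header-line expression TSV."""
    with open(path) as fh:
        header1 = fh.readline().rstrip("\n").split("\t")
        header2 = fh.readline().rstrip("\n").split("\t")
        if len(header1) < 2 or len(header1) != len(header2):
            raise ValueError("malformed expression header")
        sample_ids = header1[1:]
        fractions, conditions = [], []
        for label in header2[1:]:
            if ":" not in label:
                raise ValueError(f"sample label must be fraction:condition, got {label!r}")
            frac, cond = label.split(":", 1)
            fractions.append(frac)
            conditions.append(cond)
        try:
            data = pd.read_csv(
                fh, sep="\t", header=None, names=["gene_id"] + sample_ids, index_col=0
            )
        except ValueError as exc:
            raise ValueError(f"malformed expression body: {exc}") from exc
    if data.index.duplicated().any():
        dup = data.index[data.index.duplicated()][0]
        raise ValueError(f"duplicate gene id: {dup}")
    values = data.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        bad = data[values.isna().any(axis=1)].index[0]
        raise ValueError(f"non-numeric expression value for gene {bad}")
    samples = pd.DataFrame(
        {"fraction": fractions, "condition": conditions},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ExpressionTable(values, samples)


def write_expression(table: ExpressionTable, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(table.samples.index) + "\n")
        labels = [
            f"{row['fraction']}:{row['condition']}" for _, row in table.samples.iterrows()
        ]
        fh.write("\t" + "\t".join(labels) + "\n")
        for gene, row in table.data.iterrows():
            fh.write(gene + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


# ---------------------------------------------------------------------- BED12

def _split_name(name: str) -> tuple:
    if "|" in name:
        tx, gene = name.split("|", 1)
        return tx, gene
    return name, None


def read_bed12(path: PathLike) -> List[TranscriptModel]:
    """Read transcript models from BED12; name is ``transcript|gene`` or plain."""
    models = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"line {line_no}: BED12 needs 12 fields, got {len(f)}")
            chrom, start, _end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"line {line_no}: block count mismatch")
            exons = tuple(
                (start + bs, start + bs + sz) for bs, sz in zip(starts, sizes)
            )
            tx, gene = _split_name(name)
            models.append(
                TranscriptModel(
                    transcript_id=tx,
                    gene_id=gene,
                    contig=chrom,
                    strand=strand,
                    exons=exons,
                    cds_start=thick_start,
                    cds_end=thick_end,
                )
            )
    return models


def write_bed12(models: Sequence[TranscriptModel], path: PathLike) -> None:
    with open(path, "w") as fh:
        for m in models:
            start = m.exons[0][0]
            end = m.exons[-1][1]
            name = m.transcript_id if m.gene_id == m.transcript_id else f"{m.transcript_id}|{m.gene_id}"
            sizes = ",".join(str(e - s) for s, e in m.exons) + ","
            offs = ",".join(str(s - start) for s, e in m.exons) + ","
            fh.write(
                "\t".join(
                    [
                        m.contig,
                        str(start),
                        str(end),
                        name,
                        "0",
                        m.strand,
                        str(m.cds_start),
                        str(m.cds_end),
                        "0",
                        str(len(m.exons)),
                        sizes,
                        offs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------- track

def read_track(path: PathLike) -> ConservationTrack:
    """Read fixedStep wiggle or bedGraph into a 0-based sparse track.

    The wiggle fixedStep ``start`` is 1-based per the format definition and
    is converted; bedGraph intervals are already 0-based half-open.
    Overlapping bedGraph intervals and unsorted data producing duplicate
    positions are errors.
    """
    track = ConservationTrack()
    mode = None  # 'wig' or 'bedgraph'
    contig, pos, step, span = None, None, 1, 1
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                mode = "wig"
                fields = dict(kv.split("=") for kv in line.split()[1:])
                contig = fields["chrom"]
                pos = int(fields["start"]) - 1  # wig is 1-based
                step = int(fields.get("step", 1))
                span = int(fields.get("span", 1))
                continue
            if line.startswith("variableStep"):
                raise ValueError(f"line {line_no}: variableStep is not supported")
            parts = line.split()
            if mode == "wig" and len(parts) == 1:
                track.add_values(contig, pos, np.full(span, float(parts[0])))
                pos += step
            elif len(parts) == 4:
                mode = "bedgraph"
                c, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
                if e <= s:
                    raise ValueError(f"line {line_no}: empty bedGraph interval")
                track.add_interval(c, s, e, v)
            else:
                raise ValueError(f"line {line_no}: unrecognized track line {line!r}")
    # force overlap detection now so errors carry no confusing context
    track.contigs()
    return track


def write_wig(track: ConservationTrack, path: PathLike, precision: int = 6) -> None:
    """Write a track as fixedStep wiggle, one block per contiguous run."""
    with open(path, "w") as fh:
        for contig in track.contigs():
            for start, values in track.blocks(contig):
                fh.write(f"fixedStep chrom={contig} start={start + 1} step=1\n")
                for v in values:
                    fh.write(f"{v:.{precision}g}\n")


# ---------------------------------------------------------------------- FASTA

def read_fasta(path: PathLike) -> Dict[str, str]:
    """Read a whole FASTA into a dict (for small synthetic genomes)."""
    seqs: Dict[str, str] = {}
    name = None
    chunks: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def load_genome(path: PathLike) -> Fasta:
    """Open an indexed FASTA handle (builds the .fai on first use)."""
    return Fasta(str(path), sequence_always_upper=True)


def write_fasta(seqs: Mapping[str, str], path: PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = str(seqs[name])
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ------------------------------------------------------------------------ GMT

def read_gmt(path: PathLike) -> Dict[str, Set[str]]:
    """Read a GMT-style annotation: term, description, genes..."""
    terms: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"line {line_no}: GMT needs term, description, genes")
            terms[f[0]] = set(g for g in f[2:] if g)
    return terms


# --------------------------------------------------------------------- groups

def write_groups(groups: PartitionGroups, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tgroup\n")
        for name in (
            "up_total_only",
            "up_intersect",
            "up_er_only",
            "down_total_only",
            "down_intersect",
            "down_er_only",
            "unchanged",
            "not_expressed",
        ):
            for g in sorted(getattr(groups, name)):
                fh.write(f"{g}\t{name}\n")


def read_groups(path: PathLike) -> PartitionGroups:
    sets: Dict[str, set] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene_id"):
            raise ValueError("groups TSV must start with a gene_id header")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            gene, name = line.split("\t")
            sets.setdefault(name, set()).add(gene)
    return PartitionGroups(**{k: frozenset(v) for k, v in sets.items()})
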