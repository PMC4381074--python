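"""End-to-end driver: simulate -> partition -> UTR features -> stats -> motifs.

A :class:`RunConfig` (JSON-serializable, strict keys) describes one
reproducible run; :func:`run_pipeline` executes the enabled stages in
order, writes every intermediate as a plain-text file, and returns a
:class:`RunReport` with record counts, group sizes, the motif table and a
manifest of parameters and output checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import io as eio
from .group_stats import anova_tukey, hypergeom_enrich, scheirer_ray_hare
from .motifs import discover_motifs, scan_counts
from .partitioning import (
    ExpressionTable,
    PartitionGroups,
    call_fraction,
    filter_expressed,
    intersect_groups,
)
from .synthetic import GroundTruth, SimulationConfig, simulate_conservation, simulate_expression, simulate_utrs
from .utr_features import extract_utrs, map_conservation, summarize_features

logger = logging.getLogger("erpartition")

__all__ = ["RunConfig", "RunReport", "run_pipeline", "srh_factors"]

_STAGES = ("simulate", "partition", "utr_features", "stats", "discover", "scan")


@dataclass
class RunConfig:
    """One pipeline run.  Unknown keys in the JSON document are rejected."""

    outdir: str = "run"
    seed: int = 0
    n_genes: int = 2000
    # partitioning
    quantile: float = 0.5
    span: float = 0.3
    fc_thresh: float = 1.4
    z_thresh: float = 3.0
    # UTR features
    min_utr_length: int = 30
    gene_centered: bool = False
    # motif discovery
    widths: Tuple[int, int] = (4, 8)
    e_thresh: float = 0.05
    max_motifs: int = 10
    top_q: int = 100
    motif_group: str = "up_intersect"
    # optional external inputs (paths); simulation fills anything missing
    expression: Optional[str] = None
    genome: Optional[str] = None
    transcripts: Optional[str] = None
    conservation: Optional[str] = None
    annotation: Optional[str] = None
    stages: Dict[str, bool] = field(
        default_factory=lambda: {s: True for s in _STAGES}
    )

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for s in _STAGES:
            self.stages.setdefault(s, True)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        doc = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "widths" in doc:
            doc["widths"] = tuple(doc["widths"])
        return cls(**doc)

    def to_json(self, path) -> None:
        doc = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


@dataclass
class RunReport:
    """Summary of one run: counts, group sizes, motifs, manifest."""

    counts: Dict[str, int]
    group_sizes: Dict[str, int]
    motifs: List[Dict]
    stats: Dict[str, Dict]
    manifest: Dict[str, str]
    params: Dict

    def to_json(self, path) -> None:
        doc = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")

    def check_identities(self) -> None:
        gs = self.group_sizes
        up_total = self.counts.get("up_total")
        if up_total is not None:
            assert gs["up_total_only"] + gs["up_intersect"] == up_total
        down_total = self.counts.get("down_total")
        if down_total is not None:
            assert gs["down_total_only"] + gs["down_intersect"] == down_total


def srh_factors(features: pd.DataFrame) -> pd.DataFrame:
    """Decompose the six-group label into location and expression factors.

    location in {total_only, intersect, er_only}; expression in {up, down}.
    Unchanged genes carry no direction and are excluded.
    """
    sub = features[features["group"].str.startswith(("up_", "down_"))].copy()
    sub["expression"] = np.where(sub["group"].str.startswith("up_"), "up", "down")
    sub["location"] = sub["group"].str.replace(r"^(up|down)_", "", regex=True)
    return sub


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the enabled stages and write all outputs under ``outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts: Dict[str, int] = {}
    stats_out: Dict[str, Dict] = {}
    motifs_out: List[Dict] = []
    written: List[Path] = []
    st = config.stages

    def stage_log(name: str, **info) -> None:
        logger.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in info.items()))

    def fail(stage: str, exc: Exception) -> Exception:
        err = RuntimeError(f"stage {stage!r} failed: {exc}")
        err.__cause__ = exc
        return err

    # ------------------------------------------------------------- simulate
    truth: Optional[GroundTruth] = None
    genome = None
    models = None
    track = None
    table: Optional[ExpressionTable] = None

    if st["simulate"]:
        sim = SimulationConfig(n_genes=config.n_genes, seed=config.seed)
        table, truth = simulate_expression(sim)
        genome, models, truth = simulate_utrs(sim, truth)
        track = simulate_conservation(models, truth, sim)
        eio.write_expression(table, out / "expression.tsv")
        eio.write_fasta(genome, out / "genome.fa")
        eio.write_bed12(models, out / "transcripts.bed")
        eio.write_wig(track, out / "conservation.wig")
        truth.genes.to_csv(out / "ground_truth.tsv", sep="\t")
        written += [
            out / "expression.tsv",
            out / "genome.fa",
            out / "transcripts.bed",
            out / "conservation.wig",
            out / "ground_truth.tsv",
        ]
        counts["genes_simulated"] = table.n_genes
        stage_log("simulate", genes=table.n_genes, contigs=len(genome))

    if table is None:
        if config.expression is None:
            raise RuntimeError("stage 'partition' failed: no expression input and simulation disabled")
        table = eio.read_expression(config.expression)
    if genome is None and config.genome is not None:
        genome = eio.read_fasta(config.genome)
    if models is None and config.transcripts is not None:
        models = eio.read_bed12(config.transcripts)
    if track is None and config.conservation is not None:
        track = eio.read_track(config.conservation)

    # ------------------------------------------------------------ partition
    groups: Optional[PartitionGroups] = None
    if st["partition"]:
        try:
            expressed, not_expressed = filter_expressed(table, config.quantile)
            calls = {
                frac: call_fraction(
                    expressed,
                    frac,
                    span=config.span,
                    fc_thresh=config.fc_thresh,
                    z_thresh=config.z_thresh,
                )
                for frac in ("total", "er")
            }
            groups = intersect_groups(calls["total"], calls["er"], not_expressed)
        except Exception as exc:
            raise fail("partition", exc)
        all_calls = pd.concat(calls.values())
        all_calls.to_csv(out / "calls.tsv", sep="\t", index_label="gene_id")
        eio.write_groups(groups, out / "groups.tsv")
        written += [out / "calls.tsv", out / "groups.tsv"]
        counts["genes_expressed"] = expressed.n_genes
        counts["up_total"] = int((calls["total"]["status"] == "up").sum())
        counts["down_total"] = int((calls["total"]["status"] == "down").sum())
        counts["up_er"] = int((calls["er"]["status"] == "up").sum())
        counts["down_er"] = int((calls["er"]["status"] == "down").sum())
        stage_log("partition", expressed=expressed.n_genes, **groups.sizes())

    # --------------------------------------------------------- utr features
    features = None
    utr5 = {}
    utr3 = {}
    if st["utr_features"]:
        if genome is None or models is None:
            raise RuntimeError("stage 'utr_features' failed: genome/transcripts missing")
        if groups is None:
            raise RuntimeError("stage 'utr_features' failed: partitioning disabled")
        try:
            records = []
            for m in models:
                r5, r3 = extract_utrs(m, genome)
                if track is not None:
                    for rec, side in ((r5, "5p"), (r3, "3p")):
                        try:
                            mean, cov = map_conservation(m, side, track)
                            rec.mean_conservation, rec.covered_bases = mean, cov
                        except ValueError:
                            pass
                utr5[m.transcript_id] = r5
                utr3[m.transcript_id] = r3
                records += [r5, r3]
            features = summarize_features(
                records, groups, gene_centered=config.gene_centered,
                min_length=config.min_utr_length,
            )
        except Exception as exc:
            raise fail("utr_features", exc)
        features.to_csv(out / "features.tsv", sep="\t", index=False)
        written.append(out / "features.tsv")
        counts["utr_records"] = len(features)
        stage_log("utr_features", records=len(features))

    # ---------------------------------------------------------------- stats
    if st["stats"]:
        if features is None:
            raise RuntimeError("stage 'stats' failed: utr_features disabled")
        try:
            sub = srh_factors(features)
            f5 = sub[(sub["side"] == "5p") & sub["aug_score"].notna()]
            if not f5.empty and f5["location"].nunique() >= 2 and f5["expression"].nunique() >= 2:
                srh = scheirer_ray_hare(
                    f5["aug_score"].to_numpy(), f5["location"], f5["expression"]
                )
                stats_out["srh_aug_score"] = {
                    "h": srh.h, "df": srh.df, "p": srh.p, "n": srh.n,
                }
            for side in ("5p", "3p"):
                fc = features[
                    (features["side"] == side) & features["mean_conservation"].notna()
                ]
                if fc["group"].nunique() >= 2 and fc.groupby("group").size().min() >= 2:
                    tab = anova_tukey(fc["mean_conservation"].to_numpy(), fc["group"])
                    tab.to_csv(out / f"tukey_conservation_{side}.tsv", sep="\t", index=False)
                    written.append(out / f"tukey_conservation_{side}.tsv")
                    stats_out[f"anova_conservation_{side}"] = {
                        "f_stat": tab.attrs["f_stat"],
                        "f_p": tab.attrs["f_p"],
                        "flags": tab.attrs["flags"],
                    }
            if config.annotation is not None and groups is not None:
                terms = eio.read_gmt(config.annotation)
                universe = set().union(
                    *(getattr(groups, n) for n in (
                        "up_total_only", "up_intersect", "up_er_only",
                        "down_total_only", "down_intersect", "down_er_only",
                        "unchanged",
                    ))
                )
                enr = hypergeom_enrich(
                    set(getattr(groups, config.motif_group)), terms, universe
                )
                stats_out["enrichment"] = {
                    e.term: {"overlap": e.overlap, "p": e.p, "p_adj": e.p_adj}
                    for e in enr
                }
        except Exception as exc:
            raise fail("stats", exc)
        stage_log("stats", tests=len(stats_out))

    # ------------------------------------------------------------- discover
    discovered5 = []
    discovered3 = []
    if st["discover"]:
        if groups is None or not utr5:
            raise RuntimeError("stage 'discover' failed: upstream stages disabled")
        try:
            pos_genes = getattr(groups, config.motif_group)
            gene_of = {r.transcript_id: r.gene_id for r in utr5.values()}
            for side, store, bucket in (("5p", utr5, discovered5), ("3p", utr3, discovered3)):
                pos_seqs = [
                    r.sequence for r in store.values()
                    if gene_of[r.transcript_id] in pos_genes and r.admissible
                ]
                ref_seqs = [r.sequence for r in store.values() if r.admissible]
                if not pos_seqs:
                    continue
                run = discover_motifs(
                    pos_seqs, ref_seqs,
                    widths=range(config.widths[0], config.widths[1] + 1),
                    e_thresh=config.e_thresh, max_motifs=config.max_motifs,
                    top_q=config.top_q, seed=config.seed,
                )
                bucket.extend(run.motifs)
                for m in run.motifs:
                    motifs_out.append(
                        {
                            "side": side, "word": m.word, "width": m.width,
                            "pos_with": m.pos_with, "pos_total": m.pos_total,
                            "ref_with": m.ref_with, "ref_total": m.ref_total,
                            "p": m.p, "e": m.e, "iteration": m.iteration,
                        }
                    )
        except Exception as exc:
            raise fail("discover", exc)
        pd.DataFrame(
            motifs_out,
            columns=["side", "word", "width", "pos_with", "pos_total",
                     "ref_with", "ref_total", "p", "e", "iteration"],
        ).to_csv(out / "motifs.tsv", sep="\t", index=False)
        written.append(out / "motifs.tsv")
        counts["motifs"] = len(motifs_out)
        stage_log("discover", motifs=len(motifs_out))

    # ----------------------------------------------------------------- scan
    if st["scan"]:
        if not utr5:
            raise RuntimeError("stage 'scan' failed: utr_features disabled")
        try:
            rows = []
            for tx in utr5:
                n_sites = scan_counts(
                    discovered5, discovered3, utr5[tx].sequence, utr3[tx].sequence
                )
                rows.append({"transcript_id": tx, "cis_element_sites": n_sites})
            scan_df = pd.DataFrame(rows)
        except Exception as exc:
            raise fail("scan", exc)
        scan_df.to_csv(out / "scan_counts.tsv", sep="\t", index=False)
        written.append(out / "scan_counts.tsv")
        stage_log("scan", transcripts=len(scan_df))

    manifest = {str(p.name): _sha256(p) for p in written}
    params = dataclasses.asdict(config)
    report = RunReport(
        counts=counts,
        group_sizes=groups.sizes() if groups is not None else {},
        motifs=motifs_out,
        stats=stats_out,
        manifest=manifest,
        params=params,
    )
    if groups is not None:
        report.check_identities()
    report.to_json(out / "report.json")
    return report
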