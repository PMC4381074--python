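"""Synthetic-truth benchmarks of the pipeline's operating characteristics.

Every function here generates data with the synthetic module (or enumerates
small cases), runs the corresponding pipeline stage, and measures how well
the known truth is recovered: caller sensitivity and false-call rate, null
z-score calibration, agreement of the statistical kernels with brute-force
oracles, motif recovery, and end-to-end parameter recovery.  They power
both the test suite and the reproduction script.
"""

from __future__ import annotations

import math
from typing import Dict, List, Tuple

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .group_stats import scheirer_ray_hare
from .motifs import discover_motifs, fisher_p, match_sites
from .partitioning import call_fraction, filter_expressed, intersect_groups
from .synthetic import (
    GROUPS,
    SimulationConfig,
    simulate_conservation,
    simulate_expression,
    simulate_utrs,
)
from .tracks import ConservationTrack
from .utr_features import TranscriptModel, count_uaugs, extract_utrs, map_conservation

#: (effect in total, effect in ER) sign per group, for scoring calls
GROUP_EFFECT = {
    "up_total_only": (1, 0),
    "up_intersect": (1, 1),
    "up_er_only": (0, 1),
    "down_total_only": (-1, 0),
    "down_intersect": (-1, -1),
    "down_er_only": (0, -1),
    "unchanged": (0, 0),
}


# ------------------------------------------------------------------- caller

def caller_operating_characteristics(seed: int, n_genes: int = 10_000) -> Dict[str, float]:
    """Sensitivity and false-call rate of the regulation caller.

    Planted effects of 1.5 log2 units under the default heteroscedastic
    noise; a planted (fraction, direction) pair counts as detected when the
    call in that fraction has the planted direction.
    """
    cfg = SimulationConfig(n_genes=n_genes, seed=seed)
    table, truth = simulate_expression(cfg)
    calls = {f: call_fraction(table, f) for f in ("total", "er")}
    groups = truth.genes["group"]
    tp = fn = fp = tn = 0
    for i, frac in enumerate(("total", "er")):
        status = calls[frac]["status"]
        for gene, grp in groups.items():
            expected = GROUP_EFFECT[grp][i]
            got = status[gene]
            if expected == 1:
                tp += got == "up"
                fn += got != "up"
            elif expected == -1:
                tp += got == "down"
                fn += got != "down"
            else:
                fp += got != "unchanged"
                tn += got == "unchanged"
    return {
        "sensitivity": tp / (tp + fn),
        "false_call_rate": fp / (fp + tn),
    }


def null_z_tail(seed: int, n_genes: int = 10_000) -> float:
    """Fraction of |z| >= 3 when no effects are planted (Gaussian ~ 0.0027)."""
    cfg = SimulationConfig(n_genes=n_genes, seed=seed, effect_size=0.0)
    table, _ = simulate_expression(cfg)
    calls = call_fraction(table, "total")
    return float((calls["z"].abs() >= 3).mean())


def set_identity_gap(seed: int, n_genes: int = 5_000) -> Dict[str, int]:
    """|up_total_only| + |up_intersect| - |up_total| (0 when the algebra holds)."""
    cfg = SimulationConfig(n_genes=n_genes, seed=seed)
    table, _ = simulate_expression(cfg)
    expressed, not_expressed = filter_expressed(table)
    calls = {f: call_fraction(expressed, f) for f in ("total", "er")}
    groups = intersect_groups(calls["total"], calls["er"], not_expressed)
    up_total = int((calls["total"]["status"] == "up").sum())
    down_total = int((calls["total"]["status"] == "down").sum())
    return {
        "up_gap": len(groups.up_total_only) + len(groups.up_intersect) - up_total,
        "down_gap": len(groups.down_total_only) + len(groups.down_intersect) - down_total,
        "up_total": up_total,
    }


# ------------------------------------------------------------------ oracles

def _srh_balanced_oracle(values, fa, fb) -> Dict[str, float]:
    """Rank ANOVA by margin/cell means — valid for balanced designs only."""
    values = np.asarray(values, dtype=float)
    fa = np.asarray(fa)
    fb = np.asarray(fb)
    r = stats.rankdata(values)
    n = r.size
    gm = r.mean()
    ss_total = float(((r - gm) ** 2).sum())
    if ss_total == 0.0:
        return {"factor_a": 0.0, "factor_b": 0.0, "interaction": 0.0}
    ms = ss_total / (n - 1)
    ss_a = sum((r[fa == a].mean() - gm) ** 2 * (fa == a).sum() for a in np.unique(fa))
    ss_b = sum((r[fb == b].mean() - gm) ** 2 * (fb == b).sum() for b in np.unique(fb))
    ss_cells = sum(
        (r[(fa == a) & (fb == b)].mean() - gm) ** 2 * ((fa == a) & (fb == b)).sum()
        for a in np.unique(fa)
        for b in np.unique(fb)
    )
    return {
        "factor_a": ss_a / ms,
        "factor_b": ss_b / ms,
        "interaction": (ss_cells - ss_a - ss_b) / ms,
    }


def srh_oracle_max_error(seed: int, n_cases: int = 300) -> float:
    """Worst |H - H_oracle| over random balanced designs with N <= 12."""
    rng = np.random.default_rng(seed)
    designs = [
        (2, 2, 2),  # a levels, b levels, n per cell
        (2, 2, 3),
        (3, 2, 2),
        (2, 3, 2),
    ]
    worst = 0.0
    for _ in range(n_cases):
        a, b, npc = designs[rng.integers(len(designs))]
        fa = np.repeat([f"a{i}" for i in range(a)], b * npc)
        fb = np.tile(np.repeat([f"b{j}" for j in range(b)], npc), a)
        if rng.random() < 0.5:
            values = rng.permutation(a * b * npc).astype(float)
        else:
            values = rng.integers(0, 4, a * b * npc).astype(float)  # ties
        res = scheirer_ray_hare(values, fa, fb)
        oracle = _srh_balanced_oracle(values, fa, fb)
        for k in oracle:
            worst = max(worst, abs(res.h[k] - oracle[k]))
    return worst


def srh_type1_rates(seed: int, reps: int = 5_000) -> Dict[str, float]:
    """Rejection rates at nominal 0.05 for a null balanced 3x2, n=10/cell."""
    rng = np.random.default_rng(seed)
    fa = np.repeat(["a", "b", "c"], 20)
    fb = np.tile(np.repeat(["x", "y"], 10), 3)
    rej = np.zeros(3)
    for _ in range(reps):
        res = scheirer_ray_hare(rng.normal(size=60), fa, fb)
        rej += [
            res.p["factor_a"] < 0.05,
            res.p["factor_b"] < 0.05,
            res.p["interaction"] < 0.05,
        ]
    return {
        "factor_a": rej[0] / reps,
        "factor_b": rej[1] / reps,
        "interaction": rej[2] / reps,
    }


def fisher_exhaustive_max_error(max_total: int = 60) -> float:
    """Worst |p - oracle| over all 2x2 tables with grand total <= max_total.

    The oracle is a direct summation of the hypergeometric pmf computed
    from log-gamma, independent of the survival-function route the
    implementation takes.  The per-table function is additionally checked
    one call at a time on every table with grand total <= 20.
    """
    worst = 0.0
    for pt in range(1, max_total):
        for rt in range(1, max_total - pt + 1):
            M = pt + rt
            nw = np.arange(M + 1)[:, None]
            k = np.arange(pt + 1)[None, :]
            with np.errstate(all="ignore"):
                logpmf = (
                    gammaln(nw + 1) - gammaln(k + 1) - gammaln(nw - k + 1)
                    + gammaln(M - nw + 1) - gammaln(pt - k + 1)
                    - gammaln(np.maximum(M - nw - (pt - k), 0) + 1)
                    - (gammaln(M + 1) - gammaln(pt + 1) - gammaln(rt + 1))
                )
            valid = (k <= nw) & ((pt - k) <= (M - nw))
            pmf = np.where(valid, np.exp(np.where(valid, logpmf, -np.inf)), 0.0)
            tails = pmf[:, ::-1].cumsum(axis=1)[:, ::-1]
            pw = np.arange(pt + 1)[:, None]
            rw = np.arange(rt + 1)[None, :]
            ours = stats.hypergeom.sf(pw - 1, M, pw + rw, pt)
            oracle = tails[pw + rw, np.broadcast_to(pw, (pt + 1, rt + 1))]
            worst = max(worst, float(np.abs(ours - oracle).max()))
            if M <= 20:
                for a in range(pt + 1):
                    for b in range(rt + 1):
                        worst = max(worst, abs(fisher_p(a, pt, b, rt) - tails[a + b, a]))
    return worst


def conservation_oracle_max_error() -> float:
    """Worst mapper error against a per-base loop oracle on toy cases.

    Cases cover multi-exon UTRs, minus-strand transcripts and tracks with
    gaps.
    """
    track = ConservationTrack()
    rng = np.random.default_rng(0)
    track.add_values("c", 100, rng.normal(size=40))  # [100, 140)
    track.add_values("c", 150, rng.normal(size=30))  # gap [140, 150)
    track.add_values("c", 200, rng.normal(size=60))
    cases = [
        TranscriptModel("t1", "c", "+", ((100, 130), (150, 170)), 155, 165),
        TranscriptModel("t2", "c", "-", ((100, 130), (150, 170)), 155, 165),
        TranscriptModel("t3", "c", "+", ((120, 160),), 152, 158),  # gap inside UTR
        TranscriptModel("t4", "c", "-", ((200, 230), (240, 260)), 225, 250),
    ]
    worst = 0.0
    for model in cases:
        for side in ("5p", "3p"):
            total, n = 0.0, 0
            for s, e in model.utr_intervals(side):
                for pos in range(s, e):
                    score, cov = track.scores_at(model.contig, np.array([pos]))
                    if cov[0]:
                        total += float(score[0])
                        n += 1
            if n == 0:
                continue
            mean, covered = map_conservation(model, side, track)
            worst = max(worst, abs(mean - total / n))
            if covered != n:
                worst = max(worst, 1.0)
    return worst


def uaug_regex_mismatches(seed: int, n_seqs: int = 10_000) -> int:
    """Count of disagreements with an overlap-aware regex oracle."""
    import re

    rng = np.random.default_rng(seed)
    letters = np.array(list("ACGTN"))
    probs = np.array([0.24, 0.24, 0.24, 0.24, 0.04])
    mismatches = 0
    for _ in range(n_seqs):
        length = int(rng.integers(0, 200))
        seq = "".join(letters[rng.choice(5, size=length, p=probs)])
        if count_uaugs(seq) != len(re.findall("(?=ATG)", seq)):
            mismatches += 1
    return mismatches


# -------------------------------------------------------------------- motifs

def _random_seqs(rng: np.random.Generator, n: int, length: int, gc: float = 0.6) -> List[str]:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return [
        "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])
        for _ in range(n)
    ]


def motif_recovery(
    seed: int,
    n_pos: int = 500,
    n_ref: int = 2_000,
    length: int = 150,
    prob: float = 0.3,
    word: str = "CCGCGC",
) -> Dict[str, float]:
    """Plant a motif and measure recovery by the discovery loop.

    Returns the top motif's E-value and the fraction of planted sites its
    matcher hits.
    """
    rng = np.random.default_rng(seed)
    ref = _random_seqs(rng, n_ref, length)
    pos = _random_seqs(rng, n_pos, length)
    planted: List[Tuple[int, int]] = []
    for i in range(n_pos):
        if rng.random() < prob:
            start = int(rng.integers(0, length - len(word) + 1))
            pos[i] = pos[i][:start] + word + pos[i][start + len(word) :]
            planted.append((i, start))
    run = discover_motifs(pos, ref)
    if not run.motifs:
        return {"top_e": float("inf"), "site_fraction": 0.0, "n_motifs": 0}
    top = run.motifs[0]
    hit = 0
    for i, start in planted:
        sites = match_sites(top.word, pos[i])
        if any(p < start + len(word) and start < p + top.width for p in sites):
            hit += 1
    return {
        "top_e": top.e,
        "site_fraction": hit / max(len(planted), 1),
        "n_motifs": len(run.motifs),
    }


def motif_null_zero_rate(
    seed: int,
    n_runs: int = 100,
    n_all: int = 500,
    n_pos: int = 100,
    length: int = 80,
) -> float:
    """Fraction of null runs (positives = random subset of the reference)
    reporting zero motifs at E < 0.05."""
    zero = 0
    for r in range(n_runs):
        rng = np.random.default_rng((seed + 1) * 10_000 + r)
        allseq = _random_seqs(rng, n_all, length, gc=0.5)
        idx = rng.choice(n_all, size=n_pos, replace=False)
        pos = [allseq[i] for i in idx]
        run = discover_motifs(pos, allseq)
        zero += len(run.motifs) == 0
    return zero / n_runs


# --------------------------------------------------------------- end to end

def group_fraction_recovery(seed: int, n_genes: int = 10_000) -> Dict[str, float]:
    """Max standardized deviation of realized group counts from expectation."""
    cfg = SimulationConfig(n_genes=n_genes, seed=seed)
    _, truth = simulate_expression(cfg)
    counts = truth.genes["group"].value_counts()
    max_z = 0.0
    for g in GROUPS:
        f = cfg.group_fractions[g]
        if f <= 0:
            continue
        se = math.sqrt(f * (1 - f) / n_genes)
        max_z = max(max_z, abs(counts.get(g, 0) / n_genes - f) / se)
    return {"max_abs_z": max_z}


def conservation_shift_recovery(seed: int, n_genes: int = 2_000) -> Dict[str, float]:
    """Recover the planted +1.0 UTR conservation shift through the mapper."""
    cfg = SimulationConfig(n_genes=n_genes, seed=seed)
    _, truth = simulate_expression(cfg)
    genome, models, truth = simulate_utrs(cfg, truth)
    track = simulate_conservation(models, truth, cfg)
    target, others = [], []
    for m in models:
        try:
            mean, _ = map_conservation(m, "5p", track)
        except ValueError:
            continue
        if truth.group_of(m.gene_id) == cfg.conservation_params.shifted_group:
            target.append(mean)
        else:
            others.append(mean)
    shift = float(np.mean(target) - np.mean(others))
    return {"estimated_shift": shift, "error": abs(shift - cfg.conservation_params.group_shift)}


def srh_detection_rate(
    seed: int, n_runs: int = 20, genes_per_group: int = 200
) -> float:
    """How often SRH detects the location factor (p < 0.05) when the
    up-intersect group has a lower planted uAUG rate.

    Six equal groups of ``genes_per_group`` genes; the AUG score is computed
    from the emitted 5'UTR sequences exactly as the pipeline would.
    """
    regulated = [g for g in GROUPS if g != "unchanged"]
    fractions = {g: 1.0 / len(regulated) for g in regulated}
    fractions["unchanged"] = 0.0
    detected = 0
    for r in range(n_runs):
        cfg = SimulationConfig(
            n_genes=genes_per_group * len(regulated),
            seed=(seed + 1) * 1_000 + r,
            group_fractions=fractions,
        )
        _, truth = simulate_expression(cfg)
        genome, models, truth = simulate_utrs(cfg, truth)
        values, loc, expr = [], [], []
        for m in models:
            r5, _ = extract_utrs(m, genome)
            if not r5.admissible:
                continue
            grp = truth.group_of(m.gene_id)
            values.append(r5.uaug_count / r5.length)
            expr.append("up" if grp.startswith("up") else "down")
            loc.append(grp.split("_", 1)[1])
        res = scheirer_ray_hare(values, loc, expr)
        detected += res.p["factor_a"] < 0.05
    return detected / n_runs
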