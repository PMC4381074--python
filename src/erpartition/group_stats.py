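"""Statistics across partition groups.

Three tools used to compare UTR features between the six partition groups:

* the Scheirer--Ray--Hare test, a rank-based non-parametric analogue of
  two-factor ANOVA (factors here: subcellular location and direction of the
  expression change), with H statistics referred to chi-square;
* classical one-way linear ANOVA with single-step Tukey (studentized-range)
  post-hoc contrasts, used for the conservation-score comparisons;
* hypergeometric gene-set enrichment with Benjamini-Hochberg adjustment,
  replacing web-service GO analysis with a user-supplied annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SRHResult",
    "EnrichmentResult",
    "scheirer_ray_hare",
    "anova_tukey",
    "hypergeom_enrich",
]


@dataclass
class SRHResult:
    """Scheirer-Ray-Hare statistics for two factors and their interaction.

    ``h``, ``df`` and ``p`` are keyed by 'factor_a', 'factor_b' and
    'interaction'.  ``ms_total`` is the total mean square of the mid-ranks
    (it already reflects ties, so no separate tie-correction divisor is
    applied); ``tie_factor`` reports the classical correction factor for
    reference only.
    """

    h: Dict[str, float]
    df: Dict[str, int]
    p: Dict[str, float]
    n: int
    ms_total: float
    tie_factor: float


def _type2_ss_on_ranks(
    ranks: np.ndarray, fa: np.ndarray, fb: np.ndarray
) -> Tuple[float, float, float]:
    """Type-II sums of squares of the rank response for A, B, A:B.

    Computed by model comparison with least squares: SS(A | B), SS(B | A)
    and SS(A:B | A, B).  For balanced designs this reduces to the classical
    decomposition.
    """

    def dummies(labels: np.ndarray) -> np.ndarray:
        return pd.get_dummies(pd.Series(labels), drop_first=True).to_numpy(dtype=float)

    n = ranks.size
    intercept = np.ones((n, 1))
    da, db = dummies(fa), dummies(fb)
    inter = (da[:, :, None] * db[:, None, :]).reshape(n, -1)

    def rss(X: np.ndarray) -> float:
        coef, _, _, _ = np.linalg.lstsq(X, ranks, rcond=None)
        resid = ranks - X @ coef
        return float(resid @ resid)

    rss_a = rss(np.hstack([intercept, da]))
    rss_b = rss(np.hstack([intercept, db]))
    rss_ab = rss(np.hstack([intercept, da, db]))
    rss_full = rss(np.hstack([intercept, da, db, inter]))
    ss_a = max(0.0, rss_b - rss_ab)
    ss_b = max(0.0, rss_a - rss_ab)
    ss_int = max(0.0, rss_ab - rss_full)
    return ss_a, ss_b, ss_int


def scheirer_ray_hare(
    values: Sequence[float],
    factor_a: Sequence,
    factor_b: Sequence,
) -> SRHResult:
    """Rank-based two-factor ANOVA.

    All N observations are mid-ranked jointly (ties averaged); the two-way
    sums of squares are computed on the ranks (type II for unbalanced
    designs); H = SS_effect / MS_total with MS_total = SS_total/(N-1); each
    H is referred to chi-square with the effect's degrees of freedom.
    """
    values = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (values.size == fa.size == fb.size):
        raise ValueError("values and factor labels must have equal length")
    levels_a = np.unique(fa)
    levels_b = np.unique(fb)
    if levels_a.size < 2 or levels_b.size < 2:
        raise ValueError("each factor needs at least 2 levels")
    n = values.size
    df = {
        "factor_a": int(levels_a.size - 1),
        "factor_b": int(levels_b.size - 1),
        "interaction": int((levels_a.size - 1) * (levels_b.size - 1)),
    }
    cells = {(a, b) for a, b in zip(fa, fb)}
    if len(cells) < levels_a.size * levels_b.size:
        warnings.warn(
            "empty factor cells: SRH statistics computed from available cells",
            stacklevel=2,
        )

    ranks = stats.rankdata(values)
    ss_total = float(np.sum((ranks - ranks.mean()) ** 2))
    # classical tie-correction factor, reported for reference
    _, counts = np.unique(values, return_counts=True)
    tie_factor = 1.0 - float(np.sum(counts**3 - counts)) / max(n**3 - n, 1)

    if ss_total == 0.0:
        h = {k: 0.0 for k in df}
        p = {k: 1.0 for k in df}
        return SRHResult(h, df, p, n, 0.0, tie_factor)

    ms_total = ss_total / (n - 1)
    ss_a, ss_b, ss_int = _type2_ss_on_ranks(ranks, fa, fb)
    h = {
        "factor_a": ss_a / ms_total,
        "factor_b": ss_b / ms_total,
        "interaction": ss_int / ms_total,
    }
    p = {k: float(stats.chi2.sf(h[k], df[k])) for k in h}
    return SRHResult(h, df, p, n, ms_total, tie_factor)


def anova_tukey(
    values: Sequence[float],
    group: Sequence,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-way linear ANOVA with single-step Tukey post-hoc contrasts.

    Returns one row per unordered group pair with the mean difference and
    the studentized-range adjusted p-value, plus per-group flags in the
    ``flag`` columns of the attached ``.attrs``:
    '#' marks a group significantly higher than all others, '*' one
    significantly lower than all others (at ``alpha``, adjusted).
    The classic equal-variance ANOVA is used (no Welch correction).
    """
    values = np.asarray(values, dtype=float)
    group = np.asarray(group)
    labels, counts = np.unique(group, return_counts=True)
    if labels.size < 2:
        raise ValueError("need at least 2 groups")
    if counts.min() < 2:
        raise ValueError("need at least 2 observations per group")
    within_var = sum(
        float(np.var(values[group == g], ddof=1)) for g in labels
    )
    if within_var == 0.0:
        raise ValueError("zero within-group variance")

    f_stat, f_p = stats.f_oneway(*(values[group == g] for g in labels))
    res = pairwise_tukeyhsd(values, group, alpha=alpha)
    table = pd.DataFrame(
        data=res.summary().data[1:],
        columns=[str(c) for c in res.summary().data[0]],
    )
    table = table.rename(
        columns={"meandiff": "estimate", "p-adj": "p_adj"}
    )[["group1", "group2", "estimate", "p_adj", "reject"]]
    table["estimate"] = table["estimate"].astype(float)
    table["p_adj"] = np.asarray(res.pvalues, dtype=float)
    table["reject"] = np.asarray(res.reject, dtype=bool)

    means = {g: float(values[group == g].mean()) for g in labels}
    flags: Dict[str, str] = {}
    for g in labels:
        rows = table[(table["group1"] == g) | (table["group2"] == g)]
        all_sig = bool(rows["reject"].all()) and len(rows) == labels.size - 1
        others = [means[o] for o in labels if o != g]
        if all_sig and all(means[g] > m for m in others):
            flags[str(g)] = "#"
        elif all_sig and all(means[g] < m for m in others):
            flags[str(g)] = "*"
        else:
            flags[str(g)] = ""
    table.attrs["f_stat"] = float(f_stat)
    table.attrs["f_p"] = float(f_p)
    table.attrs["flags"] = flags
    return table


@dataclass
class EnrichmentResult:
    """One tested annotation term."""

    term: str
    candidate_size: int
    term_size: int
    overlap: int
    p: float
    p_adj: float
    rank: int


def hypergeom_enrich(
    candidates: Set[str],
    terms: Mapping[str, Set[str]],
    universe: Set[str],
    min_overlap: int = 2,
    top: int = 10,
) -> List[EnrichmentResult]:
    """Upper-tail hypergeometric term enrichment with BH adjustment.

    Term gene sets are intersected with the universe before testing; only
    terms overlapping the candidate set by at least ``min_overlap`` genes
    are tested and reported; the BH adjustment runs over the tested terms
    and the ``top`` best-ranked terms are returned.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    candidates = set(candidates)
    if not candidates <= universe:
        extra = sorted(candidates - universe)[:3]
        raise ValueError(f"candidates outside universe, e.g. {extra}")
    n_universe = len(universe)
    n_cand = len(candidates)
    rows = []
    for term, genes in terms.items():
        term_genes = set(genes) & universe
        k = len(term_genes & candidates)
        if k < min_overlap:
            continue
        p = float(stats.hypergeom.sf(k - 1, n_universe, len(term_genes), n_cand))
        rows.append((term, len(term_genes), k, p))
    if not rows:
        return []
    raw_p = [r[3] for r in rows]
    _, p_adj, _, _ = multipletests(raw_p, method="fdr_bh")
    order = np.argsort(raw_p, kind="stable")
    out = []
    for rank, i in enumerate(order[:top], start=1):
        term, term_size, k, p = rows[i]
        out.append(
            EnrichmentResult(
                term=term,
                candidate_size=n_cand,
                term_size=term_size,
                overlap=k,
                p=p,
                p_adj=float(p_adj[i]),
                rank=rank,
            )
        )
    return out
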