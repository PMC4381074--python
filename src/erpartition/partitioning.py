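"""Regulation calling in two RNA fractions and six-way group intersection.

The experimental design pools RNA over replicates, yielding one array per
fraction (total / ER) and condition (control / hypoxia).  With no replicates,
per-gene variance cannot be estimated directly; instead the spread of the
log-ratio M is modelled as a smooth function of the mean intensity A across
all genes (the familiar MA-plot heteroscedasticity), and each gene's M is
standardized by that intensity-dependent spread to give a z-score.  A gene is
called regulated when both the fold change and the z-score pass thresholds
(|FC| > 1.4 and |z| > 3 by default), and the calls from the two fractions are
intersected into six groups: up/down x {total-only, intersect, ER-only}.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "ExpressionTable",
    "LoessFit",
    "PartitionGroups",
    "FRACTIONS",
    "CONDITIONS",
    "filter_expressed",
    "compute_contrast",
    "fit_mean_sd_loess",
    "z_score",
    "call_regulation",
    "call_fraction",
    "intersect_groups",
]

FRACTIONS = ("total", "er")
CONDITIONS = ("control", "hypoxia")

GROUP_NAMES = (
    "up_total_only",
    "up_intersect",
    "up_er_only",
    "down_total_only",
    "down_intersect",
    "down_er_only",
)


@dataclass
class ExpressionTable:
    """Normalized log2 intensities: genes x labeled samples.

    ``data`` is indexed by gene id with one column per sample; ``samples``
    is indexed by sample id with columns ``fraction`` and ``condition``.
    """

    data: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup}")
        if list(self.data.columns) != list(self.samples.index):
            raise ValueError("sample columns and sample metadata disagree")
        if not np.all(np.isfinite(self.data.to_numpy(dtype=float))):
            raise ValueError("expression values must be finite")
        for frac in self.samples["fraction"].unique():
            conds = set(self.samples.loc[self.samples["fraction"] == frac, "condition"])
            if not {"control", "hypoxia"} <= conds:
                raise ValueError(f"fraction {frac!r} lacks a control or hypoxia sample")

    @property
    def gene_ids(self) -> List[str]:
        return list(self.data.index)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    def fractions(self) -> List[str]:
        return list(dict.fromkeys(self.samples["fraction"]))

    def sample_ids(self, fraction: str, condition: Optional[str] = None) -> List[str]:
        mask = self.samples["fraction"] == fraction
        if condition is not None:
            mask &= self.samples["condition"] == condition
        return list(self.samples.index[mask])


def filter_expressed(
    table: ExpressionTable, quantile: float = 0.5
) -> Tuple[ExpressionTable, List[str]]:
    """Drop weakly expressed genes.

    A gene's summary intensity is its mean over all samples; genes strictly
    below the given quantile of the summary distribution are removed.  The
    quantile uses linear interpolation; genes exactly at the threshold are
    retained.  Returns the filtered table and the list of removed
    (not-expressed) gene ids.
    """
    if table.n_genes == 0:
        raise ValueError("empty expression table")
    if not (0.0 <= quantile < 1.0):
        raise ValueError(f"quantile must lie in [0, 1): {quantile}")
    summary = table.data.mean(axis=1)
    threshold = float(np.quantile(summary.to_numpy(), quantile))
    keep = summary >= threshold
    removed = list(table.data.index[~keep])
    kept = ExpressionTable(table.data.loc[keep].copy(), table.samples)
    return kept, removed


def compute_contrast(table: ExpressionTable, fraction: str) -> pd.DataFrame:
    """Per-gene (A, M) for one fraction.

    M = mean log2(hypoxia) - mean log2(control) within the fraction; A is the
    midpoint of the two condition means.  Multiple samples per condition are
    averaged in log2 space first.
    """
    ctrl_cols = table.sample_ids(fraction, "control")
    hyp_cols = table.sample_ids(fraction, "hypoxia")
    if not ctrl_cols or not hyp_cols:
        raise ValueError(f"fraction {fraction!r} missing a condition")
    ctrl = table.data[ctrl_cols].mean(axis=1)
    hyp = table.data[hyp_cols].mean(axis=1)
    return pd.DataFrame({"A": (ctrl + hyp) / 2.0, "M": hyp - ctrl})


@dataclass
class LoessFit:
    """Intensity-dependent trend and spread of M, evaluated by interpolation.

    ``grid_a`` is the sorted distinct A values of the fit; outside the grid
    the nearest fitted value is used (no slope extrapolation), which avoids
    spurious z-scores in the sparse intensity tails.
    """

    grid_a: np.ndarray
    grid_trend: np.ndarray
    grid_spread: np.ndarray
    span: float
    robust_iters: int = 2

    def trend(self, a: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(a, dtype=float), self.grid_a, self.grid_trend)

    def spread(self, a: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(a, dtype=float), self.grid_a, self.grid_spread)


#: scales the median absolute residual to a standard deviation under normality
MAD_TO_SD = 1.4826
SPREAD_FLOOR = 1e-6
#: residuals are winsorized at this many initial-scale SDs before the
#: variance smooth; the consistency divisor E[min(Z, cap)^2] makes the
#: estimate unbiased for normal noise
WINSOR_CAP = 2.0
_WINSOR_CONSISTENCY = float(
    1.0
    - 2.0 * (WINSOR_CAP * stats.norm.pdf(WINSOR_CAP) + stats.norm.sf(WINSOR_CAP))
    + 2.0 * WINSOR_CAP**2 * stats.norm.sf(WINSOR_CAP)
)
#: fitted grids are clamped to the inner A-quantiles; outside, the nearest
#: fitted value is used (local-linear fits are noisy at the extreme edge)
_EDGE_QUANTILE = 0.025


def _clamp_grid(
    grid_x: np.ndarray, grid_y: np.ndarray, lo: float, hi: float
) -> Tuple[np.ndarray, np.ndarray]:
    keep = (grid_x >= lo) & (grid_x <= hi)
    if keep.sum() >= 2:
        return grid_x[keep], grid_y[keep]
    return grid_x, grid_y


def fit_mean_sd_loess(
    A: np.ndarray,
    M: np.ndarray,
    span: float = 0.3,
    robust_iters: int = 2,
    spread_span: Optional[float] = None,
) -> LoessFit:
    """Fit the mean--SD model of M as a function of A.

    trend(A) is a robust lowess fit of M on A.  spread(A) is a local SD
    estimated in two stages: an initial scale from the running median of
    |M - trend(A)| (window ``spread_span * n`` nearest neighbours in A,
    scaled by 1.4826), then a lowess smooth of the squared residuals
    winsorized at twice that initial scale, divided by the normal
    consistency constant.  The winsorization keeps the minority of
    genuinely regulated genes from inflating the spread (which would cost
    sensitivity) while retaining near-mean efficiency, and the local-linear
    smooth tracks intensity-dependent noise without the bias a flat window
    shows where the noise decays quickly.  ``spread_span`` defaults to a
    third of ``span``.
    """
    A = np.asarray(A, dtype=float)
    M = np.asarray(M, dtype=float)
    if A.shape != M.shape or A.ndim != 1:
        raise ValueError("A and M must be equal-length vectors")
    n = A.size
    if n < 50:
        raise ValueError(f"need at least 50 genes to fit the mean-SD model, got {n}")
    if spread_span is None:
        spread_span = span / 3.0
    window = max(10, min(n, int(round(spread_span * n))))
    if int(round(span * n)) > n:
        raise ValueError(f"span {span} needs more points than available ({n})")

    a_range = float(A.max() - A.min())
    delta = 0.005 * a_range if n > 2000 else 0.0
    lo, hi = np.quantile(A, [_EDGE_QUANTILE, 1.0 - _EDGE_QUANTILE])
    fitted = lowess(M, A, frac=span, it=robust_iters, delta=delta, return_sorted=True)
    grid_a, grid_trend = _clamp_grid(*_dedupe(fitted[:, 0], fitted[:, 1]), lo, hi)

    resid = np.abs(M - np.interp(A, grid_a, grid_trend))
    if float(resid.max(initial=0.0)) == 0.0:
        raise ValueError("degenerate spread: all residuals are zero")
    order = np.argsort(A, kind="stable")
    a_sorted = A[order]
    r_sorted = resid[order]
    rolled = (
        pd.Series(r_sorted)
        .rolling(window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    # full-size windows at the edges: the centered rolling window shrinks
    # there, which would make the initial scale noisy exactly where data
    # are sparse
    half = window // 2
    if n >= window and half > 0:
        rolled[:half] = np.median(r_sorted[:window])
        rolled[n - half :] = np.median(r_sorted[n - window :])
    sigma0 = np.maximum(MAD_TO_SD * rolled, SPREAD_FLOOR)

    capped_sq = np.minimum(r_sorted, WINSOR_CAP * sigma0) ** 2
    smoothed = lowess(
        capped_sq, a_sorted, frac=span, it=0, delta=delta, return_sorted=True
    )
    grid_sa, grid_var = _dedupe(smoothed[:, 0], smoothed[:, 1])
    grid_sa, grid_var = _clamp_grid(grid_sa, grid_var, lo, hi)
    grid_spread = np.sqrt(np.maximum(grid_var / _WINSOR_CONSISTENCY, SPREAD_FLOOR**2))
    grid_spread_on_trend_grid = np.maximum(
        np.interp(grid_a, grid_sa, grid_spread), SPREAD_FLOOR
    )
    return LoessFit(grid_a, grid_trend, grid_spread_on_trend_grid, span, robust_iters)


def _dedupe(x_sorted: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Average y over duplicate x so np.interp sees strictly increasing x."""
    df = pd.DataFrame({"x": x_sorted, "y": y}).groupby("x", sort=True)["y"].mean()
    return df.index.to_numpy(dtype=float), df.to_numpy(dtype=float)


def z_score(A: np.ndarray, M: np.ndarray, fit: LoessFit) -> np.ndarray:
    """Standardize M by the intensity-dependent trend and spread."""
    A = np.asarray(A, dtype=float)
    M = np.asarray(M, dtype=float)
    return (M - fit.trend(A)) / fit.spread(A)


def call_regulation(
    A: np.ndarray,
    M: np.ndarray,
    z: np.ndarray,
    fc_thresh: float = 1.4,
    z_thresh: float = 3.0,
) -> np.ndarray:
    """Vectorized status call: 'up', 'down' or 'unchanged'.

    up requires M >= log2(fc_thresh) and z >= z_thresh; down requires both
    negated thresholds; signs must agree.
    """
    if fc_thresh <= 1.0:
        raise ValueError(f"fc_thresh must exceed 1: {fc_thresh}")
    M = np.asarray(M, dtype=float)
    z = np.asarray(z, dtype=float)
    m_cut = np.log2(fc_thresh)
    status = np.full(M.shape, "unchanged", dtype=object)
    status[(M >= m_cut) & (z >= z_thresh)] = "up"
    status[(M <= -m_cut) & (z <= -z_thresh)] = "down"
    return status


def call_fraction(
    table: ExpressionTable,
    fraction: str,
    span: float = 0.3,
    fc_thresh: float = 1.4,
    z_thresh: float = 3.0,
    fit: Optional[LoessFit] = None,
) -> pd.DataFrame:
    """Full per-fraction calling: contrast, mean-SD fit, z, status.

    Returns a DataFrame indexed by gene id with columns
    (fraction, A, M, z, status).
    """
    am = compute_contrast(table, fraction)
    if fit is None:
        fit = fit_mean_sd_loess(am["A"].to_numpy(), am["M"].to_numpy(), span=span)
    z = z_score(am["A"].to_numpy(), am["M"].to_numpy(), fit)
    status = call_regulation(am["A"].to_numpy(), am["M"].to_numpy(), z, fc_thresh, z_thresh)
    out = am.copy()
    out.insert(0, "fraction", fraction)
    out["z"] = z
    out["status"] = status
    return out


@dataclass
class PartitionGroups:
    """Six-way partition of regulated genes plus the unchanged remainder."""

    up_total_only: FrozenSet[str] = frozenset()
    up_intersect: FrozenSet[str] = frozenset()
    up_er_only: FrozenSet[str] = frozenset()
    down_total_only: FrozenSet[str] = frozenset()
    down_intersect: FrozenSet[str] = frozenset()
    down_er_only: FrozenSet[str] = frozenset()
    unchanged: FrozenSet[str] = frozenset()
    not_expressed: FrozenSet[str] = frozenset()

    def group_of(self) -> Dict[str, List[str]]:
        """Gene id -> list of regulated group names containing it."""
        out: Dict[str, List[str]] = {}
        for name in GROUP_NAMES:
            for g in getattr(self, name):
                out.setdefault(g, []).append(name)
        return out

    def sizes(self) -> Dict[str, int]:
        names = GROUP_NAMES + ("unchanged", "not_expressed")
        return {name: len(getattr(self, name)) for name in names}


def intersect_groups(
    calls_total: pd.DataFrame,
    calls_er: pd.DataFrame,
    not_expressed: Sequence[str] = (),
) -> PartitionGroups:
    """Intersect per-fraction calls into the six partition groups.

    Both call tables must cover the same gene universe.  Genes filtered out
    as not-expressed in either fraction are excluded from all six regulated
    sets and reported separately.
    """
    if set(calls_total.index) != set(calls_er.index):
        raise ValueError("call sets cover different gene universes")
    ne = frozenset(not_expressed)
    up_t = set(calls_total.index[calls_total["status"] == "up"]) - ne
    up_e = set(calls_er.index[calls_er["status"] == "up"]) - ne
    dn_t = set(calls_total.index[calls_total["status"] == "down"]) - ne
    dn_e = set(calls_er.index[calls_er["status"] == "down"]) - ne
    regulated = up_t | up_e | dn_t | dn_e
    unchanged = frozenset(set(calls_total.index) - regulated - ne)
    return PartitionGroups(
        up_total_only=frozenset(up_t - up_e),
        up_intersect=frozenset(up_t & up_e),
        up_er_only=frozenset(up_e - up_t),
        down_total_only=frozenset(dn_t - dn_e),
        down_intersect=frozenset(dn_t & dn_e),
        down_er_only=frozenset(dn_e - dn_t),
        unchanged=unchanged,
        not_expressed=ne,
    )
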