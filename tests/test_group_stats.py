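"""Rank two-factor ANOVA, Tukey post-hoc contrasts, hypergeometric enrichment."""

import math

import numpy as np
import pytest
from scipy import stats

from erpartition.group_stats import anova_tukey, hypergeom_enrich, scheirer_ray_hare


def srh_oracle(values, fa, fb):
    """Explicit rank table and sum-of-squares decomposition by hand.

    Valid for balanced designs: effect SS from cell/margin means of the
    mid-ranks, H = SS / (SS_total/(N-1)).
    """
    values = np.asarray(values, dtype=float)
    fa = np.asarray(fa)
    fb = np.asarray(fb)
    r = stats.rankdata(values)
    n = len(r)
    gm = r.mean()
    ss_total = float(((r - gm) ** 2).sum())
    if ss_total == 0:
        return {"factor_a": 0.0, "factor_b": 0.0, "interaction": 0.0}
    ms_total = ss_total / (n - 1)
    ss_a = sum(
        (r[fa == a].mean() - gm) ** 2 * (fa == a).sum() for a in np.unique(fa)
    )
    ss_b = sum(
        (r[fb == b].mean() - gm) ** 2 * (fb == b).sum() for b in np.unique(fb)
    )
    ss_cells = sum(
        (r[(fa == a) & (fb == b)].mean() - gm) ** 2 * ((fa == a) & (fb == b)).sum()
        for a in np.unique(fa)
        for b in np.unique(fb)
    )
    return {
        "factor_a": ss_a / ms_total,
        "factor_b": ss_b / ms_total,
        "interaction": (ss_cells - ss_a - ss_b) / ms_total,
    }


class TestScheirerRayHare:
    def test_identical_values_give_zero_h_unit_p(self):
        fa = ["a"] * 4 + ["b"] * 4
        fb = ["x", "x", "y", "y"] * 2
        res = scheirer_ray_hare([5.0] * 8, fa, fb)
        assert all(h == 0.0 for h in res.h.values())
        assert all(p == 1.0 for p in res.p.values())

    def test_matches_hand_oracle_on_2x2(self):
        vals = [1, 2, 3, 4, 5, 6, 7, 8]
        fa = ["A1"] * 4 + ["A2"] * 4
        fb = ["B1", "B1", "B2", "B2"] * 2
        res = scheirer_ray_hare(vals, fa, fb)
        oracle = srh_oracle(vals, fa, fb)
        for k in oracle:
            assert res.h[k] == pytest.approx(oracle[k], abs=1e-12)

    def test_matches_oracle_exhaustively_small_balanced(self):
        # every assignment of ranks 1..8 to a balanced 2x2 with 2 per cell
        fa = ["a"] * 4 + ["b"] * 4
        fb = ["x", "x", "y", "y"] * 2
        rng = np.random.default_rng(0)
        for _ in range(200):
            vals = rng.permutation(8) + rng.integers(0, 2, 8) * 0  # ties excluded
            res = scheirer_ray_hare(vals, fa, fb)
            oracle = srh_oracle(vals, fa, fb)
            for k in oracle:
                assert res.h[k] == pytest.approx(oracle[k], abs=1e-12)

    def test_matches_oracle_with_ties_3x2(self):
        fa = np.repeat(["a", "b", "c"], 4)
        fb = np.tile(["x", "x", "y", "y"], 3)
        rng = np.random.default_rng(1)
        for _ in range(100):
            vals = rng.integers(0, 5, 12).astype(float)  # heavy ties
            if len(set(vals)) == 1:
                continue
            res = scheirer_ray_hare(vals, fa, fb)
            oracle = srh_oracle(vals, fa, fb)
            for k in oracle:
                assert res.h[k] == pytest.approx(oracle[k], abs=1e-12)

    def test_rank_invariance_within_cells(self):
        fa = np.repeat(["a", "b"], 6)
        fb = np.tile(np.repeat(["x", "y"], 3), 2)
        vals = np.array([3.0, 1.0, 2.0, 9.0, 7.0, 8.0, 4.0, 6.0, 5.0, 12.0, 10.0, 11.0])
        res1 = scheirer_ray_hare(vals, fa, fb)
        # permute values within every (A,B) cell
        rng = np.random.default_rng(2)
        vals2 = vals.copy()
        for a in "ab":
            for b in "xy":
                m = (fa == a) & (fb == b)
                vals2[m] = rng.permutation(vals2[m])
        res2 = scheirer_ray_hare(vals2, fa, fb)
        for k in res1.h:
            assert res1.h[k] == pytest.approx(res2.h[k], abs=1e-12)

    def test_single_level_factor_rejected(self):
        with pytest.raises(ValueError, match="2 levels"):
            scheirer_ray_hare([1, 2, 3, 4], ["a"] * 4, ["x", "x", "y", "y"])

    def test_empty_cell_warns_but_computes(self):
        fa = ["a", "a", "b", "b", "a", "a"]
        fb = ["x", "x", "x", "x", "y", "y"]  # cell (b, y) empty
        with pytest.warns(UserWarning, match="empty factor cells"):
            res = scheirer_ray_hare([1, 2, 3, 4, 5, 6], fa, fb)
        assert all(np.isfinite(h) for h in res.h.values())


class TestAnovaTukey:
    def test_label_symmetry(self):
        rng = np.random.default_rng(3)
        vals = np.concatenate([rng.normal(0, 1, 30), rng.normal(1, 1, 30)])
        grp = np.array(["a"] * 30 + ["b"] * 30)
        t1 = anova_tukey(vals, grp)
        swapped = np.where(grp == "a", "b", "a")
        t2 = anova_tukey(vals, swapped)
        assert t1["p_adj"].iloc[0] == pytest.approx(t2["p_adj"].iloc[0])
        assert t1["estimate"].iloc[0] == pytest.approx(-t2["estimate"].iloc[0])

    def test_shifted_group_flagged_higher(self):
        rng = np.random.default_rng(4)
        vals = np.concatenate(
            [rng.normal(0, 1, 50), rng.normal(0, 1, 50), rng.normal(2.0, 1, 50)]
        )
        grp = np.repeat(["a", "b", "c"], 50)
        tab = anova_tukey(vals, grp)
        assert tab.attrs["flags"]["c"] == "#"
        assert tab.attrs["flags"]["a"] == ""

    def test_lowered_group_flagged_star(self):
        rng = np.random.default_rng(5)
        vals = np.concatenate(
            [rng.normal(0, 1, 50), rng.normal(-2.0, 1, 50), rng.normal(0, 1, 50)]
        )
        grp = np.repeat(["a", "b", "c"], 50)
        assert anova_tukey(vals, grp).attrs["flags"]["b"] == "*"

    def test_null_adjusted_p_roughly_uniform(self):
        rng = np.random.default_rng(6)
        hits = 0
        n_sim = 400
        for _ in range(n_sim):
            vals = rng.normal(size=200)
            grp = np.repeat(["a", "b"], 100)
            tab = anova_tukey(vals, grp)
            hits += tab["p_adj"].iloc[0] < 0.05
        assert 0.02 <= hits / n_sim <= 0.08

    def test_power_for_one_sd_shift(self):
        rng = np.random.default_rng(7)
        detected = 0
        n_sim = 100
        for _ in range(n_sim):
            vals = np.concatenate([rng.normal(0, 1, 50), rng.normal(1.0, 1, 50)])
            grp = np.repeat(["a", "b"], 50)
            detected += anova_tukey(vals, grp)["p_adj"].iloc[0] < 0.01
        assert detected / n_sim >= 0.95

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            anova_tukey([1.0, 1.0, 2.0, 2.0], ["a", "a", "b", "b"])


def hypergeom_tail_oracle(k, M, n, N):
    """Brute-force upper tail by direct summation of the pmf."""
    total = 0.0
    for i in range(k, min(n, N) + 1):
        total += (
            math.comb(n, i) * math.comb(M - n, N - i) / math.comb(M, N)
        )
    return total


class TestHypergeomEnrich:
    def test_matches_direct_summation(self):
        universe = {f"g{i}" for i in range(100)}
        term = {f"g{i}" for i in range(10)}
        candidates = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(50, 55)}
        res = hypergeom_enrich(candidates, {"T": term}, universe, min_overlap=2)
        assert len(res) == 1
        assert res[0].overlap == 5
        assert res[0].p == pytest.approx(hypergeom_tail_oracle(5, 100, 10, 10), rel=1e-12)

    def test_minimum_overlap_excludes_terms(self):
        universe = {f"g{i}" for i in range(50)}
        res = hypergeom_enrich(
            {"g0", "g20", "g21"}, {"T": {"g0", "g1"}}, universe, min_overlap=2
        )
        assert res == []

    def test_term_equal_to_universe_gives_p_one(self):
        universe = {f"g{i}" for i in range(30)}
        res = hypergeom_enrich(
            {"g0", "g1", "g2"}, {"ALL": set(universe)}, universe
        )
        assert res[0].p == pytest.approx(1.0)

    def test_bh_adjustment_is_monotone(self):
        rng = np.random.default_rng(8)
        universe = {f"g{i}" for i in range(200)}
        candidates = set(rng.choice(sorted(universe), 40, replace=False))
        terms = {
            f"T{j}": set(rng.choice(sorted(universe), 25, replace=False))
            for j in range(20)
        }
        res = hypergeom_enrich(candidates, terms, universe, top=20)
        raw = [r.p for r in res]
        adj = [r.p_adj for r in res]
        assert raw == sorted(raw)
        assert adj == sorted(adj)
        assert all(a >= p for p, a in zip(raw, adj))

    def test_candidates_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside universe"):
            hypergeom_enrich({"x"}, {}, {"a", "b"})

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="empty universe"):
            hypergeom_enrich(set(), {}, set())
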