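"""Regulation calling: filter, contrast, mean-SD model, z-score, groups."""

import numpy as np
import pandas as pd
import pytest

from erpartition.partitioning import (
    ExpressionTable,
    call_fraction,
    call_regulation,
    compute_contrast,
    filter_expressed,
    fit_mean_sd_loess,
    intersect_groups,
    z_score,
    LoessFit,
)


class TestFilterExpressed:
    def test_median_threshold_drops_lower_half(self, toy_table):
        # summaries are (2.125, 4.05, 6.375, 8.3); median is between g2 and g3
        kept, removed = filter_expressed(toy_table, 0.5)
        assert set(kept.gene_ids) == {"g3", "g4"}
        assert set(removed) == {"g1", "g2"}

    def test_quantile_zero_keeps_everything(self, toy_table):
        kept, removed = filter_expressed(toy_table, 0.0)
        assert kept.n_genes == 4 and removed == []

    def test_ties_at_threshold_are_retained(self):
        data = pd.DataFrame(
            {c: [5.0, 5.0, 5.0] for c in ["tc", "th", "ec", "eh"]},
            index=pd.Index(["a", "b", "c"], name="gene_id"),
        )
        samples = pd.DataFrame(
            {"fraction": ["total", "total", "er", "er"],
             "condition": ["control", "hypoxia", "control", "hypoxia"]},
            index=pd.Index(data.columns, name="sample_id"),
        )
        kept, removed = filter_expressed(ExpressionTable(data, samples), 0.5)
        assert kept.n_genes == 3 and removed == []

    @pytest.mark.parametrize("q", [-0.1, 1.0, 1.5])
    def test_invalid_quantile_rejected(self, toy_table, q):
        with pytest.raises(ValueError):
            filter_expressed(toy_table, q)


class TestComputeContrast:
    def test_a_is_midpoint_and_m_is_difference(self, toy_table):
        am = compute_contrast(toy_table, "total")
        assert am.loc["g3", "A"] == pytest.approx(6.5)
        assert am.loc["g3", "M"] == pytest.approx(1.0)
        assert am.loc["g2", "M"] == pytest.approx(0.0)

    def test_fold_change_boundary(self):
        # M = 0.485 corresponds to a linear FC of 2^0.485 ~ 1.40
        assert 2 ** 0.485 == pytest.approx(1.4, abs=5e-4)

    def test_missing_fraction_raises(self, toy_table):
        with pytest.raises(ValueError):
            compute_contrast(toy_table, "nuclear")


class TestMeanSdLoess:
    def test_recovers_flat_trend_and_constant_spread(self):
        rng = np.random.default_rng(0)
        A = rng.uniform(2, 12, 5000)
        M = rng.normal(0.0, 0.2, 5000)
        fit = fit_mean_sd_loess(A, M)
        grid = np.linspace(A.min(), A.max(), 50)
        assert np.all(np.abs(fit.trend(grid)) < 0.05)
        assert np.all(np.abs(fit.spread(grid) / 0.2 - 1.0) <= 0.10)

    def test_degenerate_spread_raises(self):
        A = np.linspace(0, 10, 100)
        with pytest.raises(ValueError, match="degenerate"):
            fit_mean_sd_loess(A, np.zeros(100))

    def test_rising_spread_is_tracked_monotonically(self):
        rng = np.random.default_rng(1)
        A = rng.uniform(2, 12, 5000)
        sd_true = 0.1 + 0.3 * (A - 2) / 10
        fit = fit_mean_sd_loess(A, rng.normal(0, 1, 5000) * sd_true)
        grid = np.linspace(3, 11, 20)
        sp = fit.spread(grid)
        # monotone within fit tolerance: no decreasing step bigger than noise
        assert np.all(np.diff(sp) > -0.02)
        assert sp[-1] > sp[0] + 0.15

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 50"):
            fit_mean_sd_loess(np.arange(10.0), np.arange(10.0))


class TestZScore:
    def test_definition(self):
        fit = LoessFit(
            grid_a=np.array([0.0, 10.0]),
            grid_trend=np.array([0.1, 0.1]),
            grid_spread=np.array([0.2, 0.2]),
            span=0.3,
        )
        assert z_score(5.0, 0.1, fit) == pytest.approx(0.0)
        assert z_score(5.0, 0.1 + 3 * 0.2, fit) == pytest.approx(3.0)

    def test_reduces_to_m_over_sd_for_trivial_fit(self):
        fit = LoessFit(
            grid_a=np.array([0.0, 10.0]),
            grid_trend=np.zeros(2),
            grid_spread=np.full(2, 0.25),
            span=0.3,
        )
        rng = np.random.default_rng(2)
        A = rng.uniform(0, 10, 100)
        M = rng.normal(0, 1, 100)
        assert np.allclose(z_score(A, M, fit), M / 0.25, atol=1e-12)


class TestCallRegulation:
    @pytest.mark.parametrize(
        "m,z,expected",
        [
            (1.0, 4.0, "up"),
            (0.3, 5.0, "unchanged"),  # FC 1.23 < 1.4
            (-1.0, -4.0, "down"),
            (1.0, 2.0, "unchanged"),  # z below threshold
            (-1.0, 4.0, "unchanged"),  # signs disagree
        ],
    )
    def test_threshold_rule(self, m, z, expected):
        assert call_regulation(np.r_[8.0], np.r_[m], np.r_[z])[0] == expected

    def test_fc_threshold_must_exceed_one(self):
        with pytest.raises(ValueError):
            call_regulation(np.r_[8.0], np.r_[1.0], np.r_[4.0], fc_thresh=0.9)

    def test_calls_invariant_under_gene_reordering(self):
        rng = np.random.default_rng(3)
        n = 500
        data = pd.DataFrame(
            {
                "tc": rng.normal(8, 2, n),
                "th": rng.normal(8, 2, n),
                "ec": rng.normal(8, 2, n),
                "eh": rng.normal(8, 2, n),
            },
            index=pd.Index([f"g{i}" for i in range(n)], name="gene_id"),
        )
        samples = pd.DataFrame(
            {"fraction": ["total", "total", "er", "er"],
             "condition": ["control", "hypoxia", "control", "hypoxia"]},
            index=pd.Index(data.columns, name="sample_id"),
        )
        table = ExpressionTable(data, samples)
        calls1 = call_fraction(table, "total")
        perm = rng.permutation(n)
        table2 = ExpressionTable(data.iloc[perm], samples)
        calls2 = call_fraction(table2, "total")
        pd.testing.assert_frame_equal(calls1.sort_index(), calls2.sort_index())


class TestIntersectGroups:
    @staticmethod
    def _calls(universe, up=(), down=()):
        status = ["up" if g in up else "down" if g in down else "unchanged" for g in universe]
        return pd.DataFrame({"status": status}, index=list(universe))

    def test_three_way_up_split(self):
        universe = list("abcdX")
        groups = intersect_groups(
            self._calls(universe, up="abc"), self._calls(universe, up="bcd")
        )
        assert groups.up_total_only == {"a"}
        assert groups.up_intersect == {"b", "c"}
        assert groups.up_er_only == {"d"}
        assert groups.unchanged == {"X"}

    def test_empty_calls_give_empty_groups(self):
        universe = list("abc")
        groups = intersect_groups(self._calls(universe), self._calls(universe))
        assert all(
            not getattr(groups, n)
            for n in ("up_total_only", "up_intersect", "up_er_only",
                      "down_total_only", "down_intersect", "down_er_only")
        )

    def test_union_identity_up_and_down(self):
        rng = np.random.default_rng(4)
        universe = [f"g{i}" for i in range(200)]
        up_t = set(rng.choice(universe, 30, replace=False))
        up_e = set(rng.choice(universe, 25, replace=False))
        dn_t = set(rng.choice(sorted(set(universe) - up_t), 20, replace=False))
        dn_e = set(rng.choice(sorted(set(universe) - up_e), 15, replace=False))
        groups = intersect_groups(
            self._calls(universe, up=up_t, down=dn_t),
            self._calls(universe, up=up_e, down=dn_e),
        )
        assert groups.up_total_only | groups.up_intersect == up_t
        assert groups.up_intersect | groups.up_er_only == up_e
        assert groups.down_total_only | groups.down_intersect == dn_t
        assert (
            len(groups.up_total_only) + len(groups.up_intersect) + len(groups.up_er_only)
            == len(up_t | up_e)
        )

    def test_not_expressed_excluded_from_all_sets(self):
        universe = list("abcd")
        groups = intersect_groups(
            self._calls(universe, up="ab"),
            self._calls(universe, up="ab"),
            not_expressed=["a"],
        )
        assert "a" not in groups.up_intersect
        assert "a" in groups.not_expressed

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError):
            intersect_groups(self._calls("abc"), self._calls("abd"))
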