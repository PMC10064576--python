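"""Artifact and intercellular-space discrimination."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rootphen.config import PipelineConfig
from rootphen.filtering import (
    diameter_outlier_pass,
    gated_neighbors,
    iterate_filtering,
    kmeans_sized,
    majority_decision,
    majority_rule_pass,
    quantile_fences,
    small_object_threshold,
)
from rootphen.schema import CLUSTER_FEATURES


def brute_force_quartiles(values):
    """Type-7 quantiles by direct sorting + linear interpolation."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    out = []
    for q in (0.25, 0.5, 0.75):
        h = (n - 1) * q
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        out.append(v[lo] + (h - lo) * (v[hi] - v[lo]))
    return out[0], out[1], out[2], out[2] - out[0]


def make_table(diam_um, x=None, y=None):
    """Object table with consistent morphological columns derived from diameter."""
    diam_um = np.asarray(diam_um, dtype=float)
    n = len(diam_um)
    rng = np.random.default_rng(0)
    if x is None:
        x = np.arange(n) * 30.0
    if y is None:
        y = np.zeros(n)
    r = diam_um / 2
    t = pd.DataFrame(
        {
            "order": np.arange(1, n + 1),
            "s.area": np.pi * r**2,
            "s.perimeter": 2 * np.pi * r,
            "s.radius.mean": r,
            "s.radius.sd": 0.05 * r,
            "s.radius.max": 1.1 * r,
            "s.radius.min": 0.9 * r,
            "m.cx": np.asarray(x, float),
            "m.cy": np.asarray(y, float),
            "m.majoraxis": 2.2 * r,
            "m.eccentricity": np.full(n, 0.3),
            "m.theta": np.zeros(n),
            "Meandiameterµm": diam_um,
            "Diameter_log": np.log10(diam_um),
            "ring_zone": np.ones(n, dtype=int),
        }
    )
    return t


class TestQuantiles:
    @given(
        st.lists(st.floats(-1e6, 1e6, allow_nan=False, width=32), min_size=2, max_size=40)
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_fences_match_bruteforce(self, values):
        q1, q2, q3, iqr = quantile_fences(np.array(values))
        b1, b2, b3, biqr = brute_force_quartiles(values)
        assert q1 == pytest.approx(b1, abs=1e-9)
        assert q2 == pytest.approx(b2, abs=1e-9)
        assert q3 == pytest.approx(b3, abs=1e-9)
        assert iqr == pytest.approx(biqr, abs=1e-9)


class TestSmallObjectThreshold:
    def test_bimodal_valley_found(self, cfg):
        rng = np.random.default_rng(7)
        sample = np.concatenate(
            [rng.normal(0.3, 0.08, 3000), rng.normal(1.3, 0.12, 2000)]
        )
        # exclude values that would fall under the 0.8 cap discussion
        thr = small_object_threshold(sample, cfg)
        # oracle: exhaustive scan of 0.05-wide bins between the two modes
        counts, edges = np.histogram(sample, bins=np.arange(sample.min(), sample.max() + 0.05, 0.05))
        centres = 0.5 * (edges[:-1] + edges[1:])
        lo = np.argmin(np.abs(centres - 0.3))
        hi = np.argmin(np.abs(centres - 1.3))
        valley_oracle = centres[lo + 1 + np.argmin(counts[lo + 1 : hi])]
        assert thr == pytest.approx(min(valley_oracle, 0.8), abs=0.051)

    def test_unimodal_falls_back(self, cfg):
        rng = np.random.default_rng(1)
        assert small_object_threshold(rng.normal(1.2, 0.1, 2000), cfg) == 0.5

    def test_valley_above_cap_clipped_to_cap(self, cfg):
        rng = np.random.default_rng(2)
        sample = np.concatenate([rng.normal(0.7, 0.08, 2000), rng.normal(1.5, 0.08, 2000)])
        assert small_object_threshold(sample, cfg) == 0.8

    def test_single_value(self, cfg):
        assert small_object_threshold(np.array([1.0]), cfg) == 0.5


class TestGatedNeighbors:
    def test_symmetric_ring_keeps_all_six(self, cfg):
        ang = np.linspace(0, 2 * np.pi, 7)[:-1]
        x = np.concatenate([[0.0], 10 * np.cos(ang)])
        y = np.concatenate([[0.0], 10 * np.sin(ang)])
        t = make_table(np.full(7, 20.0), x=x, y=y)
        st_ = gated_neighbors(t, cfg)[0]  # focal = centre (first row)
        assert len(st_.neighbor_ids) == 6
        assert st_.dist_iqr == pytest.approx(0.0, abs=1e-9)

    def test_far_neighbor_gated_out(self, cfg):
        # five near neighbours and one at 100x the distance
        x = np.array([0.0, 10, -10, 0, 0, 7, 1000.0])
        y = np.array([0.0, 0, 0, 10, -10, 7, 0.0])
        t = make_table(np.full(7, 20.0), x=x, y=y)
        st_ = gated_neighbors(t, cfg)[0]
        assert 7 not in st_.neighbor_ids  # the far object (order 7)
        assert len(st_.neighbor_ids) == 5

    def test_two_cells_have_one_neighbor_each(self, cfg):
        t = make_table([20.0, 20.0], x=[0, 10], y=[0, 0])
        stats = gated_neighbors(t, cfg)
        assert [len(s.neighbor_ids) for s in stats] == [1, 1]

    def test_single_cell_yields_empty(self, cfg):
        assert gated_neighbors(make_table([20.0]), cfg) == []


class TestDiameterOutlier:
    def _run(self, diams, cfg):
        n = len(diams)
        ang = np.linspace(0, 2 * np.pi, n)[:-1]
        x = np.concatenate([[0.0], 20 * np.cos(ang)])
        y = np.concatenate([[0.0], 20 * np.sin(ang)])
        t = make_table(diams, x=x[:n], y=y[:n])
        nbrs = gated_neighbors(t, cfg)
        return diameter_outlier_pass(t, nbrs)

    def test_small_focal_among_large_removed(self, cfg):
        # focal log-diameter 0.5 vs six neighbours at 1.5: IQR 0 fence
        kept, removed = self._run(10 ** np.array([0.5] + [1.5] * 6), cfg)
        assert 1 in removed

    def test_all_equal_none_removed(self, cfg):
        kept, removed = self._run(np.full(7, 20.0), cfg)
        assert removed == []

    def test_gentle_gradient_kept(self, cfg):
        kept, removed = self._run(10 ** np.array([1.0, 1.1, 1.2, 1.3, 1.4, 1.5]), cfg)
        assert 1 not in removed

    def test_quantile_columns_recorded(self, cfg):
        kept, _ = self._run(np.full(7, 20.0), cfg)
        assert {"Q1", "Q3", "IQR"} <= set(kept.columns)
        assert kept["IQR"].iloc[0] == pytest.approx(0.0, abs=1e-12)


class TestKmeansSized:
    def test_two_groups_relabelled_by_size(self, cfg):
        t = make_table(np.r_[np.full(20, 10.0), np.full(20, 40.0)])
        labels = kmeans_sized(t, 2, cfg)
        assert set(labels[:20]) == {1} and set(labels[20:]) == {2}

    def test_three_separated_blobs_recovered(self, cfg):
        rng = np.random.default_rng(4)
        d = np.concatenate(
            [rng.normal(8, 0.05, 30), rng.normal(25, 0.05, 30), rng.normal(60, 0.05, 30)]
        )
        labels = kmeans_sized(make_table(d), 3, cfg)
        assert set(labels[:30]) == {1}
        assert set(labels[30:60]) == {2}
        assert set(labels[60:]) == {3}

    def test_duplicate_rows_do_not_crash(self, cfg):
        t = make_table(np.full(12, 15.0))
        labels = kmeans_sized(t, 3, cfg)
        assert len(labels) == 12

    def test_too_few_rows_raise(self, cfg):
        with pytest.raises(ValueError, match="at least"):
            kmeans_sized(make_table([10.0, 20.0]), 3, cfg)

    def test_position_columns_ignored(self, cfg):
        t1 = make_table(np.r_[np.full(10, 10.0), np.full(10, 40.0)])
        t2 = t1.copy()
        t2["m.cx"] = np.arange(20) * 1e6  # wildly different positions
        assert np.array_equal(kmeans_sized(t1, 2, cfg), kmeans_sized(t2, 2, cfg))


class TestMajorityRule:
    def test_three_threes_one_two_is_intercellular(self):
        d = majority_decision(0, [3, 3, 3, 2])
        assert d.SUM == 11 and d.MAX == 12 and d.MEAN == pytest.approx(2.75)
        assert d.is_intercellular  # 11 >= 12 - 2.75

    def test_all_threes_is_intercellular(self):
        assert majority_decision(0, [3, 3, 3, 3, 3]).is_intercellular

    def test_all_ones_kept(self):
        d = majority_decision(0, [1, 1, 1, 1])
        assert d.SUM == 4 and d.MAX == 12 and not d.is_intercellular

    def test_pass_removes_only_cluster_one_focals(self, cfg):
        # one small focal amid six large cells, plus the large cells themselves
        ang = np.linspace(0, 2 * np.pi, 7)[:-1]
        x = np.concatenate([[0.0], 30 * np.cos(ang)])
        y = np.concatenate([[0.0], 30 * np.sin(ang)])
        t = make_table(np.r_[8.0, np.full(6, 40.0)], x=x, y=y)
        nbrs = gated_neighbors(t, cfg)
        labels3 = np.r_[1, np.full(6, 3)].astype(int)
        kept, removed = majority_rule_pass(t, nbrs, labels3)
        assert removed == [1]
        assert set(kept["order"]) == {2, 3, 4, 5, 6, 7}

    def test_focal_without_neighbors_kept(self, cfg):
        t = make_table([8.0, 40.0, 40.0, 40.0], x=[0, 50, 100, 150])
        nbrs = gated_neighbors(t, cfg)
        # fabricate: give the focal an empty gated set
        nbrs[0].neighbor_ids = np.array([], dtype=int)
        kept, removed = majority_rule_pass(t, nbrs, np.array([1, 3, 3, 3]))
        assert 1 not in removed


class TestIterateFiltering:
    def test_clean_table_is_fixed_point(self, cfg):
        rng = np.random.default_rng(9)
        t = make_table(
            rng.normal(30, 1.0, 40),
            x=np.tile(np.arange(8) * 40.0, 5),
            y=np.repeat(np.arange(5) * 40.0, 8),
        )
        kept, flog = iterate_filtering(t, cfg)
        assert len(kept) == 40
        assert flog.n_removed == 0

    def test_chained_voids_removed_over_multiple_passes(self, cfg):
        # void A shields void B in pass one; removing A exposes B
        big = 10 ** np.array([1.58, 1.60, 1.62, 1.59, 1.61, 1.63, 1.60, 1.62])
        diams = np.r_[10.0, 10**1.35, big]  # A, B, 8 large cells
        x = np.r_[0.0, 20.0, 60, -60, 0, 0, 60, -60, 60, -60]
        y = np.r_[0.0, 0.0, 0, 0, 60, -60, 60, 60, -60, -60]
        t = make_table(diams, x=x, y=y)
        kept, flog = iterate_filtering(t, cfg)
        assert 1 not in set(kept["order"]) and 2 not in set(kept["order"])
        log = flog.to_frame()
        pass_a = log.loc[log["order"] == 1, "pass"].min()
        pass_b = log.loc[log["order"] == 2, "pass"].min()
        assert pass_b > pass_a  # B only falls after A is gone
        assert log["pass"].max() >= 2

    def test_kept_set_shrinks_weakly(self, synth):
        log = synth["res"].filter_log.to_frame()
        if len(log):
            per_pass = log.groupby("pass").size()
            assert (per_pass.index == np.arange(1, len(per_pass) + 1)).all()

    def test_intercell_area_accounting(self, cfg):
        big = np.full(8, 40.0)
        diams = np.r_[8.0, big]
        ang = np.linspace(0, 2 * np.pi, 9)[:-1]
        t = make_table(diams, x=np.r_[0, 40 * np.cos(ang)], y=np.r_[0, 40 * np.sin(ang)])
        kept, flog = iterate_filtering(t, cfg)
        assert 1 not in set(kept["order"])
        area_a = float(t.loc[t["order"] == 1, "s.area"].iloc[0])
        assert flog.intercell_area == pytest.approx(area_a)
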