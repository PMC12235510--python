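"""Drift correction, DBSCAN parameter rules and oracle, filtering, on-rates."""

import numpy as np
import pandas as pd
import pytest

from fluoropaint.cluster import (dbscan_cluster, drift_correct,
                                 estimate_on_rate, filter_clusters)
from fluoropaint.io import LocalizationTable
from fluoropaint.simdata import PaintSimConfig, make_rod_segments, simulate_paint


def table_from_nm(xy_nm, frames=None, pixel_nm=117.0, n_frames=1000):
    xy = np.asarray(xy_nm, dtype=float)
    if frames is None:
        frames = np.zeros(len(xy), dtype=int)
    df = pd.DataFrame({"frame": frames, "x": xy[:, 0] / pixel_nm,
                       "y": xy[:, 1] / pixel_nm, "photons": 1000.0})
    return LocalizationTable(df, pixel_nm, n_frames)


def brute_force_dbscan(xy, eps, min_samples):
    """O(n^2) DBSCAN reference (independent of sklearn)."""
    n = len(xy)
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    neigh = d2 <= eps**2
    core = neigh.sum(axis=1) >= min_samples
    labels = -np.ones(n, dtype=int)
    cid = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        labels[i] = cid
        stack = [i]
        while stack:
            j = stack.pop()
            for k in np.nonzero(neigh[j])[0]:
                if labels[k] == -1:
                    labels[k] = cid
                    if core[k]:
                        stack.append(k)
        cid += 1
    return labels, core


def dense_bead_stream(seed=0, drift=(0.0, 0.0)):
    """Compact, bright segments: a good fixture for drift registration."""
    cfg = PaintSimConfig(k_on_per_segment=20.0, mean_dwell_s=0.04,
                         frame_time_s=0.02, n_frames=2000,
                         loc_precision_nm=6.0, drift_nm_per_frame=drift,
                         fov_px=48, seed=seed)
    segs = make_rod_segments(20, cfg.fov_nm, length_range_nm=(8.0, 12.0),
                             radius_nm=2.0, rng=np.random.default_rng(3))
    locs, truth = simulate_paint(segs, cfg)
    return cfg, locs, truth


class TestDriftCorrect:
    def test_zero_drift_is_near_identity(self):
        _, locs, _ = dense_bead_stream(seed=5)
        corrected, _ = drift_correct(locs)
        dx = (corrected.df["x"] - locs.df["x"]).to_numpy() * locs.pixel_nm
        dy = (corrected.df["y"] - locs.df["y"]).to_numpy() * locs.pixel_nm
        rms = np.sqrt(np.mean(dx**2 + dy**2))
        assert rms < 1.0

    def test_linear_drift_removed_below_precision(self):
        cfg, locs, truth = dense_bead_stream(seed=6, drift=(0.3, -0.2))
        corrected, trace = drift_correct(locs)
        est = np.column_stack([trace.drift_x_nm, trace.drift_y_nm])
        resid = est - truth.drift_nm
        resid -= resid.mean(axis=0)  # common offset is unobservable
        rms = np.sqrt((resid**2).sum(axis=1).mean())
        assert rms < cfg.loc_precision_nm

    def test_default_window_matches_acquisition_rule(self):
        _, locs, _ = dense_bead_stream(seed=7)
        _, trace = drift_correct(locs)  # defaults: 100 frames, 60 nm cap
        assert len(trace) == locs.n_frames
        import inspect

        sig = inspect.signature(drift_correct)
        assert sig.parameters["segment_frames"].default == 100
        assert sig.parameters["max_drift_nm"].default == 60.0

    def test_too_few_windows_rejected(self):
        xy = np.random.default_rng(0).uniform(0, 1000, (50, 2))
        locs = table_from_nm(xy, n_frames=50)
        with pytest.raises(ValueError):
            drift_correct(locs, segment_frames=100)


class TestDBSCAN:
    def test_parameter_rules(self):
        xy = np.random.default_rng(0).uniform(0, 5000, (300, 2))
        locs = table_from_nm(xy, pixel_nm=117.0, n_frames=7500)
        cs = dbscan_cluster(locs)
        assert cs.eps_nm == pytest.approx(58.5)
        assert cs.min_samples == 75

    def test_min_samples_below_one_errors(self):
        locs = table_from_nm(np.zeros((5, 2)), n_frames=10)
        with pytest.raises(ValueError, match="override"):
            dbscan_cluster(locs)

    def test_small_cluster_all_core(self):
        xy = np.array([[0, 0], [10, 0], [0, 10], [10, 10], [5, 5]], float)
        locs = table_from_nm(xy, n_frames=1000)
        cs = dbscan_cluster(locs, eps_override=20.0, min_samples_override=3)
        assert len(cs.cluster_stats) == 1
        assert cs.cluster_stats.iloc[0]["n_core"] == 5

    def test_isolated_point_is_noise(self):
        xy = np.vstack([np.zeros((5, 2)) + [[0, 0], [5, 0], [0, 5], [5, 5], [2, 2]],
                        [[500.0, 500.0]]])
        locs = table_from_nm(xy, n_frames=1000)
        cs = dbscan_cluster(locs, eps_override=20.0, min_samples_override=3)
        assert cs.labels[-1] == -1

    @pytest.mark.parametrize("seed", range(50))
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(20, 200)
        # mixture of clumps and scattered points
        centers = rng.uniform(0, 1000, (rng.integers(1, 6), 2))
        clumped = centers[rng.integers(0, len(centers), n // 2)] + \
            rng.normal(0, 15, (n // 2, 2))
        scattered = rng.uniform(0, 1000, (n - n // 2, 2))
        xy = np.vstack([clumped, scattered])
        eps, min_samples = 40.0, 5
        locs = table_from_nm(xy, n_frames=1000)
        cs = dbscan_cluster(locs, eps_override=eps,
                            min_samples_override=min_samples)
        ref_labels, ref_core = brute_force_dbscan(xy, eps, min_samples)
        assert np.array_equal(cs.core_flags, ref_core)
        # same noise set
        assert np.array_equal(cs.labels == -1, ref_labels == -1)
        # core partition identical up to relabelling
        for lab in np.unique(ref_labels[ref_labels >= 0]):
            members = np.nonzero((ref_labels == lab) & ref_core)[0]
            assert len(np.unique(cs.labels[members])) == 1
        # border points attach to a cluster owning a core neighbour
        d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
        border = (cs.labels >= 0) & ~ref_core
        for i in np.nonzero(border)[0]:
            near_core = ref_core & (d2[i] <= eps**2)
            assert cs.labels[i] in set(cs.labels[near_core])


class TestFilterClusters:
    def _cs_with_ratio(self, n_core, n_total):
        rng = np.random.default_rng(1)
        xy = rng.normal(0, 10, (n_total, 2))
        locs = table_from_nm(xy, n_frames=1000)
        cs = dbscan_cluster(locs, eps_override=100.0, min_samples_override=2)
        # overwrite stats to encode the requested core ratio
        cs.cluster_stats.loc[0, "n_core"] = n_core
        cs.cluster_stats.loc[0, "core_ratio"] = n_core / n_total
        return cs

    def test_full_core_kept(self):
        fc = filter_clusters(self._cs_with_ratio(10, 10))
        assert len(fc.cluster_stats) == 1

    def test_low_ratio_removed(self):
        fc = filter_clusters(self._cs_with_ratio(7, 10))
        assert len(fc.cluster_stats) == 0
        assert np.all(fc.labels == -1)

    def test_default_threshold(self):
        import inspect

        sig = inspect.signature(filter_clusters)
        assert sig.parameters["min_core_ratio"].default == 0.8

    def test_custom_predicate(self):
        cs = self._cs_with_ratio(10, 10)
        fc = filter_clusters(cs, predicate=lambda row: row["n_locs"] > 10**6)
        assert len(fc.cluster_stats) == 0


class TestOnRate:
    def _single_cluster(self, n_locs):
        rng = np.random.default_rng(2)
        xy = rng.normal(0, 10, (n_locs, 2))
        locs = table_from_nm(xy, n_frames=15000)
        return dbscan_cluster(locs, eps_override=100.0,
                              min_samples_override=2)

    @pytest.mark.parametrize("n,t,expected", [
        (357, 300.0, 1.19), (196, 1000.0, 0.196),
    ])
    def test_rate_arithmetic(self, n, t, expected):
        cs = self._single_cluster(n)
        _, mean, _ = estimate_on_rate(cs, t)
        assert mean == pytest.approx(expected, abs=1e-12)

    def test_zero_time_rejected(self):
        with pytest.raises(ValueError):
            estimate_on_rate(self._single_cluster(10), 0.0)

    def test_no_clusters_rejected(self):
        cs = self._single_cluster(10)
        empty = filter_clusters(cs, min_core_ratio=2.0)
        with pytest.raises(ValueError):
            estimate_on_rate(empty, 10.0)


class TestSegmentRecovery:
    def test_segments_map_to_filtered_clusters(self):
        """Well-separated segments survive the pipeline 1:1."""
        cfg = PaintSimConfig(k_on_per_segment=1.3, mean_dwell_s=0.02,
                             frame_time_s=0.02, n_frames=7500,
                             loc_precision_nm=6.0,
                             nonspecific_rate_per_um2_s=0.3,
                             fov_px=48, seed=13)
        segs = make_rod_segments(30, cfg.fov_nm, rng=np.random.default_rng(4))
        locs, truth = simulate_paint(segs, cfg)
        cs = filter_clusters(dbscan_cluster(locs))
        centers = np.array([s.spine.mean(axis=0) for s in segs])
        hits = 0
        for _, row in cs.cluster_stats.iterrows():
            d = np.linalg.norm(centers - [row["cx_nm"], row["cy_nm"]], axis=1)
            if d.min() < 100.0:
                hits += 1
        assert hits >= 0.95 * len(segs)
        assert len(cs.cluster_stats) <= len(segs) + 2
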