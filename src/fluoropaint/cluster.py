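"""Drift correction, DBSCAN segment clustering, filtering, and on-rates.

Parameter rules follow the acquisition geometry: DBSCAN ``eps`` defaults to
half a camera pixel (in nm) and ``min_samples`` to 1% of the frame count,
both rounded to integers; clusters are kept when their core-sample ratio
exceeds 0.8. Drift is removed by windowed image cross-correlation
(100-frame windows, per-window shift capped at 60 nm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.registration import phase_cross_correlation
from sklearn.cluster import DBSCAN

from .io import LocalizationTable


@dataclass
class ClusterSet:
    """DBSCAN labelling of a localization table (-1 = noise)."""

    locs: LocalizationTable
    labels: np.ndarray
    core_flags: np.ndarray
    cluster_stats: pd.DataFrame
    eps_nm: float
    min_samples: int

    def cluster_xy_nm(self, label: int) -> np.ndarray:
        sel = self.labels == label
        return np.column_stack([self.locs.x_nm[sel], self.locs.y_nm[sel]])

    @property
    def cluster_ids(self) -> np.ndarray:
        return self.cluster_stats["cluster"].to_numpy()


def drift_correct(locs: LocalizationTable, segment_frames: int = 100,
                  max_drift_nm: float = 60.0, bin_nm: float = 10.0,
                  smooth_bins: float = 1.0,
                  ) -> tuple[LocalizationTable, pd.DataFrame]:
    """Estimate and subtract stage drift by windowed cross-correlation.

    Localizations are grouped in windows of ``segment_frames`` frames and
    rendered as smoothed 2D histograms. Each window is pre-shifted by the
    running drift estimate and registered against the first window
    (subpixel cross-correlation); the per-window increment is capped at
    ``max_drift_nm``. Window-center estimates are interpolated per frame
    and subtracted. Returns the corrected table and the drift trace in nm.
    """
    n_windows = int(np.ceil(locs.n_frames / segment_frames))
    if n_windows < 2:
        raise ValueError("need at least 2 windows of frames for drift correction")
    x, y = locs.x_nm, locs.y_nm
    frames = locs.df["frame"].to_numpy()
    pad = 2 * max_drift_nm + 4 * bin_nm
    x0, x1 = x.min() - pad, x.max() + pad
    y0, y1 = y.min() - pad, y.max() + pad
    bins = [np.arange(y0, y1 + bin_nm, bin_nm), np.arange(x0, x1 + bin_nm, bin_nm)]

    def render(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        img, _, _ = np.histogram2d(ys, xs, bins=bins)
        return ndimage.gaussian_filter(img, smooth_bins)

    win = np.minimum(frames // segment_frames, n_windows - 1)
    ref = None
    centers = (np.arange(n_windows) + 0.5) * segment_frames
    drift = np.zeros((n_windows, 2))  # (dx, dy) in nm
    running = np.zeros(2)
    for k in range(n_windows):
        sel = win == k
        if sel.sum() < 10:
            warnings.warn(f"drift window {k}: too few localizations, carried over")
            drift[k] = running
            continue
        img = render(x[sel] - running[0], y[sel] - running[1])
        if ref is None:
            ref = img
            drift[k] = running
            continue
        shift, _, _ = phase_cross_correlation(ref, img, upsample_factor=20,
                                              normalization=None)
        delta = -np.array([shift[1], shift[0]]) * bin_nm  # moving vs reference
        delta = np.clip(delta, -max_drift_nm, max_drift_nm)
        running = running + delta
        drift[k] = running

    fidx = np.arange(locs.n_frames, dtype=float)
    dx = np.interp(fidx, centers, drift[:, 0])
    dy = np.interp(fidx, centers, drift[:, 1])
    df = locs.df.copy()
    df["x"] = df["x"] - dx[frames] / locs.pixel_nm
    df["y"] = df["y"] - dy[frames] / locs.pixel_nm
    trace = pd.DataFrame({"frame": np.arange(locs.n_frames),
                          "drift_x_nm": dx, "drift_y_nm": dy})
    return LocalizationTable(df, locs.pixel_nm, locs.n_frames), trace


def dbscan_cluster(locs: LocalizationTable,
                   eps_override: float | None = None,
                   min_samples_override: int | None = None) -> ClusterSet:
    """Density clustering with acquisition-derived parameters.

    ``eps = 0.5 * pixel_nm`` (nm) and ``min_samples = round(0.01 * n_frames)``
    unless overridden. Core points have at least ``min_samples`` neighbours
    within ``eps`` (the point itself included). Localizations are processed
    in a fixed order (frame, then x, then y) so border-point assignment is
    deterministic.
    """
    if len(locs) == 0:
        raise ValueError("empty localization table")
    eps = eps_override if eps_override is not None else 0.5 * locs.pixel_nm
    if min_samples_override is not None:
        min_samples = int(min_samples_override)
    else:
        min_samples = int(round(0.01 * locs.n_frames))
    if min_samples < 1:
        raise ValueError(
            "min_samples rounds to < 1 for this frame count; pass min_samples_override")

    order = np.lexsort((locs.df["y"].to_numpy(), locs.df["x"].to_numpy(),
                        locs.df["frame"].to_numpy()))
    xy = np.column_stack([locs.x_nm, locs.y_nm])[order]
    db = DBSCAN(eps=eps, min_samples=min_samples).fit(xy)
    labels = np.empty(len(locs), dtype=int)
    labels[order] = db.labels_
    core = np.zeros(len(locs), dtype=bool)
    core[order[db.core_sample_indices_]] = True

    stats = _cluster_stats(locs, labels, core)
    return ClusterSet(locs=locs, labels=labels, core_flags=core,
                      cluster_stats=stats, eps_nm=float(eps),
                      min_samples=min_samples)


def _cluster_stats(locs: LocalizationTable, labels: np.ndarray,
                   core: np.ndarray) -> pd.DataFrame:
    rows = []
    frames = locs.df["frame"].to_numpy()
    for lab in np.unique(labels[labels >= 0]):
        sel = labels == lab
        rows.append({
            "cluster": int(lab),
            "n_locs": int(sel.sum()),
            "n_core": int((sel & core).sum()),
            "core_ratio": float((sel & core).sum() / sel.sum()),
            "cx_nm": float(locs.x_nm[sel].mean()),
            "cy_nm": float(locs.y_nm[sel].mean()),
            "duration_frames": int(frames[sel].max() - frames[sel].min() + 1),
        })
    cols = ["cluster", "n_locs", "n_core", "core_ratio", "cx_nm", "cy_nm",
            "duration_frames"]
    return pd.DataFrame(rows, columns=cols)


def filter_clusters(cs: ClusterSet, min_core_ratio: float = 0.8,
                    predicate=None) -> ClusterSet:
    """Keep clusters with core-sample ratio above ``min_core_ratio``.

    ``predicate`` is an optional extra acceptance test receiving the
    cluster's stats row (a pandas Series); it is off by default.
    Localizations of removed clusters are relabelled as noise (-1).
    """
    keep_ids = []
    for _, row in cs.cluster_stats.iterrows():
        if row["core_ratio"] <= min_core_ratio:
            continue
        if predicate is not None and not predicate(row):
            continue
        keep_ids.append(int(row["cluster"]))
    keep_set = set(keep_ids)
    labels = np.where(np.isin(cs.labels, keep_ids), cs.labels, -1)
    stats = cs.cluster_stats[cs.cluster_stats["cluster"].isin(keep_set)]
    return ClusterSet(locs=cs.locs, labels=labels, core_flags=cs.core_flags,
                      cluster_stats=stats.reset_index(drop=True),
                      eps_nm=cs.eps_nm, min_samples=cs.min_samples)


def estimate_on_rate(cs: ClusterSet, acquisition_time_s: float,
                     link_events: bool = False):
    """Localizations per cluster per second, averaged across clusters.

    Returns ``(per_cluster_df, mean_rate, sem)``. With ``link_events``,
    consecutive-frame localizations within a cluster are merged into single
    binding events before counting (reported as ``event_rate_per_s``).
    """
    if acquisition_time_s <= 0:
        raise ValueError("acquisition time must be positive")
    if len(cs.cluster_stats) == 0:
        raise ValueError("no clusters survive; cannot estimate an on-rate")
    df = cs.cluster_stats.copy()
    df["rate_per_s"] = df["n_locs"] / acquisition_time_s
    if link_events:
        frames = cs.locs.df["frame"].to_numpy()
        n_events = []
        for lab in df["cluster"]:
            f = np.sort(frames[cs.labels == lab])
            n_events.append(int(1 + np.sum(np.diff(f) > 1)) if len(f) else 0)
        df["event_rate_per_s"] = np.array(n_events) / acquisition_time_s
    rates = df["rate_per_s"].to_numpy()
    mean = float(rates.mean())
    sem = float(rates.std(ddof=1) / np.sqrt(len(rates))) if len(rates) > 1 else 0.0
    return df, mean, sem
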