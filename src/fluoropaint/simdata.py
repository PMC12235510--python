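"""Synthetic data generators with known ground truth.

Three experiment families are emulated, matching the structure of the
analyses in this package:

* **Characterization movies** — immobilized fluorogenic probes as
  diffraction-limited Gaussian spots over a diffuse, concentration-
  proportional background, Poisson photon noise, linear sCMOS camera model.
* **DNA-PAINT localization streams** — transient binding (Poisson arrivals,
  exponential dwells) to rod-like segments, Gaussian localization error,
  linear stage drift, uniform nonspecific events; the event log carries the
  ground truth for every downstream estimand.
* **Two-state intensity traces** — continuous-time telegraph processes
  discretized to camera frames with time-weighted intensity mixing.

All generators draw from child streams of one master seed and are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .camera import CameraCalibration, MovieStack
from .io import LocalizationTable

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def count_binding_registers(imager_seq: str, docking_seq: str) -> int:
    """Number of positions (overlaps allowed) where the imager can hybridize.

    Counts exact matches of the reverse complement of ``imager_seq`` inside
    ``docking_seq``. A repetitive docking extension can present several
    binding registers to one short imager, multiplying its effective
    on-rate.
    """
    for name, s in (("imager", imager_seq), ("docking", docking_seq)):
        bad = set(s) - set("ACGT")
        if bad:
            raise ValueError(f"{name} sequence has non-ACGT character(s): {sorted(bad)}")
    if len(imager_seq) > len(docking_seq):
        raise ValueError("imager longer than docking sequence")
    rc = reverse_complement(imager_seq)
    return sum(docking_seq.startswith(rc, i)
               for i in range(len(docking_seq) - len(rc) + 1))


# ---------------------------------------------------------------------------
# ground-truth types


@dataclass(frozen=True)
class ProbeGroundTruth:
    """True photophysical parameters of a simulated fluorogenic probe.

    ``s_n_true`` and ``b_n_true`` are the probe's signal and molar
    background relative to a fluorophore-only reference, so
    ``s_n_true / b_n_true`` is the ground-truth fluorogenic factor.
    """

    name: str
    length_nt: int
    r0_nm: float
    s_n_true: float
    b_n_true: float
    has_secondary_structure: bool = False

    def __post_init__(self) -> None:
        if self.length_nt < 5:
            raise ValueError("length_nt must be >= 5")
        if self.r0_nm <= 0:
            raise ValueError("r0_nm must be positive")
        for nm, v in (("s_n_true", self.s_n_true), ("b_n_true", self.b_n_true)):
            if not (0 < v <= 1):
                raise ValueError(f"{nm} must be in (0, 1]")

    @property
    def ff_true(self) -> float:
        return self.s_n_true / self.b_n_true


@dataclass
class SegmentGroundTruth:
    """A rod-like target: spine polyline (nm) with a cylinder radius."""

    spine: np.ndarray  # (k, 2) points in nm
    radius_nm: float
    n_docking_sites: int = 48

    def __post_init__(self) -> None:
        self.spine = np.asarray(self.spine, dtype=float)
        if self.spine.ndim != 2 or self.spine.shape[0] < 2 or self.spine.shape[1] != 2:
            raise ValueError("spine must be a (k>=2, 2) polyline")
        if self.radius_nm <= 0:
            raise ValueError("radius_nm must be positive")
        if self.n_docking_sites < 1:
            raise ValueError("n_docking_sites must be positive")

    @property
    def length_nm(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.spine, axis=0), axis=1)))


@dataclass(frozen=True)
class PaintSimConfig:
    """Conditions of a simulated DNA-PAINT acquisition."""

    k_on_per_segment: float = 1.19        # binding events / s / segment
    mean_dwell_s: float = 0.02            # exponential dwell mean
    frame_time_s: float = 0.02            # 20 ms exposures
    n_frames: int = 15000                 # 300 s acquisition
    loc_precision_nm: float = 6.0
    drift_nm_per_frame: tuple[float, float] = (0.0, 0.0)
    nonspecific_rate_per_um2_s: float = 0.0
    pixel_nm: float = 117.0
    fov_px: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        for nm in ("k_on_per_segment", "mean_dwell_s", "frame_time_s",
                   "loc_precision_nm", "pixel_nm"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be strictly positive")
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        if self.nonspecific_rate_per_um2_s < 0:
            raise ValueError("nonspecific rate must be >= 0")

    @property
    def fov_nm(self) -> float:
        return self.fov_px * self.pixel_nm

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_time_s


@dataclass(frozen=True)
class TraceSimConfig:
    """Conditions of a simulated two-state intensity-trace acquisition."""

    k_on: float = 0.5           # 1/s, unbound -> bound
    k_off: float = 2.0          # 1/s, bound -> unbound
    exposure_s: float = 0.2     # 200 ms frames
    n_frames: int = 1500
    i_bound: float = 1000.0     # photons / frame
    i_unbound: float = 0.0
    noise_sd: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_on <= 0 or self.k_off <= 0:
            raise ValueError("rates must be strictly positive")
        if self.exposure_s <= 0 or self.n_frames <= 0:
            raise ValueError("exposure and frame count must be positive")
        if not self.i_bound > self.i_unbound >= 0:
            raise ValueError("need i_bound > i_unbound >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Deterministic per-stream generators derived from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# rod-segment helpers


def make_rod_segments(n: int, fov_nm: float, length_range_nm: tuple[float, float] = (60.0, 120.0),
                      radius_nm: float = 16.0, n_docking_sites: int = 48,
                      margin_nm: float = 200.0,
                      rng: np.random.Generator | None = None) -> list[SegmentGroundTruth]:
    """Place n well-separated straight rods on a jittered grid in the FOV."""
    rng = rng or np.random.default_rng(0)
    grid = int(np.ceil(np.sqrt(n)))
    cell = (fov_nm - 2 * margin_nm) / grid
    if cell < max(length_range_nm):
        raise ValueError("FOV too small for this many well-separated segments")
    segs: list[SegmentGroundTruth] = []
    order = rng.permutation(grid * grid)[:n]
    for idx in order:
        gy, gx = divmod(int(idx), grid)
        cx = margin_nm + (gx + 0.5) * cell + rng.uniform(-0.1, 0.1) * cell
        cy = margin_nm + (gy + 0.5) * cell + rng.uniform(-0.1, 0.1) * cell
        length = rng.uniform(*length_range_nm)
        theta = rng.uniform(0, np.pi)
        d = 0.5 * length * np.array([np.cos(theta), np.sin(theta)])
        spine = np.array([[cx, cy] - d, [cx, cy] + d])
        segs.append(SegmentGroundTruth(spine, radius_nm, n_docking_sites))
    return segs


def _sample_on_projection(seg: SegmentGroundTruth, n: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Uniform points on the 2D projection of the cylinder around the spine.

    The projection of a rod is a rectangle of width 2*radius along the
    spine plus semicircular end caps; points are drawn uniformly over that
    stadium shape.
    """
    r = seg.radius_nm
    vecs = np.diff(seg.spine, axis=0)
    seglen = np.linalg.norm(vecs, axis=1)
    L = seglen.sum()
    area_rect = 2 * r * L
    area_caps = np.pi * r**2
    p_rect = area_rect / (area_rect + area_caps)
    pts = np.empty((n, 2))
    in_rect = rng.random(n) < p_rect
    k = int(in_rect.sum())
    if k:
        s = rng.uniform(0, L, size=k)
        v = rng.uniform(-r, r, size=k)
        cum = np.concatenate([[0.0], np.cumsum(seglen)])
        iseg = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(vecs) - 1)
        t = (s - cum[iseg]) / seglen[iseg]
        base = seg.spine[iseg] + t[:, None] * vecs[iseg]
        tang = vecs[iseg] / seglen[iseg][:, None]
        norm = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
        pts[in_rect] = base + v[:, None] * norm
    m = n - k
    if m:
        # uniform in a disc, split between the two end caps
        rad = r * np.sqrt(rng.random(m))
        ang = rng.uniform(0, 2 * np.pi, size=m)
        offs = np.stack([rad * np.cos(ang), rad * np.sin(ang)], axis=1)
        which_end = rng.integers(0, 2, size=m)
        ends = np.where(which_end[:, None] == 0, seg.spine[0], seg.spine[-1])
        pts[~in_rect] = ends + offs
    return pts


# ---------------------------------------------------------------------------
# DNA-PAINT stream


@dataclass
class PaintTruth:
    """Ground truth of a simulated PAINT acquisition.

    ``events`` has one row per binding event (segment, site position, start
    time, dwell, number of localizations it produced); ``loc_event`` /
    ``loc_segment`` assign each row of the localization table to its event
    and segment (-1 = nonspecific).
    """

    events: pd.DataFrame
    loc_event: np.ndarray
    loc_segment: np.ndarray
    drift_nm: np.ndarray  # (n_frames, 2) cumulative injected drift
    segments: list[SegmentGroundTruth] = field(default_factory=list)


def expected_localization_rate(k_on: float, mean_dwell_s: float,
                               frame_time_s: float) -> float:
    """Expected localizations / s / segment under the >=50% overlap rule.

    A frame records a localization when the binding event overlaps it by at
    least half the exposure. For Poisson arrivals at rate ``k_on`` and
    Exp(tau) dwells, the window of event start times that half-covers a
    given frame has expected length E[d; d >= dt/2] = (tau + dt/2) e^{-dt/(2 tau)},
    so the per-frame localization probability is k_on times that, and the
    rate per second divides by the frame time.
    """
    tau, dt = mean_dwell_s, frame_time_s
    return k_on * (tau + dt / 2) * np.exp(-dt / (2 * tau)) / dt


def k_on_for_localization_rate(target_rate: float, mean_dwell_s: float,
                               frame_time_s: float) -> float:
    """Invert :func:`expected_localization_rate` for the event rate."""
    return target_rate / expected_localization_rate(1.0, mean_dwell_s, frame_time_s)


def simulate_paint(segments: list[SegmentGroundTruth],
                   cfg: PaintSimConfig) -> tuple[LocalizationTable, PaintTruth]:
    """Simulate a DNA-PAINT localization stream from rod-like segments.

    Binding events per segment form a Poisson process; each event picks one
    of the segment's docking sites (sites drawn once, uniformly over the
    projected cylinder), lasts an exponential dwell, and yields one
    localization per camera frame it overlaps by at least half the
    exposure. Localizations get isotropic Gaussian error plus the
    cumulative linear drift; nonspecific localizations appear uniformly in
    the FOV at the configured areal rate.
    """
    if not segments:
        raise ValueError("need at least one segment")
    fov = cfg.fov_nm
    for i, seg in enumerate(segments):
        if np.any(seg.spine < 0) or np.any(seg.spine > fov):
            raise ValueError(f"segment {i} spine outside the FOV")

    rng_ev, rng_site, rng_err, rng_ns, rng_phot = child_rngs(cfg.seed, 5)
    T, dt = cfg.duration_s, cfg.frame_time_s

    seg_ids, t0s, dwells, sites = [], [], [], []
    for i, seg in enumerate(segments):
        site_xy = _sample_on_projection(seg, seg.n_docking_sites, rng_site)
        n_ev = rng_ev.poisson(cfg.k_on_per_segment * T)
        if n_ev == 0:
            continue
        t0 = np.sort(rng_ev.uniform(0, T, size=n_ev))
        d = rng_ev.exponential(cfg.mean_dwell_s, size=n_ev)
        which = rng_ev.integers(0, seg.n_docking_sites, size=n_ev)
        seg_ids.append(np.full(n_ev, i))
        t0s.append(t0)
        dwells.append(d)
        sites.append(site_xy[which])
    if not t0s:
        seg_id = np.empty(0, int)
        t0 = dwell = np.empty(0)
        site = np.empty((0, 2))
    else:
        seg_id = np.concatenate(seg_ids)
        t0 = np.concatenate(t0s)
        dwell = np.concatenate(dwells)
        site = np.concatenate(sites)

    # frames overlapped by >= dt/2, vectorized over events
    k0 = np.floor(t0 / dt).astype(np.int64)
    k1 = np.floor((t0 + dwell) / dt).astype(np.int64)
    same = k0 == k1
    left_ov = np.where(same, dwell, (k0 + 1) * dt - t0)
    right_ov = t0 + dwell - k1 * dt
    inc_left = left_ov >= dt / 2
    inc_right = ~same & (right_ov >= dt / 2)

    ev_idx_parts, frame_parts = [], []
    ev_all = np.arange(len(t0))
    ev_idx_parts.append(ev_all[inc_left]); frame_parts.append(k0[inc_left])
    ev_idx_parts.append(ev_all[inc_right]); frame_parts.append(k1[inc_right])
    n_mid = np.clip(k1 - k0 - 1, 0, None)
    tot_mid = int(n_mid.sum())
    if tot_mid:
        ev_mid = np.repeat(ev_all, n_mid)
        offs = np.arange(tot_mid) - np.repeat(np.cumsum(n_mid) - n_mid, n_mid)
        frame_parts.append(k0[ev_mid] + 1 + offs)
        ev_idx_parts.append(ev_mid)
    loc_ev = np.concatenate(ev_idx_parts)
    loc_frame = np.concatenate(frame_parts)
    keep = (loc_frame >= 0) & (loc_frame < cfg.n_frames)
    loc_ev, loc_frame = loc_ev[keep], loc_frame[keep]

    drift = np.outer(np.arange(cfg.n_frames), np.asarray(cfg.drift_nm_per_frame, float))
    xy = (site[loc_ev]
          + rng_err.normal(0, cfg.loc_precision_nm, size=(len(loc_ev), 2))
          + drift[loc_frame])
    loc_segment = seg_id[loc_ev]

    # nonspecific: single-frame localizations, uniform in space and time
    area_um2 = (fov / 1000.0) ** 2
    n_ns = rng_ns.poisson(cfg.nonspecific_rate_per_um2_s * area_um2 * T)
    if n_ns:
        ns_frame = rng_ns.integers(0, cfg.n_frames, size=n_ns)
        ns_xy = rng_ns.uniform(0, fov, size=(n_ns, 2)) + drift[ns_frame]
        loc_frame = np.concatenate([loc_frame, ns_frame])
        xy = np.concatenate([xy, ns_xy])
        loc_ev = np.concatenate([loc_ev, np.full(n_ns, -1)])
        loc_segment = np.concatenate([loc_segment, np.full(n_ns, -1)])

    order = np.lexsort((xy[:, 0], xy[:, 1], loc_frame))
    loc_frame, xy = loc_frame[order], xy[order]
    loc_ev, loc_segment = loc_ev[order], loc_segment[order]

    photons = rng_phot.poisson(1000.0, size=len(loc_frame)).astype(float)
    lp_px = cfg.loc_precision_nm / cfg.pixel_nm
    df = pd.DataFrame({
        "frame": loc_frame,
        "x": xy[:, 0] / cfg.pixel_nm,
        "y": xy[:, 1] / cfg.pixel_nm,
        "photons": photons,
        "sx": 1.1, "sy": 1.1, "bg": 0.0, "lpx": lp_px, "lpy": lp_px,
    })
    table = LocalizationTable(df, cfg.pixel_nm, cfg.n_frames)

    n_locs_per_event = np.bincount(loc_ev[loc_ev >= 0], minlength=len(t0))
    events = pd.DataFrame({
        "event": np.arange(len(t0)),
        "segment": seg_id,
        "x_nm": site[:, 0], "y_nm": site[:, 1],
        "t_start_s": t0, "dwell_s": dwell,
        "n_locs": n_locs_per_event,
    })
    truth = PaintTruth(events=events, loc_event=loc_ev, loc_segment=loc_segment,
                       drift_nm=drift, segments=list(segments))
    return table, truth


# ---------------------------------------------------------------------------
# characterization movies


def _render_spots(shape: tuple[int, int], xy: np.ndarray, photons: np.ndarray,
                  sigma_px: float) -> np.ndarray:
    """Expected photon image of Gaussian PSF spots (pixel-integrated)."""
    from scipy.special import erf

    img = np.zeros(shape)
    h, w = shape
    half = int(np.ceil(5 * sigma_px))
    s2 = sigma_px * np.sqrt(2)
    for (x, y), n in zip(xy, photons):
        x0, y0 = int(round(x)), int(round(y))
        xs = np.arange(max(x0 - half, 0), min(x0 + half + 1, w))
        ys = np.arange(max(y0 - half, 0), min(y0 + half + 1, h))
        if len(xs) == 0 or len(ys) == 0:
            continue
        fx = 0.5 * (erf((xs + 0.5 - x) / s2) - erf((xs - 0.5 - x) / s2))
        fy = 0.5 * (erf((ys + 0.5 - y) / s2) - erf((ys - 0.5 - y) / s2))
        img[np.ix_(ys, xs)] += n * np.outer(fy, fx)
    return img


def simulate_characterization_movie(
    probe: ProbeGroundTruth,
    concentration_nM: float,
    n_molecules: int,
    ref_signal_photons: float = 4000.0,
    ref_bg_photons_per_nM: float = 5.0,
    camera: CameraCalibration | None = None,
    seed: int = 0,
    n_frames: int = 10,
    fov_px: int = 256,
    psf_sigma_px: float = 1.1,
    dark_photons: float = 10.0,
    unquenched_fraction: float = 0.0,
    min_separation_px: float = 10.0,
    shot_noise: bool = True,
) -> tuple[MovieStack, pd.DataFrame]:
    """Simulate a TIRF characterization movie of immobilized probes.

    Spots emit ``s_n_true * ref_signal_photons`` per frame (fraction
    ``unquenched_fraction`` of molecules carry a dead quencher and emit the
    full reference signal); the diffuse background is
    ``dark + b_n_true * ref_bg_photons_per_nM * concentration`` photons per
    pixel. ADU = baseline + gain * photons, Poisson shot noise, quantized
    to 16-bit. Returns the movie and the ground-truth spot table.
    """
    if concentration_nM < 0:
        raise ValueError("concentration must be >= 0")
    camera = camera or CameraCalibration()
    rng_pos, rng_noise, rng_pop = child_rngs(seed, 3)

    margin = 6.0
    pos: list[np.ndarray] = []
    attempts = 0
    while len(pos) < n_molecules and attempts < 100 * max(n_molecules, 1):
        p = rng_pos.uniform(margin, fov_px - margin, size=2)
        if all(np.max(np.abs(p - q)) >= min_separation_px for q in pos):
            pos.append(p)
        attempts += 1
    if len(pos) < n_molecules:
        raise ValueError("could not place molecules with the requested separation")
    xy = np.array(pos) if pos else np.empty((0, 2))

    unquenched = rng_pop.random(n_molecules) < unquenched_fraction
    spot_means = np.where(unquenched, ref_signal_photons,
                          probe.s_n_true * ref_signal_photons)
    bg_rate = dark_photons + probe.b_n_true * ref_bg_photons_per_nM * concentration_nM

    expected = _render_spots((fov_px, fov_px), xy, spot_means, psf_sigma_px) + bg_rate
    frames = np.empty((n_frames, fov_px, fov_px), dtype=np.uint16)
    for i in range(n_frames):
        photons = rng_noise.poisson(expected).astype(float) if shot_noise else expected
        adu = np.rint(camera.baseline + camera.gain * photons)
        frames[i] = np.clip(adu, 0, 2**16 - 1).astype(np.uint16)

    truth = pd.DataFrame({
        "x": xy[:, 0], "y": xy[:, 1],
        "photons_per_frame": spot_means,
        "unquenched": unquenched,
    })
    return MovieStack(frames, camera), truth


# ---------------------------------------------------------------------------
# intensity traces


@dataclass
class TraceSimResult:
    """Simulated traces with their continuous-time ground truth."""

    traces: np.ndarray          # (n_traces, n_frames) noisy intensities
    bound_fraction: np.ndarray  # (n_traces, n_frames) time in bound state per frame
    state_paths: np.ndarray     # (n_traces, n_frames) majority state per frame
    dwells_bound: list[np.ndarray]    # true continuous dwells per trace
    dwells_unbound: list[np.ndarray]


def simulate_traces(cfg: TraceSimConfig, n_traces: int = 1) -> TraceSimResult:
    """Simulate two-state telegraph intensity traces discretized to frames.

    The underlying process alternates exponential sojourns (rates ``k_on``
    unbound->bound, ``k_off`` bound->unbound) starting from the stationary
    distribution; the frame intensity is the time-weighted mix of the two
    levels plus Gaussian read noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    T = cfg.n_frames * cfg.exposure_s
    traces = np.empty((n_traces, cfg.n_frames))
    fracs = np.empty((n_traces, cfg.n_frames))
    d_bound: list[np.ndarray] = []
    d_unbound: list[np.ndarray] = []
    p_bound = cfg.k_on / (cfg.k_on + cfg.k_off)
    edges = np.arange(cfg.n_frames + 1) * cfg.exposure_s
    for i in range(n_traces):
        state = int(rng.random() < p_bound)
        t, times, states, db, du = 0.0, [0.0], [state], [], []
        while t < T:
            rate = cfg.k_off if state else cfg.k_on
            d = rng.exponential(1.0 / rate)
            (db if state else du).append(d)  # ground-truth sojourn, untruncated
            t += d
            state = 1 - state
            times.append(min(t, T))
            states.append(state)
        # accumulate bound time per frame from the sojourn intervals
        bound_time = np.zeros(cfg.n_frames)
        for t0, t1, s in zip(times[:-1], times[1:], states[:-1]):
            if not s or t1 <= t0:
                continue
            a, b = np.searchsorted(edges, [t0, t1], side="right") - 1
            b = min(b, cfg.n_frames - 1)
            if a == b:
                bound_time[a] += t1 - t0
            else:
                bound_time[a] += edges[a + 1] - t0
                bound_time[a + 1:b] += cfg.exposure_s
                bound_time[b] += t1 - edges[b]
        frac = bound_time / cfg.exposure_s
        clean = cfg.i_unbound + (cfg.i_bound - cfg.i_unbound) * frac
        noise = rng.normal(0, cfg.noise_sd, size=cfg.n_frames) if cfg.noise_sd else 0.0
        traces[i] = clean + noise
        fracs[i] = frac
        d_bound.append(np.array(db))
        d_unbound.append(np.array(du))
    return TraceSimResult(traces=traces, bound_fraction=fracs,
                          state_paths=(fracs > 0.5).astype(int),
                          dwells_bound=d_bound, dwells_unbound=d_unbound)
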