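"""Hybridization dwell-time kinetics from two-state intensity traces.

Traces are segmented with a two-state Gaussian-emission HMM; run lengths
become dwell times. Because the camera only resolves dwells between one
frame time (``t_min``) and the trace duration (``t_max``), lifetimes are
fitted with the **truncated exponential** likelihood

    f(t) = (1/tau) exp(-t/tau) / (exp(-t_min/tau) - exp(-t_max/tau)),

which removes the upward bias of the naive sample mean caused by the
shortest dwells being unobservable. Confidence intervals come from a
seeded nonparametric bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar


@dataclass
class HMMSegmentation:
    """Decoded state path of one intensity trace (1 = bound, higher mean)."""

    states: np.ndarray
    level_means: np.ndarray
    single_state: bool = False


@dataclass
class DwellSet:
    """Dwell durations with the censoring metadata needed for fitting."""

    durations_s: np.ndarray          # complete (untruncated) dwells
    t_min_s: float                   # shortest observable dwell (1 frame)
    t_max_s: float                   # observation window (trace duration)
    state: str = "bound"
    truncated_durations_s: np.ndarray = field(
        default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.durations_s = np.asarray(self.durations_s, dtype=float)
        if self.t_min_s >= self.t_max_s:
            raise ValueError("t_min must be < t_max")
        if np.any(self.durations_s < self.t_min_s - 1e-12) or \
                np.any(self.durations_s > self.t_max_s + 1e-12):
            raise ValueError("durations must lie in [t_min, t_max]")


@dataclass
class LifetimeEstimate:
    """Exponential lifetime with a bootstrap 95% confidence interval."""

    tau_s: float
    ci_low: float
    ci_high: float
    n_events: int
    boot_taus: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.tau_s <= self.ci_high):
            raise ValueError("require ci_low <= tau <= ci_high")


def segment_trace_hmm(trace: np.ndarray, seed: int = 0) -> HMMSegmentation:
    """Two-state Gaussian HMM segmentation of an intensity trace.

    EM-trained (k-means initialized means) and Viterbi-decoded via
    hmmlearn; the higher-mean state is labelled 1 (bound). A degenerate
    (zero-variance) trace returns a flagged single-state result.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1 or len(trace) < 20:
        raise ValueError("trace must be 1D with at least 20 frames")
    if np.ptp(trace) == 0 or np.std(trace) == 0:
        warnings.warn("degenerate (constant) trace: single-state result")
        return HMMSegmentation(states=np.zeros(len(trace), dtype=int),
                               level_means=np.array([trace[0]]),
                               single_state=True)

    from hmmlearn.hmm import GaussianHMM
    from sklearn.cluster import KMeans

    X = trace.reshape(-1, 1)
    km = KMeans(n_clusters=2, n_init=5, random_state=seed).fit(X)
    means0 = np.sort(km.cluster_centers_.ravel()).reshape(-1, 1)
    model = GaussianHMM(n_components=2, covariance_type="diag", n_iter=200,
                        random_state=seed, init_params="c", params="stmc",
                        min_covar=1e-6)
    model.startprob_ = np.array([0.5, 0.5])
    model.transmat_ = np.array([[0.95, 0.05], [0.05, 0.95]])
    model.means_ = means0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X)
        states = model.predict(X)
    means = model.means_.ravel()
    if means[0] > means[1]:  # enforce: state 1 = higher mean = bound
        states = 1 - states
        means = means[::-1]
    return HMMSegmentation(states=states, level_means=means, single_state=False)


def extract_dwells(states: np.ndarray, frame_time_s: float,
                   state: int = 1) -> DwellSet:
    """Run lengths of ``state`` converted to seconds.

    The first and last runs of a trace touch the observation boundaries and
    are therefore censored; they are kept separately
    (``truncated_durations_s``) and excluded from fitting by default.
    ``t_min`` is one frame, ``t_max`` the trace duration.
    """
    states = np.asarray(states)
    n = len(states)
    if n == 0:
        raise ValueError("empty state path")
    change = np.nonzero(np.diff(states))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n]])
    lengths = ends - starts
    vals = states[starts]
    sel = vals == state
    runs = lengths[sel].astype(float) * frame_time_s
    # boundary runs are censored
    first_last = np.zeros(sel.sum(), dtype=bool)
    idx = np.nonzero(sel)[0]
    if len(idx):
        if idx[0] == 0:
            first_last[0] = True
        if idx[-1] == len(vals) - 1:
            first_last[-1] = True
    return DwellSet(durations_s=runs[~first_last],
                    t_min_s=frame_time_s,
                    t_max_s=max(n, 2) * frame_time_s,
                    state="bound" if state == 1 else "unbound",
                    truncated_durations_s=runs[first_last])


def merge_dwells(dwell_sets: list[DwellSet]) -> DwellSet:
    """Pool dwells from several traces (common t_min, max t_max)."""
    if not dwell_sets:
        raise ValueError("no dwell sets to merge")
    t_min = dwell_sets[0].t_min_s
    if any(abs(d.t_min_s - t_min) > 1e-12 for d in dwell_sets):
        raise ValueError("dwell sets have inconsistent t_min")
    return DwellSet(
        durations_s=np.concatenate([d.durations_s for d in dwell_sets]),
        t_min_s=t_min,
        t_max_s=max(d.t_max_s for d in dwell_sets),
        state=dwell_sets[0].state,
        truncated_durations_s=np.concatenate(
            [d.truncated_durations_s for d in dwell_sets]),
    )


def _neg_loglik_per_event(tau: float, tbar: float, t_min: float,
                          t_max: float) -> float:
    """Truncated-exponential negative log-likelihood divided by n.

    Depends on the data only through the sample mean (sufficient
    statistic), which keeps bootstrap refits cheap.
    """
    a, b = t_min / tau, t_max / tau
    # log(exp(-a) - exp(-b)) computed stably
    log_norm = -a + np.log1p(-np.exp(-(b - a)))
    return np.log(tau) + tbar / tau + log_norm


def _solve_tau(tbar: float, t_min: float, t_max: float) -> float:
    """Maximize the truncated-exponential likelihood for a sample mean."""
    # if tbar is at/above the midpoint the MLE diverges (uniform limit)
    if tbar >= (t_min + t_max) / 2 - 1e-12:
        return np.inf
    if tbar <= t_min + 1e-12:
        return 0.0
    res = minimize_scalar(
        lambda lt: _neg_loglik_per_event(np.exp(lt), tbar, t_min, t_max),
        bounds=(np.log(t_min / 100), np.log(t_max * 100)), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(np.exp(res.x))


def fit_dwell_mle(dwells: DwellSet, n_boot: int = 1000, seed: int = 0,
                  ci: float = 0.95) -> LifetimeEstimate:
    """Truncated-exponential MLE of the dwell lifetime with bootstrap CI.

    Raises if fewer than 10 complete dwells are available or the estimate
    sits on a boundary (all dwells at ``t_min``, or a sample mean so large
    the truncated model degenerates to uniform).
    """
    t = dwells.durations_s
    if len(t) < 10:
        raise ValueError(f"need >= 10 untruncated dwells, got {len(t)}")
    tau = _solve_tau(float(t.mean()), dwells.t_min_s, dwells.t_max_s)
    if tau == 0.0:
        raise RuntimeError("all dwells at t_min: lifetime not identifiable")
    if not np.isfinite(tau):
        raise RuntimeError("sample mean exceeds the truncated-model midpoint; "
                           "lifetime not identifiable in this window")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(t), size=(n_boot, len(t)))
    boot_means = t[idx].mean(axis=1)
    boot = np.array([_solve_tau(m, dwells.t_min_s, dwells.t_max_s)
                     for m in boot_means])
    boot = boot[np.isfinite(boot) & (boot > 0)]
    alpha = (1 - ci) / 2
    lo, hi = np.quantile(boot, [alpha, 1 - alpha])
    return LifetimeEstimate(tau_s=tau, ci_low=float(min(lo, tau)),
                            ci_high=float(max(hi, tau)), n_events=len(t),
                            boot_taus=boot)


def lifetime_ratio(a: LifetimeEstimate, b: LifetimeEstimate,
                   ci: float = 0.95) -> tuple[float, float, float]:
    """Ratio tau_a / tau_b with a bootstrap confidence interval.

    Uses the stored bootstrap samples of both estimates (independent
    resampling), so the CI reflects the uncertainty of both lifetimes.
    """
    ratio = a.tau_s / b.tau_s
    if len(a.boot_taus) and len(b.boot_taus):
        n = min(len(a.boot_taus), len(b.boot_taus))
        ratios = a.boot_taus[:n] / b.boot_taus[:n]
        alpha = (1 - ci) / 2
        lo, hi = np.quantile(ratios, [alpha, 1 - alpha])
    else:
        lo = hi = ratio
    return float(ratio), float(lo), float(hi)
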