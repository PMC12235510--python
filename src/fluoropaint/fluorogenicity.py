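"""Fluorogenic-factor quantification.

The fluorogenic factor FF is the fold change in emission upon
hybridization, computed from four measured quantities:

* ``S_FQ`` / ``S_F`` — mean single-spot brightness of the doubly labelled
  probe and of a fluorophore-only reference; their ratio is the normalized
  signal ``S_N``.
* ``B_FQ,mol`` / ``B_F,mol`` — slopes of the diffuse background vs probe
  concentration (molar background) for probe and reference; their ratio is
  the normalized molar background ``B_N,mol``.

``FF = S_N / B_N,mol``. Normalizing both quantities to the same
fluorophore-only reference cancels any global brightness changes (quantum
yield, excitation power), isolating the effect of the quencher.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture


@dataclass
class BrightnessFit:
    """Gaussian-mixture fit of a spot-brightness distribution.

    Samples with partially bleached or missing quenchers form a second,
    brighter population at the fluorophore-only level; when a reference
    mean is supplied that population is excluded before selecting the mean.
    """

    component_means: np.ndarray
    component_weights: np.ndarray
    component_sds: np.ndarray
    selected_mean: float
    excluded_components: list[int] = field(default_factory=list)


@dataclass
class FFResult:
    """Fluorogenic factor and the quantities it is built from."""

    s_fq: float
    s_f: float
    s_n: float
    b_fq_mol: float
    b_f_mol: float
    b_n_mol: float
    ff: float
    se_ff: float = 0.0


def fit_brightness(photon_counts: np.ndarray,
                   reference_mean: float | None = None,
                   exclusion_window: float = 0.2,
                   seed: int = 0) -> BrightnessFit:
    """Fit a 1- or 2-component Gaussian mixture to spot photon counts.

    The number of components is chosen by BIC. If ``reference_mean`` is
    given, components within ``+-exclusion_window`` (relative) of it are
    treated as unquenched probes and excluded; the remaining component with
    the largest weight supplies ``selected_mean``. The fit is on raw
    counts (not binned frequencies), so it is bin-width independent.
    """
    counts = np.asarray(photon_counts, dtype=float).reshape(-1, 1)
    if len(counts) < 50:
        raise ValueError(f"need >= 50 photon counts, got {len(counts)}")
    if np.ptp(counts) == 0:
        raise ValueError("all photon counts identical; cannot fit a distribution")

    fits = {}
    for k in (1, 2):
        gm = GaussianMixture(n_components=k, random_state=seed, n_init=3)
        gm.fit(counts)
        fits[k] = (gm.bic(counts), gm)
    k_best = min(fits, key=lambda k: fits[k][0])
    gm = fits[k_best][1]
    means = gm.means_.ravel()
    weights = gm.weights_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    order = np.argsort(means)
    means, weights, sds = means[order], weights[order], sds[order]

    excluded: list[int] = []
    if reference_mean is not None and len(means) > 1:
        excluded = [i for i, m in enumerate(means)
                    if abs(m - reference_mean) <= exclusion_window * reference_mean]
        if len(excluded) == len(means):
            excluded = excluded[:-1]  # keep at least one component
    keep = [i for i in range(len(means)) if i not in excluded]
    sel = keep[int(np.argmax(weights[keep]))]
    return BrightnessFit(component_means=means, component_weights=weights,
                         component_sds=sds, selected_mean=float(means[sel]),
                         excluded_components=excluded)


def regress_background(points: list[tuple[float, float]]):
    """OLS of background (photons/px) vs concentration (nM).

    Returns ``(slope, intercept, se_slope, se_intercept)``; the slope is
    the molar background B_mol in photons/px/nM.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (concentration, background) pairs")
    conc, bg = pts[:, 0], pts[:, 1]
    if len(np.unique(conc)) < 2:
        raise ValueError("need at least 2 distinct concentrations for a regression")
    res = stats.linregress(conc, bg)
    n = len(conc)
    if n > 2:
        se_slope, se_int = res.stderr, res.intercept_stderr
    else:
        se_slope = se_int = 0.0
    return float(res.slope), float(res.intercept), float(se_slope), float(se_int)


def compute_ff(s_fq: float, s_f: float, b_fq_mol: float, b_f_mol: float,
               ses: tuple[float, float, float, float] | None = None) -> FFResult:
    """Compute S_N, B_N,mol and FF = S_N / B_N,mol with error propagation.

    ``ses`` are standard errors of (s_fq, s_f, b_fq_mol, b_f_mol); the FF
    standard error follows from first-order propagation of the ratio of
    ratios (relative errors add in quadrature).
    """
    vals = (s_fq, s_f, b_fq_mol, b_f_mol)
    if any(v <= 0 for v in vals):
        raise ValueError("all four inputs must be strictly positive")
    s_n = s_fq / s_f
    b_n = b_fq_mol / b_f_mol
    ff = s_n / b_n
    se_ff = 0.0
    if ses is not None:
        rel2 = sum((se / v) ** 2 for se, v in zip(ses, vals))
        se_ff = ff * np.sqrt(rel2)
    return FFResult(s_fq=s_fq, s_f=s_f, s_n=s_n, b_fq_mol=b_fq_mol,
                    b_f_mol=b_f_mol, b_n_mol=b_n, ff=ff, se_ff=float(se_ff))


def measure_probe_movies(movies_by_conc, brightness_conc: float = 10.0,
                         box_px: int = 7, gradient_threshold: float = 3000.0,
                         seed: int = 0):
    """Measure (mean brightness, molar background) from a concentration series.

    ``movies_by_conc`` maps concentration (nM) to a
    :class:`~fluoropaint.camera.MovieStack`. Spot brightness is taken from
    the movie at ``brightness_conc`` (detection on ADU, fitting in
    photons); backgrounds from every movie enter the linear regression.
    Returns ``(brightness_fit_photons, slope, se_slope, photon_counts)``.
    """
    from .camera import extract_background, fit_spots_in_movie

    if brightness_conc not in movies_by_conc:
        raise ValueError("no movie at the brightness concentration")
    fits = fit_spots_in_movie(movies_by_conc[brightness_conc], box_px,
                              gradient_threshold)
    counts = np.array([f.photons for f in fits])
    bright = fit_brightness(counts, seed=seed)
    pts = [(c, extract_background(m)[0]) for c, m in sorted(movies_by_conc.items())]
    slope, _, se_slope, _ = regress_background(pts)
    return bright, slope, se_slope, counts


def estimate_ff_from_movies(probe_movies, reference_movies,
                            brightness_conc: float = 10.0,
                            box_px: int = 7, gradient_threshold: float = 3000.0,
                            seed: int = 0) -> FFResult:
    """End-to-end FF from probe and reference concentration series.

    The reference brightness is fitted first; any unquenched population in
    the probe's brightness distribution (within 20% of the reference mean)
    is excluded before forming S_FQ.
    """
    from .camera import extract_background, fit_spots_in_movie

    ref_bright, ref_slope, ref_se, _ = measure_probe_movies(
        reference_movies, brightness_conc, box_px, gradient_threshold, seed)

    fits = fit_spots_in_movie(probe_movies[brightness_conc], box_px,
                              gradient_threshold)
    counts = np.array([f.photons for f in fits])
    probe_bright = fit_brightness(counts, reference_mean=ref_bright.selected_mean,
                                  seed=seed)
    pts = [(c, extract_background(m)[0]) for c, m in sorted(probe_movies.items())]
    slope, _, se_slope, _ = regress_background(pts)
    n_p = max(len(counts), 1)
    se_sfq = float(np.std(counts) / np.sqrt(n_p))
    return compute_ff(probe_bright.selected_mean, ref_bright.selected_mean,
                      slope, ref_slope, ses=(se_sfq, 0.0, se_slope, ref_se))
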