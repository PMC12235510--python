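"""Per-cluster Fourier ring correlation (FRC) resolution.

Localizations of a cluster are split at random into two halves, each half
is rendered, and the normalized cross-correlation of their Fourier
transforms is averaged over rings of equal spatial frequency. The curve is
fitted with a mono-exponential decay and the resolution read where the fit
crosses the 1/7 threshold. Random half-splits (averaged over several
seeded draws) are used instead of odd/even frames because binding events
span several frames and would correlate the halves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit

FRC_THRESHOLD = 1.0 / 7.0


@dataclass
class FRCResult:
    """An FRC curve with its mono-exponential fit and threshold crossing."""

    freqs: np.ndarray        # cycles / nm
    correlation: np.ndarray
    amplitude: float = np.nan
    decay_freq: float = np.nan   # f0 of A*exp(-f/f0)
    resolution_nm: float = np.nan
    skipped_reason: str | None = None

    @property
    def resolution_defined(self) -> bool:
        return np.isfinite(self.resolution_nm)


def _render_half(xy_nm: np.ndarray, origin: np.ndarray, shape: tuple[int, int],
                 px_nm: float, sigma_nm: float) -> np.ndarray:
    """Histogram rendering followed by a Gaussian blur (FRC reconstruction)."""
    ij = np.floor((xy_nm - origin) / px_nm).astype(int)
    img = np.zeros(shape)
    np.add.at(img, (ij[:, 1], ij[:, 0]), 1.0)
    return ndimage.gaussian_filter(img, sigma_nm / px_nm)


def frc_curve(xy_nm: np.ndarray, render_px_nm: float = 1.0, n_splits: int = 5,
              sigma_nm: float | None = None, min_locs: int = 20,
              seed: int = 0) -> FRCResult:
    """FRC curve of one cluster, averaged over random half-splits.

    ``sigma_nm`` is the rendering blur (defaults to 3.9 nm when no
    per-localization precision is supplied). Clusters below ``min_locs``
    localizations are skipped with a reason rather than an error.
    """
    xy = np.asarray(xy_nm, dtype=float)
    if len(xy) < min_locs:
        return FRCResult(freqs=np.empty(0), correlation=np.empty(0),
                         skipped_reason=f"{len(xy)} < {min_locs} localizations")
    sigma_nm = 3.9 if sigma_nm is None else sigma_nm
    rng = np.random.default_rng(seed)

    pad = 6 * sigma_nm + 4 * render_px_nm
    origin = xy.min(axis=0) - pad
    extent = xy.max(axis=0) + pad - origin
    n = int(2 ** np.ceil(np.log2(max(extent) / render_px_nm + 1)))
    shape = (n, n)

    f1d = np.fft.fftfreq(n, d=render_px_nm)
    fgrid = np.hypot(f1d[:, None], f1d[None, :])
    rings = np.clip(np.rint(fgrid * n * render_px_nm).astype(int), 0, n // 2)
    n_rings = n // 2 + 1
    freqs = np.arange(n_rings) / (n * render_px_nm)

    curves = np.zeros((n_splits, n_rings))
    for s in range(n_splits):
        half = rng.permutation(len(xy)) < len(xy) // 2
        F1 = np.fft.fft2(_render_half(xy[half], origin, shape, render_px_nm, sigma_nm))
        F2 = np.fft.fft2(_render_half(xy[~half], origin, shape, render_px_nm, sigma_nm))
        num = np.bincount(rings.ravel(), weights=np.real(F1 * np.conj(F2)).ravel(),
                          minlength=n_rings)
        d1 = np.bincount(rings.ravel(), weights=np.abs(F1).ravel() ** 2,
                         minlength=n_rings)
        d2 = np.bincount(rings.ravel(), weights=np.abs(F2).ravel() ** 2,
                         minlength=n_rings)
        with np.errstate(invalid="ignore", divide="ignore"):
            curves[s] = num / np.sqrt(d1 * d2)
    corr = np.nanmean(curves, axis=0)
    good = np.isfinite(corr)
    return FRCResult(freqs=freqs[good], correlation=corr[good])


def frc_resolution(result: FRCResult, threshold: float = FRC_THRESHOLD) -> FRCResult:
    """Fit A*exp(-f/f0) to the FRC curve and read the threshold crossing.

    A is clipped to [0, 1.05]. The resolution is 1/f* where the fitted
    curve equals the threshold, i.e. f* = f0 * ln(A/threshold); it is
    undefined (NaN, reported) when the fit never crosses the threshold or
    does not converge.
    """
    if result.skipped_reason is not None:
        return result
    f, c = result.freqs, result.correlation
    if len(f) < 5:
        raise ValueError("need at least 5 rings to fit the FRC curve")
    sel = f > 0
    f, c = f[sel], c[sel]

    def model(x, a, f0):
        return a * np.exp(-x / f0)

    try:
        popt, _ = curve_fit(model, f, c, p0=[1.0, max(f.max() / 5, 1e-6)],
                            bounds=([0.0, 1e-9], [1.05, np.inf]), maxfev=2000)
        a, f0 = popt
    except Exception:
        result.skipped_reason = "mono-exponential fit did not converge"
        return result
    result.amplitude = float(a)
    result.decay_freq = float(f0)
    if a > threshold:
        fstar = f0 * np.log(a / threshold)
        result.resolution_nm = float(1.0 / fstar)
    return result


def cluster_frc(xy_nm: np.ndarray, render_px_nm: float = 1.0, n_splits: int = 5,
                sigma_nm: float | None = None, min_locs: int = 20,
                seed: int = 0) -> FRCResult:
    """Curve plus resolution in one call."""
    res = frc_curve(xy_nm, render_px_nm, n_splits, sigma_nm, min_locs, seed)
    if res.skipped_reason is None:
        res = frc_resolution(res)
    return res
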