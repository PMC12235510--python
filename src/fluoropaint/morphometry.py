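"""Super-resolved segment morphometry: render, smooth, binarize, skeletonize.

A cluster's localizations are rendered as unit-integral Gaussians on a fine
grid, low-pass filtered (order-1 Butterworth then Gaussian), binarized with
the ISODATA intermeans threshold (discarding overly large components),
thinned to a Hilditch skeleton, and measured: the spine is the longest
skeleton branch and the radius the median distance from spine pixels to the
binary boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.special import erf


@dataclass(frozen=True)
class MorphometryParams:
    """Rendering and filtering settings of the morphometry chain.

    ``butterworth_cutoff`` is in cycles per nm (0.02 = a 50 nm cutoff
    period). Defining it physically keeps the filter invariant to the
    rendering pixel size, and coincides with cycles-per-pixel on the
    common 1 nm rendering grid. ``render_px_nm`` defaults to half the
    rendering sigma so the Gaussian kernel is adequately sampled.
    """

    render_sigma_nm: float = 3.9
    butterworth_order: int = 1
    butterworth_cutoff: float = 0.02
    gauss_sigma_nm: float = 5.85
    max_area_nm2: float = 5000.0
    render_px_nm: float = 1.95

    def __post_init__(self) -> None:
        for nm in ("render_sigma_nm", "butterworth_cutoff", "gauss_sigma_nm",
                   "max_area_nm2", "render_px_nm"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be positive")
        if self.butterworth_order < 1:
            raise ValueError("butterworth_order must be >= 1")
        if self.render_px_nm > self.render_sigma_nm:
            raise ValueError("render_px_nm must not exceed render_sigma_nm")


@dataclass
class SegmentMorphology:
    """Measured geometry of one binarized segment."""

    spine: np.ndarray            # (k, 2) ordered (row, col) pixel path
    spine_length_nm: float
    radius_nm: float
    area_nm2: float
    disconnected_skeleton: bool = False


def render_gaussian(xy_nm: np.ndarray, params: MorphometryParams,
                    pad_nm: float | None = None
                    ) -> tuple[np.ndarray, tuple[float, float]]:
    """Render localizations as a sum of unit-integral Gaussians.

    Each localization contributes a pixel-integrated isotropic Gaussian of
    sigma ``render_sigma_nm``, so the image integrates to the number of
    localizations. Returns the image (rows = y) and the (x, y) origin of
    pixel (0, 0) in nm.
    """
    xy = np.asarray(xy_nm, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or len(xy) == 0:
        raise ValueError("need a nonempty (n, 2) array of nm coordinates")
    px = params.render_px_nm
    if pad_nm is None:
        pad_nm = 4 * (params.render_sigma_nm + params.gauss_sigma_nm) + 4 * px
    x0, y0 = xy[:, 0].min() - pad_nm, xy[:, 1].min() - pad_nm
    w = int(np.ceil((xy[:, 0].max() + pad_nm - x0) / px)) + 1
    h = int(np.ceil((xy[:, 1].max() + pad_nm - y0) / px)) + 1
    img = np.zeros((h, w))
    s2 = params.render_sigma_nm * np.sqrt(2)
    half = int(np.ceil(6 * params.render_sigma_nm / px))
    for x, y in xy:
        cx, cy = (x - x0) / px, (y - y0) / px
        xs = np.arange(max(int(cx) - half, 0), min(int(cx) + half + 1, w))
        ys = np.arange(max(int(cy) - half, 0), min(int(cy) + half + 1, h))
        # pixel i covers [i-0.5, i+0.5] pixel units -> nm via px
        fx = 0.5 * (erf(((xs + 0.5) - cx) * px / s2) - erf(((xs - 0.5) - cx) * px / s2))
        fy = 0.5 * (erf(((ys + 0.5) - cy) * px / s2) - erf(((ys - 0.5) - cy) * px / s2))
        img[np.ix_(ys, xs)] += np.outer(fy, fx)
    return img, (x0, y0)


def smooth(image: np.ndarray, params: MorphometryParams) -> np.ndarray:
    """Low-pass: radial Butterworth (frequency domain) + Gaussian blur.

    The Butterworth magnitude is ``1 / sqrt(1 + (f/f_c)^(2n))`` with ``f_c``
    in cycles/nm; DC gain is exactly 1, so constant images pass unchanged.
    """
    image = np.asarray(image, dtype=float)
    fy = np.fft.fftfreq(image.shape[0], d=params.render_px_nm)[:, None]
    fx = np.fft.rfftfreq(image.shape[1], d=params.render_px_nm)[None, :]
    f = np.hypot(fy, fx)
    h = 1.0 / np.sqrt(1.0 + (f / params.butterworth_cutoff) ** (2 * params.butterworth_order))
    out = np.fft.irfft2(np.fft.rfft2(image) * h, s=image.shape)
    sigma_px = params.gauss_sigma_nm / params.render_px_nm
    return ndimage.gaussian_filter(out, sigma_px, mode="nearest")


def isodata_threshold(image: np.ndarray, tol: float = 1e-8,
                      max_iter: int = 500) -> float:
    """ISODATA iterative intermeans threshold on raw pixel values.

    Starting from the global mean, alternately splits the pixels at the
    current threshold and moves it to the midpoint of the two class means
    until it converges.
    """
    vals = np.asarray(image, dtype=float).ravel()
    if np.ptp(vals) == 0:
        raise ValueError("constant image has no threshold")
    t = vals.mean()
    for _ in range(max_iter):
        lo, hi = vals[vals <= t], vals[vals > t]
        if len(lo) == 0 or len(hi) == 0:
            break
        t_new = 0.5 * (lo.mean() + hi.mean())
        if abs(t_new - t) < tol:
            return float(t_new)
        t = t_new
    return float(t)


def binarize_isodata(image: np.ndarray,
                     max_area_nm2: float | None = None,
                     render_px_nm: float = 1.95) -> np.ndarray:
    """ISODATA binarization with removal of overly large components.

    Connected components (8-connectivity) whose area exceeds
    ``max_area_nm2`` are dropped; pass ``None`` to keep everything.
    """
    t = isodata_threshold(image)
    binary = np.asarray(image) > t
    if max_area_nm2 is not None and binary.any():
        lab, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
        areas = np.bincount(lab.ravel())[1:] * render_px_nm**2
        too_big = np.nonzero(areas > max_area_nm2)[0] + 1
        if len(too_big):
            binary &= ~np.isin(lab, too_big)
    return binary


# ---------------------------------------------------------------------------
# Hilditch thinning

# 8-neighborhood in circular order starting at north
_NEIGH = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def _crossing_number(img: np.ndarray, r: int, c: int) -> int:
    """Number of 0 -> 1 transitions around the 8-neighborhood."""
    seq = [img[r + dr, c + dc] for dr, dc in _NEIGH]
    seq.append(seq[0])
    return sum(1 for a, b in zip(seq[:-1], seq[1:]) if a == 0 and b == 1)


def skeletonize_hilditch(binary: np.ndarray, max_iter: int = 10000) -> np.ndarray:
    """Hilditch thinning of a binary image.

    Sequentially deletes boundary pixels that (i) have 2-6 foreground
    neighbours, (ii) have crossing number 1 (connectivity preserved), and
    (iii, iv) pass the Hilditch north/east neighbour tests, until the image
    stops changing. The result is a 1-pixel-wide, 8-connected skeleton;
    thinning it again is a no-op.
    """
    binary = np.asarray(binary).astype(np.uint8)
    if binary.sum() == 0:
        raise ValueError("empty foreground: nothing to skeletonize")
    img = np.pad(binary, 1)
    for _ in range(max_iter):
        # phase 1: candidates from the pass-start snapshot, so only one
        # boundary layer is peeled per pass and erosion stays symmetric
        snap = img.copy()
        cand = []
        rows, cols = np.nonzero(snap)
        for r, c in zip(rows, cols):
            nb = [snap[r + dr, c + dc] for dr, dc in _NEIGH]
            b = sum(nb)
            if not (2 <= b <= 6):
                continue
            if _crossing_number(snap, r, c) != 1:
                continue
            # north neighbour test: p2*p4*p8 == 0 or A(p2) != 1
            if nb[0] and nb[2] and nb[6] and _crossing_number(snap, r - 1, c) == 1:
                continue
            # east neighbour test: p2*p4*p6 == 0 or A(p4) != 1
            if nb[0] and nb[2] and nb[4] and _crossing_number(snap, r, c + 1) == 1:
                continue
            cand.append((r, c))
        # phase 2: delete sequentially, re-checking connectivity on the
        # live image so simultaneous deletions cannot break the skeleton
        changed = False
        for r, c in cand:
            nb = [img[r + dr, c + dc] for dr, dc in _NEIGH]
            b = sum(nb)
            if not (2 <= b <= 6):
                continue
            if _crossing_number(img, r, c) != 1:
                continue
            img[r, c] = 0
            changed = True
        if not changed:
            break
    return img[1:-1, 1:-1].astype(bool)


# ---------------------------------------------------------------------------
# spine and radius


def _boundary_distances(binary: np.ndarray, pixels: np.ndarray) -> np.ndarray:
    """Distance from each (row, col) pixel to the subpixel binary boundary.

    The boundary is the marching-squares contour of the binary image at
    level 0.5 (vertices spaced <= 1 px, so nearest-vertex distance is an
    accurate stand-in for nearest-segment distance at radii of a few px).
    """
    from scipy.spatial import cKDTree
    from skimage import measure

    contours = measure.find_contours(np.pad(binary.astype(float), 1), 0.5)
    if not contours:
        raise ValueError("binary image has no boundary contour")
    verts = np.vstack(contours) - 1.0  # undo the padding offset
    tree = cKDTree(verts)
    d, _ = tree.query(pixels)
    return d


def _skeleton_graph(skeleton: np.ndarray):
    """Sparse weighted graph over skeleton pixels (8-connected, Euclidean)."""
    pts = np.argwhere(skeleton)
    index = -np.ones(skeleton.shape, dtype=int)
    index[pts[:, 0], pts[:, 1]] = np.arange(len(pts))
    rows, cols, w = [], [], []
    h, wid = skeleton.shape
    for i, (r, c) in enumerate(pts):
        for dr, dc in _NEIGH[:4]:  # half the neighbourhood; graph symmetrized
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < wid and index[rr, cc] >= 0:
                j = index[rr, cc]
                rows += [i, j]
                cols += [j, i]
                w += [np.hypot(dr, dc)] * 2
    g = coo_matrix((w, (rows, cols)), shape=(len(pts), len(pts))).tocsr()
    return pts, g


def _longest_path(pts: np.ndarray, graph) -> np.ndarray:
    """Approximate graph geodesic via double Dijkstra sweeps.

    Ties are broken by lexicographic pixel order so the spine is
    deterministic.
    """
    def farthest(src: int):
        dist, pred = dijkstra(graph, indices=src, return_predecessors=True)
        dist[np.isinf(dist)] = -1
        best = np.max(dist)
        cand = np.nonzero(dist == best)[0]
        cand = cand[np.lexsort((pts[cand, 1], pts[cand, 0]))]
        return int(cand[0]), pred

    start = int(np.lexsort((pts[:, 1], pts[:, 0]))[0])
    a, _ = farthest(start)
    b, pred = farthest(a)
    path = [b]
    while path[-1] != a:
        path.append(int(pred[path[-1]]))
    return pts[path[::-1]]


def measure_segment(binary: np.ndarray, skeleton: np.ndarray,
                    params: MorphometryParams,
                    radius_over_full_skeleton: bool = False) -> SegmentMorphology:
    """Spine length and radius of a binarized segment.

    The spine is the longest simple path between the two most distant
    skeleton pixels (double Dijkstra on the 8-connected pixel graph with
    Euclidean step weights). The radius is the median distance from spine
    pixels to the subpixel boundary contour (marching squares at level
    0.5), which equals the Euclidean distance transform minus half a pixel
    on axis-aligned edges but stays rotation-robust on oblique ones.
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    if skeleton.sum() == 0:
        raise ValueError("empty skeleton")
    pts, graph = _skeleton_graph(skeleton)
    n_comp, comp = connected_components(graph, directed=False)
    disconnected = n_comp > 1
    if disconnected:
        largest = np.argmax(np.bincount(comp))
        keep = comp == largest
        sub = np.zeros_like(skeleton)
        sub[pts[keep, 0], pts[keep, 1]] = True
        pts, graph = _skeleton_graph(sub)

    px = params.render_px_nm
    if len(pts) == 1:
        spine = pts
        length_nm = 0.0
    else:
        spine = _longest_path(pts, graph)
        steps = np.linalg.norm(np.diff(spine, axis=0), axis=1)
        length_nm = float(steps.sum() * px)

    src = pts if radius_over_full_skeleton else spine
    d = _boundary_distances(binary, src.astype(float))
    radius_nm = float(np.median(d) * px)
    area_nm2 = float(binary.sum() * px**2)
    return SegmentMorphology(spine=spine, spine_length_nm=length_nm,
                             radius_nm=radius_nm, area_nm2=area_nm2,
                             disconnected_skeleton=disconnected)


def measure_cluster(xy_nm: np.ndarray, params: MorphometryParams | None = None
                    ) -> SegmentMorphology | None:
    """Full chain on one cluster's localizations (nm coordinates).

    Returns ``None`` when the binarized image is empty (e.g. everything
    removed by the area filter).
    """
    params = params or MorphometryParams()
    img, _ = render_gaussian(xy_nm, params)
    sm = smooth(img, params)
    binary = binarize_isodata(sm, params.max_area_nm2, params.render_px_nm)
    if not binary.any():
        return None
    skel = skeletonize_hilditch(binary)
    return measure_segment(binary, skel, params)
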