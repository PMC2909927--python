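"""Pupil and limbal boundary detection by three competing methods.

Three routes are implemented:

* ``segment_daugman`` — the classical integrodifferential operator: the
  Gaussian-smoothed partial derivative with respect to radius of the mean
  contour intensity is maximized over circles centred at *every* pixel
  (exhaustive), limbal boundary first at a coarse smoothing scale, then the
  pupil inside the detected iris at a fine scale.
* ``segment_masek`` — Canny edge map followed by a circular Hough transform,
  limbal boundary first, then the pupil within the detected disk.
* ``segment_proposed`` — a blob-seeded, pupil-first variant of the
  integrodifferential method: global thresholding and morphological blob
  analysis give a coarse pupil estimate, the integrodifferential operator is
  then applied in reverse order (pupil first, inside a small search window;
  limbal second) so only a few hundred candidate centres are ever evaluated.

Definitions shared by every route
---------------------------------
The contour mean at center ``c`` and integer radius ``r`` is the mean of the
bilinearly interpolated intensity at ``angular_samples`` equally spaced angles
(samples whose 4-pixel interpolation neighborhood leaves the image, or that
fall in a masked angular sector, are excluded).  The radial edge score at
radius ``r`` is the forward difference ``m(r + 1) - m(r)`` smoothed along the
radius axis with a 1-D Gaussian; the detected circle is the global argmax over
candidates x radii, with ties broken by smaller radius, then row-major center
order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d, sobel
from skimage import feature as _skfeature
from skimage import measure as _skmeasure
from skimage import morphology as _skmorph
from skimage.draw import circle_perimeter as _circle_perimeter
from skimage.filters import threshold_multiotsu, threshold_otsu

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import (DegenerateInputError, EstimateFailureError,
                     InvalidArgumentError, SegmentationFailureError)
from .types import Circle, SegmentationResult

__all__ = [
    "SearchSpec",
    "integrodifferential_search",
    "segment_daugman",
    "canny_edge_map",
    "circular_hough",
    "segment_masek",
    "threshold_pupil_estimate",
    "segment_proposed",
]


@dataclass
class SearchSpec:
    """Parameters of one integrodifferential search.

    ``candidate_centers`` is an ``(N, 2)`` integer array of (row, col)
    candidates, or None for the full pixel grid (optionally restricted by the
    boolean ``center_mask``).  ``radius_range`` is inclusive ``(r_min, r_max)``
    in pixels.  ``arc_mask`` lists angular sectors (degrees, inclusive) whose
    samples are skipped.

    ``inner_dark_limit``, when set, disqualifies candidate circles whose
    contour mean two radii inside the edge exceeds the limit — a darkness
    prior used by the blob-seeded pupil search: the pupil boundary's interior
    is dark, which separates it from the equally sharp limbal edge.

    ``min_coverage`` disqualifies contours with fewer than that fraction of
    their (unmasked) samples inside the image; the full segmentations use 1.0
    so a partially clipped contour can never win on its unclipped arc, while
    the default 0.0 keeps the raw operator's exclusion semantics (any valid
    sample counts).
    """

    candidate_centers: np.ndarray | None
    radius_range: tuple[int, int]
    smoothing_sigma: float = 1.0
    angular_samples: int = 128
    arc_mask: tuple = ()
    center_mask: np.ndarray | None = None
    inner_dark_limit: float | None = None
    min_coverage: float = 0.0

    def __post_init__(self):
        r0, r1 = self.radius_range
        if not (0 < r0 < r1):
            raise InvalidArgumentError("require 0 < r_min < r_max")
        if self.angular_samples < 16:
            raise InvalidArgumentError("angular_samples must be >= 16")
        if self.candidate_centers is not None:
            cc = np.atleast_2d(np.asarray(self.candidate_centers, dtype=int))
            if cc.size == 0:
                raise InvalidArgumentError("candidate center set is empty")
            if cc.shape[1] != 2:
                raise InvalidArgumentError("candidate centers must be (N, 2)")
            self.candidate_centers = cc


def _angles(n: int, arc_mask) -> np.ndarray:
    """Equally spaced sample angles, dropping those inside masked sectors."""
    out = []
    for a in range(n):
        theta = 2 * math.pi * a / n
        deg = math.degrees(theta) % 360.0
        if any(lo <= deg <= hi for lo, hi in arc_mask):
            continue
        out.append(theta)
    if not out:
        raise InvalidArgumentError("arc mask excludes every sample angle")
    return np.asarray(out)


def _contour_means_grid(image: np.ndarray, radii, thetas) -> np.ndarray:
    """Contour means for every pixel as candidate center; shape (K, H, W).

    For a fixed (radius, angle) the sample point for all centers is the image
    translated by a common offset, so each term is four weighted slice-shifts
    of the image; validity (the full bilinear neighborhood inside the image)
    is a rectangle of centers.
    """
    H, W = image.shape
    K = len(radii)
    sums = np.zeros((K, H, W))
    cnts = np.zeros((K, H, W))
    for k, r in enumerate(radii):
        for t in thetas:
            dy = -r * math.sin(t)
            dx = r * math.cos(t)
            i0 = math.floor(dy)
            j0 = math.floor(dx)
            fy = dy - i0
            fx = dx - j0
            ry0, ry1 = max(0, -i0), min(H, H - 1 - i0)
            rx0, rx1 = max(0, -j0), min(W, W - 1 - j0)
            if ry0 >= ry1 or rx0 >= rx1:
                continue
            a = image[ry0 + i0:ry1 + i0, rx0 + j0:rx1 + j0]
            b = image[ry0 + i0:ry1 + i0, rx0 + j0 + 1:rx1 + j0 + 1]
            c = image[ry0 + i0 + 1:ry1 + i0 + 1, rx0 + j0:rx1 + j0]
            d = image[ry0 + i0 + 1:ry1 + i0 + 1, rx0 + j0 + 1:rx1 + j0 + 1]
            val = (1 - fy) * ((1 - fx) * a + fx * b) + fy * ((1 - fx) * c + fx * d)
            sums[k, ry0:ry1, rx0:rx1] += val
            cnts[k, ry0:ry1, rx0:rx1] += 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(cnts > 0, sums / np.where(cnts > 0, cnts, 1.0), np.nan), cnts


def _contour_means_points(image: np.ndarray, centers, radii, thetas) -> np.ndarray:
    """Contour means for an explicit candidate list; shape (K, N)."""
    H, W = image.shape
    cy = centers[:, 0].astype(float)
    cx = centers[:, 1].astype(float)
    K, N = len(radii), len(centers)
    sums = np.zeros((K, N))
    cnts = np.zeros((K, N))
    for k, r in enumerate(radii):
        for t in thetas:
            y = cy - r * math.sin(t)
            x = cx + r * math.cos(t)
            y0 = np.floor(y).astype(int)
            x0 = np.floor(x).astype(int)
            valid = (y0 >= 0) & (y0 <= H - 2) & (x0 >= 0) & (x0 <= W - 2)
            ys = np.clip(y0, 0, H - 2)
            xs = np.clip(x0, 0, W - 2)
            fy = y - y0
            fx = x - x0
            val = ((1 - fy) * ((1 - fx) * image[ys, xs] + fx * image[ys, xs + 1])
                   + fy * ((1 - fx) * image[ys + 1, xs] + fx * image[ys + 1, xs + 1]))
            sums[k] += np.where(valid, val, 0.0)
            cnts[k] += valid
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(cnts > 0, sums / np.where(cnts > 0, cnts, 1.0), np.nan), cnts


def integrodifferential_search(image: np.ndarray, spec: SearchSpec,
                               min_score: float = 0.0):
    """Circle maximizing the smoothed radial derivative of the contour mean.

    Returns ``(Circle, score)``; raises :class:`DegenerateInputError` when no
    candidate produces a score above ``min_score`` (e.g. a constant image,
    where every radial derivative is zero).
    """
    image = np.asarray(image, dtype=float)
    r0, r1 = spec.radius_range
    radii = np.arange(r0, r1 + 2)  # means needed one radius past r_max
    thetas = _angles(spec.angular_samples, spec.arc_mask)

    if spec.candidate_centers is None:
        means, cnts = _contour_means_grid(image, radii, thetas)  # (K, H, W)
    else:
        means, cnts = _contour_means_points(image, spec.candidate_centers,
                                            radii, thetas)
    if spec.min_coverage > 0:
        need = max(1, math.ceil(spec.min_coverage * len(thetas)))
        means[cnts < need] = np.nan

    deriv = means[1:] - means[:-1]  # score for radius radii[k]
    bad = ~np.isfinite(deriv)
    deriv = np.where(bad, 0.0, deriv)
    score = gaussian_filter1d(deriv, spec.smoothing_sigma, axis=0, mode="nearest")
    score[bad] = -np.inf
    if spec.inner_dark_limit is not None:
        inner_idx = np.maximum(np.arange(score.shape[0]) - 2, 0)
        inner = means[inner_idx]
        score[~(inner <= spec.inner_dark_limit)] = -np.inf
    if spec.candidate_centers is None and spec.center_mask is not None:
        score[:, ~spec.center_mask] = -np.inf

    flat = score.reshape(score.shape[0], -1)
    idx = int(np.argmax(flat))  # first occurrence: smallest radius, row-major
    k, ci = divmod(idx, flat.shape[1])
    best = float(flat[k, ci])
    if not np.isfinite(best) or best <= min_score:
        raise DegenerateInputError(
            f"no circular edge above score {min_score} in the search range")
    if spec.candidate_centers is None:
        row, col = divmod(ci, image.shape[1])
    else:
        row, col = (int(spec.candidate_centers[ci, 0]),
                    int(spec.candidate_centers[ci, 1]))
    return Circle(float(row), float(col), float(radii[k])), best


# -- Canny + circular Hough (Masek route) -------------------------------------

def canny_edge_map(image: np.ndarray, sigma: float = 2.0,
                   low_thresh: float = 0.2, high_thresh: float = 0.5,
                   mask: np.ndarray | None = None) -> np.ndarray:
    """Canny edge map with hysteresis thresholds given as fractions of the
    maximum gradient magnitude (single-pixel-wide edges)."""
    if not (0 <= low_thresh < high_thresh <= 1):
        raise InvalidArgumentError("require 0 <= low_thresh < high_thresh <= 1")
    image = np.asarray(image, dtype=float)
    sm = gaussian_filter(image, sigma)
    gmag = np.hypot(sobel(sm, axis=0), sobel(sm, axis=1))
    if mask is not None:
        gmax = gmag[mask].max() if mask.any() else 0.0
    else:
        gmax = gmag.max()
    if gmax == 0.0:
        return np.zeros_like(image, dtype=bool)
    return _skfeature.canny(image, sigma=sigma,
                            low_threshold=low_thresh * gmax,
                            high_threshold=high_thresh * gmax,
                            mask=mask)


def circular_hough(edges: np.ndarray, radius_range: tuple[int, int]):
    """Circular Hough transform: each edge pixel votes a circle of centres.

    Each edge pixel adds one vote to every center on the midpoint-rasterized
    circle of each radius around it; the accumulator maximum locates the
    boundary.  Returns ``(Circle, votes)`` for the global maximum; ties are
    broken by smaller radius, then row-major center order.  Votes are the
    number of edge pixels lying on the rasterized circle around the winning
    center.
    """
    edges = np.asarray(edges, dtype=bool)
    if not edges.any():
        raise InvalidArgumentError("edge map contains no edge pixels")
    r0, r1 = radius_range
    if not (0 < r0 < r1):
        raise InvalidArgumentError("require 0 < r_min < r_max")
    radii = np.arange(r0, r1 + 1)
    H, W = edges.shape
    ys, xs = np.nonzero(edges)
    acc = np.zeros((len(radii), H, W), dtype=np.int64)
    for k, r in enumerate(radii):
        dr, dc = _circle_perimeter(0, 0, int(r))
        # the rasterizer may repeat pixels at octant joins; one vote per center
        dr, dc = np.unique(np.stack([dr, dc], axis=1), axis=0).T
        rows = ys[:, None] + dr[None, :]
        cols = xs[:, None] + dc[None, :]
        keep = (rows >= 0) & (rows < H) & (cols >= 0) & (cols < W)
        np.add.at(acc[k], (rows[keep], cols[keep]), 1)
    flat = acc.reshape(len(radii), -1)
    idx = int(np.argmax(flat))
    k, ci = divmod(idx, flat.shape[1])
    row, col = divmod(ci, edges.shape[1])
    votes = int(round(float(flat[k, ci])))
    return Circle(float(row), float(col), float(radii[k])), votes


# -- blob-seeded pupil estimate (proposed route) ------------------------------

def _dark_threshold(image: np.ndarray) -> float:
    """Cut separating the darkest intensity class (the pupil).

    A 3-class multi-Otsu keeps the pupil apart even when iris and sclera form
    two further modes; plain Otsu is the fallback for images with too few
    distinct gray levels.
    """
    try:
        return float(threshold_multiotsu(image, classes=3)[0])
    except ValueError:
        return float(threshold_otsu(image))

def threshold_pupil_estimate(image: np.ndarray,
                             config: PipelineConfig = DEFAULT_CONFIG):
    """Coarse pupil circle from global thresholding and blob analysis.

    Dark pixels are isolated with a 3-class multi-Otsu threshold (the lowest
    cut, so the darkest class — the pupil — separates even when the iris and
    sclera form two further modes; plain Otsu is the fallback for images with
    too few gray levels).  Morphological opening then closing with a disk
    removes eyelash strands and fills specular holes, and the connected dark
    component with the largest area among those whose centroid lies in the
    central portion of the image is taken as the pupil blob.  Returns
    ``(Circle(centroid, sqrt(area / pi)), area)``.
    """
    image = np.asarray(image, dtype=float)
    if image.max() == image.min():
        raise EstimateFailureError("constant image has no dark blob")
    dark = image <= _dark_threshold(image)
    selem = _skmorph.disk(config.morph_radius)
    dark = _skmorph.closing(_skmorph.opening(dark, selem), selem)
    labels = _skmeasure.label(dark)
    H, W = image.shape
    lo = (1 - config.central_fraction) / 2
    hi = 1 - lo
    best = None
    for region in _skmeasure.regionprops(labels):
        cy, cx = region.centroid
        if not (lo * H <= cy <= hi * H and lo * W <= cx <= hi * W):
            continue
        if best is None or region.area > best.area:
            best = region
    if best is None or best.area < 4:
        raise EstimateFailureError("no central dark blob found")
    radius = math.sqrt(best.area / math.pi)
    cy, cx = best.centroid
    return Circle(cy, cx, radius), int(best.area)


# -- full segmentations -------------------------------------------------------

def _clip_containment(pupil: Circle, limbal: Circle, warnings: list) -> Circle:
    """Shrink the pupil radius if the pupil disk leaks out of the limbal disk."""
    slack = limbal.radius - (pupil.center_distance(limbal) + pupil.radius)
    if slack < -1.0:
        new_r = max(1.0, limbal.radius - pupil.center_distance(limbal))
        warnings.append(
            f"pupil disk exceeded limbal disk by {-slack:.1f} px; radius clipped")
        return Circle(pupil.row, pupil.col, new_r)
    return pupil


def _limbal_radius_range(image: np.ndarray, config: PipelineConfig):
    m = min(image.shape)
    return (max(2, round(config.limbal_min_frac * m)),
            round(config.limbal_max_frac * m))


def _pupil_radius_range(limbal_radius: float, config: PipelineConfig):
    return (max(2, round(config.pupil_min_frac * limbal_radius)),
            max(3, round(config.pupil_max_frac * limbal_radius)))


def _require_size(image: np.ndarray):
    if image.shape[0] < 64 or image.shape[1] < 64:
        raise InvalidArgumentError("image must be at least 64x64")


def segment_daugman(image: np.ndarray,
                    config: PipelineConfig = DEFAULT_CONFIG) -> SegmentationResult:
    """Exhaustive integrodifferential segmentation, limbal boundary first.

    The limbal search is exhaustive over every pixel at the coarse smoothing
    scale (skipping eyelid sectors); the pupil search is restricted to centers
    inside the detected limbal disk with radii a fraction of its radius, at
    the fine scale.
    """
    image = np.asarray(image, dtype=float)
    _require_size(image)
    warnings: list[str] = []
    try:
        limbal, lscore = integrodifferential_search(
            image,
            SearchSpec(None, _limbal_radius_range(image, config),
                       smoothing_sigma=config.sigma_coarse,
                       angular_samples=config.angles_limbal,
                       arc_mask=config.eyelid_sectors,
                       min_coverage=1.0),
            min_score=config.min_edge_score)
    except DegenerateInputError as exc:
        raise SegmentationFailureError("limbal", str(exc)) from exc

    # pupil: centers inside the limbal disk; crop to its bounding box for speed
    H, W = image.shape
    rmin, rmax = _pupil_radius_range(limbal.radius, config)
    margin = rmax + 2
    top = max(0, int(limbal.row - limbal.radius - margin))
    bot = min(H, int(limbal.row + limbal.radius + margin) + 1)
    left = max(0, int(limbal.col - limbal.radius - margin))
    right = min(W, int(limbal.col + limbal.radius + margin) + 1)
    sub = image[top:bot, left:right]
    yy, xx = np.mgrid[top:bot, left:right]
    disk = np.hypot(yy - limbal.row, xx - limbal.col) <= limbal.radius
    try:
        pupil, pscore = integrodifferential_search(
            sub,
            SearchSpec(None, (rmin, rmax),
                       smoothing_sigma=config.sigma_fine,
                       angular_samples=config.angles_pupil,
                       center_mask=disk, min_coverage=1.0),
            min_score=config.min_edge_score)
    except DegenerateInputError as exc:
        raise SegmentationFailureError("pupil", str(exc)) from exc
    pupil = Circle(pupil.row + top, pupil.col + left, pupil.radius)
    pupil = _clip_containment(pupil, limbal, warnings)
    return SegmentationResult(pupil, limbal, "daugman",
                              pupil_score=pscore, limbal_score=lscore,
                              warnings=warnings,
                              details={"n_limbal_candidates": H * W,
                                       "n_pupil_candidates": int(disk.sum())})


def segment_masek(image: np.ndarray,
                  config: PipelineConfig = DEFAULT_CONFIG) -> SegmentationResult:
    """Canny + circular Hough segmentation, limbal boundary first."""
    image = np.asarray(image, dtype=float)
    _require_size(image)
    warnings: list[str] = []
    edges = canny_edge_map(image, config.canny_sigma,
                           config.canny_low, config.canny_high)
    if not edges.any():
        raise SegmentationFailureError("limbal", "edge map is empty")
    limbal, lvotes = circular_hough(edges, _limbal_radius_range(image, config))

    H, W = image.shape
    rmin, rmax = _pupil_radius_range(limbal.radius, config)
    top = max(0, int(limbal.row - limbal.radius))
    bot = min(H, int(limbal.row + limbal.radius) + 1)
    left = max(0, int(limbal.col - limbal.radius))
    right = min(W, int(limbal.col + limbal.radius) + 1)
    sub = image[top:bot, left:right]
    yy, xx = np.mgrid[top:bot, left:right]
    disk = np.hypot(yy - limbal.row, xx - limbal.col) <= limbal.radius - 1
    inner = canny_edge_map(sub, config.canny_sigma_fine,
                           config.canny_low, config.canny_high, mask=disk)
    if not inner.any():
        raise SegmentationFailureError("pupil", "no edges inside the limbal disk")
    rmax = min(rmax, max(rmin + 1, min(sub.shape) // 2 - 1))
    pupil, pvotes = circular_hough(inner, (rmin, rmax))
    pupil = Circle(pupil.row + top, pupil.col + left, pupil.radius)
    pupil = _clip_containment(pupil, limbal, warnings)
    return SegmentationResult(pupil, limbal, "masek",
                              pupil_score=float(pvotes), limbal_score=float(lvotes),
                              warnings=warnings)


def segment_proposed(image: np.ndarray,
                     config: PipelineConfig = DEFAULT_CONFIG) -> SegmentationResult:
    """Blob-seeded integrodifferential segmentation, pupil boundary first.

    The thresholded blob estimate ``(c0, r0)`` seeds a ``search_window`` x
    ``search_window`` grid of candidate centers (spanning offsets -5..+4 for
    the default window of 10) with radii in ``[0.8 r0, 1.2 r0]`` at the fine
    smoothing scale; the limbal boundary is then searched on a second window
    centered on the found pupil center at the coarse scale, skipping eyelid
    sectors.
    """
    image = np.asarray(image, dtype=float)
    _require_size(image)
    warnings: list[str] = []
    try:
        est, _area = threshold_pupil_estimate(image, config)
    except EstimateFailureError as exc:
        raise SegmentationFailureError("estimate", str(exc)) from exc

    w = config.search_window
    off = np.arange(-(w // 2), w - w // 2)  # -5..+4 for w = 10

    def window(row, col):
        rows = np.clip(int(round(row)) + off, 0, image.shape[0] - 1)
        cols = np.clip(int(round(col)) + off, 0, image.shape[1] - 1)
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        return np.column_stack([rr.ravel(), cc.ravel()])

    pupil_centers = window(est.row, est.col)
    rmin = max(2, round(0.8 * est.radius))
    rmax = max(rmin + 1, round(1.2 * est.radius))
    try:
        pupil, pscore = integrodifferential_search(
            image,
            SearchSpec(pupil_centers, (rmin, rmax),
                       smoothing_sigma=config.sigma_fine,
                       angular_samples=config.angles_pupil,
                       inner_dark_limit=_dark_threshold(image),
                       min_coverage=1.0),
            min_score=config.min_edge_score)
    except DegenerateInputError as exc:
        raise SegmentationFailureError("pupil", str(exc)) from exc

    limbal_centers = window(pupil.row, pupil.col)
    # pupil-first advantage: the limbal radius must exceed the found pupil
    # radius, so the pupil/iris edge can never win the limbal search
    lmin, lmax = _limbal_radius_range(image, config)
    lmin = max(lmin, int(round(1.15 * pupil.radius)) + 2)
    if lmin >= lmax:
        raise SegmentationFailureError(
            "limbal", "no room for a limbal radius above the pupil radius")
    try:
        limbal, lscore = integrodifferential_search(
            image,
            SearchSpec(limbal_centers, (lmin, lmax),
                       smoothing_sigma=config.sigma_coarse,
                       angular_samples=config.angles_limbal,
                       arc_mask=config.eyelid_sectors,
                       min_coverage=1.0),
            min_score=config.min_edge_score)
    except DegenerateInputError as exc:
        raise SegmentationFailureError("limbal", str(exc)) from exc
    pupil = _clip_containment(pupil, limbal, warnings)
    return SegmentationResult(pupil, limbal, "proposed",
                              pupil_score=pscore, limbal_score=lscore,
                              warnings=warnings,
                              details={"n_pupil_candidates": len(pupil_centers),
                                       "n_limbal_candidates": len(limbal_centers),
                                       "estimate": est})
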