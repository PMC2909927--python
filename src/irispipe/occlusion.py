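"""Occlusion (noise-mask) detection: specular reflections, eyelashes, eyelids.

The detected pixels form the noise mask that the normalization and encoding
stages exclude from the iris code, and matching excludes from the Hamming
distance.  True = occluded.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter, sobel
from skimage import morphology as _skmorph

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import InvalidArgumentError
from .types import SegmentationResult

__all__ = ["detect_specular_and_eyelash", "detect_eyelids", "combine_masks"]


def _annulus_mask(shape, seg: SegmentationResult) -> np.ndarray:
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    d_p = np.hypot(yy - seg.pupil.row, xx - seg.pupil.col)
    d_l = np.hypot(yy - seg.limbal.row, xx - seg.limbal.col)
    return (d_l <= seg.limbal.radius) & (d_p > seg.pupil.radius)


def detect_specular_and_eyelash(image: np.ndarray,
                                bright_thresh: float = 0.97,
                                dark_thresh: float = 0.05,
                                seg: SegmentationResult | None = None) -> np.ndarray:
    """Threshold-based mask of specular highlights and (dark) eyelash pixels.

    Pixels at or above ``bright_thresh`` are specular and are dilated by 2 px
    to cover halos.  Pixels at or below ``dark_thresh`` are eyelash candidates
    but are masked only inside the iris annulus (requires ``seg``), so the
    pupil itself is never flagged.
    """
    if not (0 <= dark_thresh < bright_thresh <= 1):
        raise InvalidArgumentError("require 0 <= dark_thresh < bright_thresh <= 1")
    image = np.asarray(image, dtype=float)
    specular = image >= bright_thresh
    if specular.any():
        specular = _skmorph.dilation(specular, _skmorph.disk(2))
    mask = specular
    if seg is not None:
        lash = (image <= dark_thresh) & _annulus_mask(image.shape, seg)
        mask = mask | lash
    return mask


def detect_eyelids(image: np.ndarray, seg: SegmentationResult,
                   config: PipelineConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Horizontal-line eyelid mask from the texture-energy profile of the disk.

    Eyelid skin is smooth while the iris is strongly textured, so inside the
    limbal disk (pupil and a thin limbus rim excluded) the mean gradient
    magnitude per row drops sharply where a lid covers the eye.  Starting from
    the top (bottom) of the disk, the run of rows whose gradient energy stays
    below a fraction of the disk's median row energy is taken as lid; the
    horizontal boundary line is the last row of that run and everything above
    the upper line (below the lower line) is masked.  Zones without such a
    low-texture run — an eye without lids — contribute nothing.
    """
    image = np.asarray(image, dtype=float)
    H, W = image.shape
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    d_l = np.hypot(yy - seg.limbal.row, xx - seg.limbal.col)
    d_p = np.hypot(yy - seg.pupil.row, xx - seg.pupil.col)
    interior = (d_l <= seg.limbal.radius - 3) & (d_p > seg.pupil.radius + 3)

    sm = gaussian_filter(image, 1.0)
    gmag = np.hypot(sobel(sm, axis=0), sobel(sm, axis=1))
    counts = interior.sum(axis=1)
    with np.errstate(invalid="ignore"):
        row_energy = np.where(counts > 0,
                              (gmag * interior).sum(axis=1) / np.maximum(counts, 1),
                              np.nan)
    rows = np.flatnonzero(counts >= 8)
    if rows.size == 0:
        return np.zeros((H, W), dtype=bool)
    baseline = float(np.nanmedian(row_energy[rows]))
    mask = np.zeros((H, W), dtype=bool)
    if baseline <= 0:
        return mask
    smooth = row_energy < 0.3 * baseline
    zone = max(3, int(2 * seg.limbal.radius / 3))  # upper/lower thirds of the disk
    for scan, above in ((rows[:zone], True), (rows[::-1][:zone], False)):
        run_end = None
        for r in scan:
            if smooth[r]:
                run_end = r
            else:
                break
        if run_end is None:
            continue
        if above:
            mask[:run_end + 1, :] = True
        else:
            mask[run_end:, :] = True
    return mask


def combine_masks(*masks: np.ndarray) -> np.ndarray:
    """Boolean union of noise masks (idempotent)."""
    out = np.zeros_like(np.asarray(masks[0], dtype=bool))
    for m in masks:
        out |= np.asarray(m, dtype=bool)
    return out
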