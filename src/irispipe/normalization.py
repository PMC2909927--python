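"""Rubber-sheet normalization: iris annulus -> fixed dimensionless polar grid.

The homogeneous rubber-sheet model remaps the iris from Cartesian coordinates
to a doubly dimensionless, non-concentric polar coordinate system: for angular
index ``j`` (angle ``theta = 2*pi*j / angular_res``) and radial index ``i``
(dimensionless ``rho = (i + 0.5) / radial_res``) the sample point is the
linear interpolation between the pupil-boundary point and the limbal-boundary
point at that angle, each taken on its own circle.  The output dimensions are
fixed regardless of pupil size, which is what makes iris codes comparable
across dilation, scale and camera distance.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidArgumentError
from .types import PolarIris, SegmentationResult

__all__ = ["rubber_sheet"]


def rubber_sheet(image: np.ndarray, seg: SegmentationResult,
                 noise_mask: np.ndarray | None = None,
                 radial_res: int = 20, angular_res: int = 240) -> PolarIris:
    """Remap the segmented iris annulus to a ``radial_res x angular_res`` grid.

    Intensities are bilinearly interpolated; the validity mask is cleared for
    samples whose interpolation neighborhood leaves the image or whose nearest
    pixel is flagged in ``noise_mask``.
    """
    if radial_res < 4 or angular_res < 4:
        raise InvalidArgumentError("polar resolutions must be >= 4")
    if not isinstance(seg, SegmentationResult):
        raise InvalidArgumentError("seg must be a SegmentationResult")
    image = np.asarray(image, dtype=float)
    H, W = image.shape

    theta = 2 * np.pi * np.arange(angular_res) / angular_res
    u_row, u_col = -np.sin(theta), np.cos(theta)
    p_row = seg.pupil.row + seg.pupil.radius * u_row
    p_col = seg.pupil.col + seg.pupil.radius * u_col
    l_row = seg.limbal.row + seg.limbal.radius * u_row
    l_col = seg.limbal.col + seg.limbal.radius * u_col

    rho = ((np.arange(radial_res) + 0.5) / radial_res)[:, None]
    rows = (1 - rho) * p_row[None, :] + rho * l_row[None, :]
    cols = (1 - rho) * p_col[None, :] + rho * l_col[None, :]

    y0 = np.floor(rows).astype(int)
    x0 = np.floor(cols).astype(int)
    valid = (y0 >= 0) & (y0 <= H - 2) & (x0 >= 0) & (x0 <= W - 2)
    ys = np.clip(y0, 0, H - 2)
    xs = np.clip(x0, 0, W - 2)
    fy = rows - y0
    fx = cols - x0
    vals = ((1 - fy) * ((1 - fx) * image[ys, xs] + fx * image[ys, xs + 1])
            + fy * ((1 - fx) * image[ys + 1, xs] + fx * image[ys + 1, xs + 1]))
    vals = np.where(valid, vals, 0.0)

    if noise_mask is not None:
        noise_mask = np.asarray(noise_mask, dtype=bool)
        ni = np.clip(np.rint(rows).astype(int), 0, H - 1)
        nj = np.clip(np.rint(cols).astype(int), 0, W - 1)
        valid &= ~noise_mask[ni, nj]

    return PolarIris(vals, valid, seg)
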