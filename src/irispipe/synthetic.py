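"""Synthetic eye images with exact ground truth.

The generator produces grayscale eye images with the statistical structure a
slit-lamp iris photograph exhibits: a dark near-circular pupil, a textured iris
annulus, a bright sclera, non-concentric pupil and limbal circles, eyelid and
specular occlusions, and controlled pupil dilation of a fixed iris identity.

The iris texture is defined *in the normalized polar domain* (radial x angular
grid) and rendered into the image by inverting the rubber-sheet mapping used by
:func:`irispipe.normalization.rubber_sheet`.  Rendering an identity at two
pupil sizes therefore produces images whose normalized remaps agree up to
resampling error — the property that makes dilation experiments meaningful
with exact ground truth.

All randomness flows through explicit integer seeds; a list of
:class:`EyeSpec` objects fully determines a dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import InvalidArgumentError
from .types import Circle, GroundTruth

__all__ = [
    "EyeSpec",
    "IrisTexture",
    "generate_iris_texture",
    "render_eye",
    "generate_dilation_series",
]

# Intensity painted for eyelid skin; between iris band and sclera so the lid
# boundary carries a clear gradient but is darker than sclera.
EYELID_INTENSITY = 0.78


@dataclass(frozen=True)
class EyeSpec:
    """Complete recipe for one synthetic eye image.

    ``mean_intensity`` is the (pupil, iris, sclera) triplet and must be
    strictly increasing — the contrast ordering both boundary detectors
    assume (the pupil/iris transition is fainter than iris/sclera).
    ``specular_spots`` is a sequence of ``((row, col), radius, intensity)``.
    """

    height: int
    width: int
    pupil_center: tuple[float, float]
    pupil_radius: float
    limbal_center: tuple[float, float]
    limbal_radius: float
    texture_seed: int = 0
    mean_intensity: tuple[float, float, float] = (0.1, 0.5, 0.9)
    noise_sd: float = 0.02
    eyelid_coverage: float = 0.0
    specular_spots: tuple = ()
    noise_seed: int = 0

    def __post_init__(self):
        if self.height < 8 or self.width < 8:
            raise InvalidArgumentError("image must be at least 8x8")
        if not (0 < self.pupil_radius < self.limbal_radius):
            raise InvalidArgumentError("require 0 < pupil_radius < limbal_radius")
        d = math.hypot(self.pupil_center[0] - self.limbal_center[0],
                       self.pupil_center[1] - self.limbal_center[1])
        if d + self.pupil_radius > self.limbal_radius:
            raise InvalidArgumentError("pupil disk must lie inside the limbal disk")
        p, i, s = self.mean_intensity
        if not (0 <= p < i < s <= 1):
            raise InvalidArgumentError(
                "mean intensities must satisfy pupil < iris < sclera in [0, 1]")
        if not (0 <= self.eyelid_coverage < 1):
            raise InvalidArgumentError("eyelid_coverage must lie in [0, 1)")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")

    @property
    def pupil(self) -> Circle:
        return Circle(self.pupil_center[0], self.pupil_center[1], self.pupil_radius)

    @property
    def limbal(self) -> Circle:
        return Circle(self.limbal_center[0], self.limbal_center[1], self.limbal_radius)


@dataclass(frozen=True)
class IrisTexture:
    """Identity-bearing intensity pattern on the normalized polar grid."""

    values: np.ndarray  # (radial_res, angular_res), float in [0, 1]
    seed: int

    @property
    def radial_res(self) -> int:
        return self.values.shape[0]

    @property
    def angular_res(self) -> int:
        return self.values.shape[1]


def generate_iris_texture(seed: int, radial_res: int = 20, angular_res: int = 240,
                          blur_sigma: float = 1.5) -> IrisTexture:
    """Band-limited pseudo-random iris texture, deterministic in ``seed``.

    Gaussian white noise on the polar grid is blurred (wrap-around along the
    angular axis, since the ring is closed) so no single-pixel detail remains;
    the field is then standardized to mean 0.5, sd 0.12 and clipped to
    [0.05, 0.95].  Distinct seeds give essentially uncorrelated textures.
    """
    if radial_res < 4 or angular_res < 4:
        raise InvalidArgumentError("texture resolutions must be >= 4")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((radial_res, angular_res))
    sm = gaussian_filter(noise, blur_sigma, mode=("nearest", "wrap"))
    sm = (sm - sm.mean()) / sm.std()
    vals = np.clip(0.5 + 0.12 * sm, 0.05, 0.95)
    return IrisTexture(vals, seed)


# -- rubber-sheet inversion ---------------------------------------------------

def _solve_polar_coords(rows, cols, spec: EyeSpec, n_iter: int = 30):
    """Invert the non-concentric rubber-sheet map for the given pixel positions.

    A point x satisfies ``x = (1 - rho) * p(theta) + rho * l(theta)`` where
    ``p``/``l`` are the pupil/limbal boundary points at common angle ``theta``.
    Writing d = limbal_center - pupil_center this becomes
    ``x - c_p = (r_p + rho (r_l - r_p)) u(theta) + rho d``, solved by fixed
    point: given rho, the direction is ``u = normalize(x - c_p - rho d)``;
    given u, rho follows by least squares.  Converges fast since |d| << r.
    """
    pr, pc = spec.pupil_center
    lr, lc = spec.limbal_center
    d_row, d_col = lr - pr, lc - pc
    rp, dr = spec.pupil_radius, spec.limbal_radius - spec.pupil_radius
    xr = rows - pr
    xc = cols - pc
    rho = np.zeros_like(xr)
    for _ in range(n_iter):
        v_row = xr - rho * d_row
        v_col = xc - rho * d_col
        norm = np.hypot(v_row, v_col)
        norm = np.where(norm > 1e-12, norm, 1.0)
        u_row, u_col = v_row / norm, v_col / norm
        q_row = d_row + dr * u_row
        q_col = d_col + dr * u_col
        denom = q_row ** 2 + q_col ** 2
        rho = ((xr - rp * u_row) * q_row + (xc - rp * u_col) * q_col) / denom
        rho = np.clip(rho, 0.0, 1.5)
    theta = np.arctan2(-u_row, u_col) % (2 * np.pi)
    return np.clip(rho, 0.0, 1.0), theta


def _sample_texture(texture: IrisTexture, rho, theta):
    """Bilinear texture lookup at dimensionless (rho, theta); wraps the angle."""
    R, A = texture.values.shape
    i_f = np.clip(rho * R - 0.5, 0.0, R - 1.0)
    j_f = (theta / (2 * np.pi)) * A
    i0 = np.floor(i_f).astype(int)
    i1 = np.minimum(i0 + 1, R - 1)
    fi = i_f - i0
    j0 = np.floor(j_f).astype(int) % A
    j1 = (j0 + 1) % A
    fj = j_f - np.floor(j_f)
    t = texture.values
    return ((1 - fi) * ((1 - fj) * t[i0, j0] + fj * t[i0, j1])
            + fi * ((1 - fj) * t[i1, j0] + fj * t[i1, j1]))


# -- eyelids ------------------------------------------------------------------

def _lid_region(spec: EyeSpec, depth: float, top: bool, yy, xx):
    """Pixels occluded by a parabolic lid of vertex ``depth`` px into the limbal disk."""
    lr, lc = spec.limbal_center
    r = spec.limbal_radius
    x2 = ((xx - lc) / r) ** 2
    if top:
        boundary = (lr - r + depth) - depth * x2
        return yy <= boundary
    boundary = (lr + r - depth) + depth * x2
    return yy >= boundary


def _fit_lid_depth(spec: EyeSpec, target_frac: float, top: bool, yy, xx, annulus):
    """Bisect the vertex depth so the lid covers ``target_frac`` of the annulus."""
    n_ann = annulus.sum()
    if target_frac <= 0 or n_ann == 0:
        return None
    lo, hi = 0.0, 2.0 * spec.limbal_radius
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        frac = (annulus & _lid_region(spec, mid, top, yy, xx)).sum() / n_ann
        if frac < target_frac:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# -- rendering ----------------------------------------------------------------

def render_eye(spec: EyeSpec, texture: IrisTexture) -> tuple[np.ndarray, GroundTruth]:
    """Render one eye image and its exact ground truth.

    The iris annulus takes intensities from ``texture`` sampled at each pixel's
    dimensionless polar coordinate (the inverse of the rubber-sheet map); the
    pupil and sclera are filled at their mean intensities; Gaussian noise of sd
    ``spec.noise_sd`` is added and clipped; eyelid and specular occlusions are
    painted last and recorded in the occlusion mask.

    With the default iris mean intensity of 0.5 the annulus carries the texture
    values verbatim, so ``rubber_sheet`` on the output (with the true circles)
    recovers the texture up to resampling error.
    """
    p_mean, i_mean, s_mean = spec.mean_intensity
    H, W = spec.height, spec.width
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    d_p = np.hypot(yy - spec.pupil_center[0], xx - spec.pupil_center[1])
    d_l = np.hypot(yy - spec.limbal_center[0], xx - spec.limbal_center[1])
    pupil_mask = d_p <= spec.pupil_radius
    annulus = (d_l <= spec.limbal_radius) & ~pupil_mask

    img = np.full((H, W), s_mean)
    if annulus.any():
        rho, theta = _solve_polar_coords(yy[annulus], xx[annulus], spec)
        tex = _sample_texture(texture, rho, theta)
        img[annulus] = np.clip(tex + (i_mean - 0.5), 0.0, 1.0)
    img[pupil_mask] = p_mean

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.noise_seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    occl = np.zeros((H, W), dtype=bool)
    if spec.eyelid_coverage > 0:
        # two-thirds of the target coverage on the upper lid, one third below
        for top, frac in ((True, spec.eyelid_coverage * 2 / 3),
                          (False, spec.eyelid_coverage / 3)):
            depth = _fit_lid_depth(spec, frac, top, yy, xx, annulus)
            if depth is not None:
                region = _lid_region(spec, depth, top, yy, xx)
                img[region] = EYELID_INTENSITY
                occl |= region
    for (srow, scol), sr, sval in spec.specular_spots:
        disk = np.hypot(yy - srow, xx - scol) <= sr
        img[disk] = np.clip(sval, 0.0, 1.0)
        occl |= disk

    truth = GroundTruth(spec.pupil, spec.limbal, occl)
    return img, truth


def generate_dilation_series(texture: IrisTexture, base_spec: EyeSpec,
                             pupil_radii, seed: int,
                             fresh_noise: bool = True):
    """Render one image per pupil radius with the same iris identity.

    Each image reuses ``texture`` (and the base spec's geometry) with only the
    pupil radius changed; with ``fresh_noise`` each image gets its own noise
    realization derived from ``seed``, otherwise all share ``seed`` exactly.
    """
    out = []
    for i, r in enumerate(pupil_radii):
        if r >= base_spec.limbal_radius:
            raise InvalidArgumentError(
                f"pupil radius {r} must be < limbal radius {base_spec.limbal_radius}")
        spec = replace(base_spec, pupil_radius=float(r),
                       noise_seed=(seed + i) if fresh_noise else seed)
        out.append(render_eye(spec, texture))
    return out
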