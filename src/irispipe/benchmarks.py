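"""Reference synthetic benchmarks exercising the whole pipeline.

These functions define the package's standard study conditions — the image
geometry, texture statistics, noise and occlusion levels used by the test
suite and by ``scripts/acceptance.py`` — so every reported number is
recomputable from a seed.

Conditions
----------
* Segmentation benchmark: 192x192 images, limbal radius 72 px with the center
  jittered up to 3 px, pupil radii uniform in [20, 60] px, pupil center offset
  up to 10 px from the limbal center, additive noise sd 0.02, no occlusions.
* Identity benchmark: 20 identities x 3 images, 160x160, limbal radius 60 px,
  pupil radii {26, 30, 34} px across the three captures, eyelid coverage 0.15,
  one specular spot, noise sd 0.02; the full pipeline (proposed segmentation,
  occlusion masking, normalization, encoding) runs per image and all pairs are
  matched.
* Dilation benchmark: one identity; a gallery of 68 non-dilated captures
  (pupil diameter 3.2-4.0 mm) and 7 dilated probes — 3 at 4.6 mm, 3 at
  6.3 mm, 1 at 7.4 mm — at the declared analog scale of 10 px per mm, giving
  204 / 204 / 68 gallery x probe comparisons per level.
"""

from __future__ import annotations

import math

import numpy as np

from .config import DEFAULT_CONFIG, PipelineConfig
from .encoding import encode
from .errors import SegmentationFailureError
from .evaluation import (DilationTable, HDSeparation, classify_segmentation,
                         dilation_sweep, hd_distributions, success_table)
from .matching import match
from .normalization import rubber_sheet
from .occlusion import combine_masks, detect_eyelids, detect_specular_and_eyelash
from .segmentation import segment_daugman, segment_masek, segment_proposed
from .synthetic import EyeSpec, generate_iris_texture, render_eye
from .types import IrisCode

__all__ = [
    "benchmark_eye_spec",
    "run_segmentation_benchmark",
    "process_image",
    "run_identity_benchmark",
    "run_dilation_benchmark",
]


def benchmark_eye_spec(seed: int, size: int = 192, limbal_radius: float = 72.0,
                       noise_sd: float = 0.02) -> EyeSpec:
    """One segmentation-benchmark eye: geometry drawn from ``seed``."""
    rng = np.random.default_rng(seed)
    c = size / 2
    l_row = c + rng.uniform(-3, 3)
    l_col = c + rng.uniform(-3, 3)
    pupil_r = rng.uniform(20, 60)
    max_off = min(10.0, limbal_radius - pupil_r - 1)
    off = rng.uniform(0, max(0.0, max_off))
    ang = rng.uniform(0, 2 * math.pi)
    return EyeSpec(
        height=size, width=size,
        pupil_center=(l_row - off * math.sin(ang), l_col + off * math.cos(ang)),
        pupil_radius=pupil_r,
        limbal_center=(l_row, l_col), limbal_radius=limbal_radius,
        texture_seed=seed, noise_sd=noise_sd, noise_seed=seed + 1_000_000)


_METHODS = {"daugman": segment_daugman,
            "masek": segment_masek,
            "proposed": segment_proposed}


def run_segmentation_benchmark(seeds=range(50),
                               config: PipelineConfig = DEFAULT_CONFIG,
                               methods=("daugman", "masek", "proposed")) -> dict:
    """Run every method on the benchmark eyes and tabulate boundary errors.

    Returns a dict with per-method :class:`ErrorCategory` lists, the
    success-rate :class:`EvalTable`, per-method pupil success rates, and the
    recorded pupil-stage candidate counts of the proposed method.
    """
    seeds = list(seeds)
    categories = {m: [] for m in methods}
    proposed_candidates = []
    for seed in seeds:
        spec = benchmark_eye_spec(seed)
        texture = generate_iris_texture(spec.texture_seed, config.radial_res,
                                        config.angular_res,
                                        config.texture_blur_sigma)
        image, truth = render_eye(spec, texture)
        for m in methods:
            try:
                res = _METHODS[m](image, config)
            except SegmentationFailureError:
                res = None
            if m == "proposed" and res is not None:
                proposed_candidates.append(res.details["n_pupil_candidates"])
            categories[m].append(classify_segmentation(
                res, truth, config.success_max_px, config.slight_max_px))
    table = success_table(categories, len(seeds), config.success_max_px)
    pupil_rate = {m: np.mean([c.pupil_displacement <= config.success_max_px
                              for c in cats])
                  for m, cats in categories.items()}
    return {"categories": categories, "table": table,
            "pupil_success_rate": pupil_rate,
            "proposed_pupil_candidates": proposed_candidates,
            "n_images": len(seeds)}


def process_image(image: np.ndarray,
                  config: PipelineConfig = DEFAULT_CONFIG) -> IrisCode:
    """Full pipeline on one image: proposed segmentation -> occlusion mask ->
    rubber sheet -> iris code.  Raises on segmentation failure."""
    seg = segment_proposed(image, config)
    noise = combine_masks(
        detect_specular_and_eyelash(image, config.bright_thresh,
                                    config.dark_thresh, seg),
        detect_eyelids(image, seg, config))
    polar = rubber_sheet(image, seg, noise, config.radial_res, config.angular_res)
    return encode(polar, config.wavelength, config.sigma_on_f)


def _identity_spec(texture_seed: int, noise_seed: int, pupil_radius: float,
                   spot_angle: float, size: int = 160,
                   limbal_radius: float = 60.0,
                   config: PipelineConfig = DEFAULT_CONFIG) -> EyeSpec:
    c = size / 2
    spot_r = (pupil_radius + limbal_radius) / 2
    spot = ((c - spot_r * math.sin(spot_angle), c + spot_r * math.cos(spot_angle)),
            3.0, 1.0)
    return EyeSpec(height=size, width=size,
                   pupil_center=(c + 2.0, c - 1.0), pupil_radius=pupil_radius,
                   limbal_center=(c, c), limbal_radius=limbal_radius,
                   texture_seed=texture_seed, noise_sd=config.noise_sd,
                   eyelid_coverage=0.15, specular_spots=(spot,),
                   noise_seed=noise_seed)


def run_identity_benchmark(n_identities: int = 20, n_images: int = 3,
                           seed: int = 0,
                           config: PipelineConfig = DEFAULT_CONFIG):
    """Multi-identity benchmark: all-pairs HDs and their class separation.

    Images that fail segmentation are excluded from matching (matching is only
    meaningful on successfully processed images).  Returns
    ``(HDSeparation, comparisons, n_processed)``.
    """
    rng = np.random.default_rng(seed)
    radii = [26.0, 30.0, 34.0]
    codes, labels = [], []
    for ident in range(n_identities):
        tex_seed = int(rng.integers(2 ** 31))
        for j in range(n_images):
            spec = _identity_spec(tex_seed, int(rng.integers(2 ** 31)),
                                  radii[j % len(radii)],
                                  spot_angle=float(rng.uniform(-0.6, 0.6)),
                                  config=config)
            texture = generate_iris_texture(tex_seed, config.radial_res,
                                            config.angular_res,
                                            config.texture_blur_sigma)
            image, _truth = render_eye(spec, texture)
            try:
                codes.append(process_image(image, config))
                labels.append(ident)
            except SegmentationFailureError:
                continue
    comparisons = []
    for i in range(len(codes)):
        for j in range(i + 1, len(codes)):
            comparisons.append((match(codes[i], codes[j],
                                      max_shift=config.max_shift,
                                      criterion=config.criterion),
                                labels[i] == labels[j]))
    return hd_distributions(comparisons), comparisons, len(codes)


def run_dilation_benchmark(seed: int = 0, n_gallery: int = 68,
                           dilated_mm=(4.6, 4.6, 4.6, 6.3, 6.3, 6.3, 7.4),
                           criteria=(0.37, 0.38, 0.39, 0.40, 0.41),
                           config: PipelineConfig = DEFAULT_CONFIG) -> DilationTable:
    """Dilation x criterion identification sweep on a single iris identity.

    Pupil diameters in mm map to pixel radii through the declared analog scale
    ``config.px_per_mm`` (radius_px = diameter_mm * px_per_mm / 2).  Gallery
    images carry non-dilated diameters (3.2-4.0 mm); probes carry the dilated
    diameters, grouped by level.  Images failing segmentation fall back to
    exclusion from their group.
    """
    rng = np.random.default_rng(seed)
    tex_seed = int(rng.integers(2 ** 31))
    texture = generate_iris_texture(tex_seed, config.radial_res,
                                    config.angular_res, config.texture_blur_sigma)

    def make_code(diameter_mm: float):
        radius = diameter_mm * config.px_per_mm / 2
        spec = _identity_spec(tex_seed, int(rng.integers(2 ** 31)), radius,
                              spot_angle=float(rng.uniform(-0.6, 0.6)),
                              config=config)
        image, _ = render_eye(spec, texture)
        try:
            return process_image(image, config)
        except SegmentationFailureError:
            return None

    gallery = [make_code(float(rng.uniform(3.2, 4.0))) for _ in range(n_gallery)]
    gallery = [g for g in gallery if g is not None]
    probes: dict[float, list] = {}
    for mm in dilated_mm:
        code = make_code(mm)
        if code is not None:
            probes.setdefault(mm, []).append(code)
    return dilation_sweep(gallery, probes, list(criteria), config.max_shift)
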