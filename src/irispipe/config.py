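"""Pipeline configuration: every tunable in one serializable place.

The defaults are the documented operating point of the pipeline; the CLI loads
a TOML file into a :class:`PipelineConfig` and lets flags override fields.
Unknown keys in a config file are rejected rather than ignored.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from pathlib import Path

from .errors import InvalidArgumentError

__all__ = ["PipelineConfig", "DEFAULT_CONFIG"]


@dataclass
class PipelineConfig:
    # physical analog scale (synthetic data; maps mm pupil diameters to pixels)
    px_per_mm: float = 10.0

    # normalization
    radial_res: int = 20
    angular_res: int = 240

    # encoding (single log-Gabor scale)
    wavelength: float = 18.0
    sigma_on_f: float = 0.5

    # matching
    max_shift: int = 8
    criterion: float = 0.40

    # integrodifferential search
    sigma_coarse: float = 2.0   # radial smoothing for the limbal boundary
    sigma_fine: float = 1.0     # radial smoothing for the pupil boundary
    angles_pupil: int = 128
    angles_limbal: int = 256
    limbal_min_frac: float = 0.25   # of min image dimension
    limbal_max_frac: float = 0.45
    pupil_min_frac: float = 0.15    # of detected limbal radius
    pupil_max_frac: float = 0.80
    min_edge_score: float = 0.02    # below this the search is degenerate
    search_window: int = 10         # side of the candidate-center grid (proposed)
    # limbal searches skip these angular sectors (degrees) to avoid eyelids
    eyelid_sectors: tuple = ((45.0, 135.0), (225.0, 315.0))

    # Canny (Masek route); thresholds are fractions of the max gradient magnitude
    canny_sigma: float = 2.0
    canny_sigma_fine: float = 1.0
    canny_low: float = 0.2
    canny_high: float = 0.5

    # blob-based pupil estimate
    morph_radius: int = 3
    central_fraction: float = 0.6

    # occlusion thresholds (intensity units); bright sits well above the
    # sclera mean (0.9) so only true specular highlights qualify
    bright_thresh: float = 0.97
    dark_thresh: float = 0.05

    # evaluation error taxonomy (pixels of combined displacement)
    success_max_px: float = 2.0
    slight_max_px: float = 5.0

    # synthetic generator
    noise_sd: float = 0.02
    texture_blur_sigma: float = 1.5

    seed: int = 0

    def __post_init__(self):
        if self.radial_res < 4 or self.angular_res < 4:
            raise InvalidArgumentError("polar resolutions must be >= 4")
        if not (0 < self.sigma_on_f < 1):
            raise InvalidArgumentError("sigma_on_f must lie in (0, 1)")
        if self.wavelength < 2:
            raise InvalidArgumentError("wavelength must be >= 2 px")
        if not (0 <= self.canny_low < self.canny_high <= 1):
            raise InvalidArgumentError("require 0 <= canny_low < canny_high <= 1")
        if not (0 <= self.dark_thresh < self.bright_thresh <= 1):
            raise InvalidArgumentError("require 0 <= dark_thresh < bright_thresh <= 1")
        if self.max_shift < 0:
            raise InvalidArgumentError("max_shift must be >= 0")
        if not (0 <= self.criterion <= 1):
            raise InvalidArgumentError("criterion must lie in [0, 1]")
        if not (0 < self.limbal_min_frac < self.limbal_max_frac < 1):
            raise InvalidArgumentError("limbal radius fractions out of order")
        if not (0 < self.pupil_min_frac < self.pupil_max_frac <= 1):
            raise InvalidArgumentError("pupil radius fractions out of order")

    # -- serialization -------------------------------------------------------

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        if "eyelid_sectors" in data:
            data["eyelid_sectors"] = tuple(tuple(s) for s in data["eyelid_sectors"])
        return cls(**data)

    def to_toml(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "eyelid_sectors":
                inner = ", ".join(f"[{a}, {b}]" for a, b in v)
                lines.append(f"{f.name} = [{inner}]")
            elif isinstance(v, bool):
                lines.append(f"{f.name} = {'true' if v else 'false'}")
            elif isinstance(v, (int, float)):
                lines.append(f"{f.name} = {v}")
            else:
                lines.append(f'{f.name} = "{v}"')
        Path(path).write_text("\n".join(lines) + "\n")


DEFAULT_CONFIG = PipelineConfig()
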