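"""Reading and writing pipeline artifacts.

Images: PNG/TIFF/BMP, 8/16-bit gray or color (converted by luminance), loaded
as float arrays normalized to [0, 1].  Structured outputs: JSON sidecars for
circles and masks (masks run-length encoded over the flattened array), JSON
iris codes with base64-packed bits, CSV comparison tables.
"""

from __future__ import annotations

import base64
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import InvalidArgumentError
from .types import Circle, GroundTruth, IrisCode, SegmentationResult

__all__ = [
    "load_image", "save_image",
    "circle_to_dict", "circle_from_dict",
    "mask_to_rle", "mask_from_rle",
    "save_segmentation", "load_segmentation",
    "save_ground_truth", "load_ground_truth",
    "save_code", "load_code",
]

_LUMA = np.array([0.2125, 0.7154, 0.0721])


def load_image(path: str | Path) -> np.ndarray:
    """Load a grayscale image as float64 in [0, 1] (color -> luminance)."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    if arr.ndim != 2:
        raise InvalidArgumentError(f"unsupported image shape {arr.shape}")
    arr = arr.astype(float)
    if arr.max() > 1.0:
        arr = arr / (65535.0 if arr.max() > 255 else 255.0)
    return np.clip(arr, 0.0, 1.0)


def save_image(path: str | Path, image: np.ndarray) -> None:
    """Write a [0, 1] float image as 8-bit grayscale."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(path, (arr * 255).round().astype(np.uint8))


def circle_to_dict(c: Circle) -> dict:
    return {"row": c.row, "col": c.col, "r": c.radius}


def circle_from_dict(d: dict) -> Circle:
    return Circle(float(d["row"]), float(d["col"]), float(d["r"]))


def mask_to_rle(mask: np.ndarray) -> dict:
    """Run-length encode a boolean mask (runs of the flattened array,
    alternating False/True and starting with False)."""
    flat = np.asarray(mask, dtype=bool).ravel()
    changes = np.flatnonzero(np.diff(flat.astype(np.int8)))
    bounds = np.concatenate([[0], changes + 1, [flat.size]])
    runs = np.diff(bounds).tolist()
    if flat.size and flat[0]:
        runs = [0] + runs
    return {"shape": list(mask.shape), "runs": runs}


def mask_from_rle(d: dict) -> np.ndarray:
    shape = tuple(d["shape"])
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos, val = 0, False
    for run in d["runs"]:
        if val:
            flat[pos:pos + run] = True
        pos += run
        val = not val
    return flat.reshape(shape)


def save_segmentation(path: str | Path, seg: SegmentationResult,
                      noise_mask: np.ndarray | None = None) -> None:
    data = {"method": seg.method,
            "pupil": circle_to_dict(seg.pupil),
            "limbal": circle_to_dict(seg.limbal),
            "pupil_score": seg.pupil_score,
            "limbal_score": seg.limbal_score,
            "warnings": seg.warnings}
    if noise_mask is not None:
        data["occlusion_rle"] = mask_to_rle(noise_mask)
    Path(path).write_text(json.dumps(data, indent=1))


def load_segmentation(path: str | Path):
    data = json.loads(Path(path).read_text())
    seg = SegmentationResult(circle_from_dict(data["pupil"]),
                             circle_from_dict(data["limbal"]),
                             data.get("method", "unknown"),
                             pupil_score=data.get("pupil_score"),
                             limbal_score=data.get("limbal_score"),
                             warnings=list(data.get("warnings", [])))
    mask = (mask_from_rle(data["occlusion_rle"])
            if "occlusion_rle" in data else None)
    return seg, mask


def save_ground_truth(path: str | Path, truth: GroundTruth) -> None:
    Path(path).write_text(json.dumps({
        "pupil": circle_to_dict(truth.pupil),
        "limbal": circle_to_dict(truth.limbal),
        "occlusion_rle": mask_to_rle(truth.occlusion_mask)}, indent=1))


def load_ground_truth(path: str | Path) -> GroundTruth:
    data = json.loads(Path(path).read_text())
    return GroundTruth(circle_from_dict(data["pupil"]),
                       circle_from_dict(data["limbal"]),
                       mask_from_rle(data["occlusion_rle"]))


def _pack(bits: np.ndarray) -> str:
    return base64.b64encode(np.packbits(bits.ravel())).decode("ascii")


def _unpack(s: str, shape) -> np.ndarray:
    raw = np.unpackbits(np.frombuffer(base64.b64decode(s), dtype=np.uint8))
    return raw[:int(np.prod(shape))].astype(bool).reshape(shape)


def save_code(path: str | Path, code: IrisCode) -> None:
    Path(path).write_text(json.dumps({
        "shape": list(code.bits.shape),
        "length": code.length,
        "bits": _pack(code.bits),
        "mask": _pack(code.mask),
        "metadata": code.meta}, indent=1))


def load_code(path: str | Path) -> IrisCode:
    data = json.loads(Path(path).read_text())
    shape = tuple(data["shape"])
    return IrisCode(_unpack(data["bits"], shape), _unpack(data["mask"], shape),
                    dict(data.get("metadata", {})))
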