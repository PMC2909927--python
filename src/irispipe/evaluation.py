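"""Evaluation designs: error taxonomy, success-rate tables, HD distributions
and the dilation x decision-criterion identification sweep.

Segmentation accuracy is summarized by a two-level error taxonomy — *slight*
(boundaries displaced by a few pixels) versus *extreme* (clearly displaced) —
quantified here as combined displacement (Euclidean center offset plus
absolute radius error, max over the two boundaries): success <= 2 px, slight
<= 5 px, extreme beyond.  Success-rate tables count per-boundary successes per
method; percentages are printed to one decimal with half-up rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .matching import match
from .types import (Circle, ErrorCategory, GroundTruth, IrisCode, MatchResult,
                    SegmentationResult)

__all__ = [
    "percent",
    "boundary_displacements",
    "classify_segmentation",
    "EvalTable",
    "success_table",
    "HDSeparation",
    "hd_distributions",
    "DilationTable",
    "dilation_sweep",
]


def percent(count: int, total: int) -> float:
    """``100 * count / total`` rounded half-up to one decimal place."""
    if total <= 0:
        raise InvalidArgumentError("total must be > 0")
    q = (Decimal(100) * Decimal(count) / Decimal(total)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP)
    return float(q)


def _circle_displacement(found: Circle, truth: Circle) -> float:
    return (math.hypot(found.row - truth.row, found.col - truth.col)
            + abs(found.radius - truth.radius))


def boundary_displacements(result: SegmentationResult,
                           truth: GroundTruth) -> tuple[float, float]:
    """Per-boundary combined displacement (center offset + |radius error|)."""
    return (_circle_displacement(result.pupil, truth.pupil),
            _circle_displacement(result.limbal, truth.limbal))


def classify_segmentation(result: SegmentationResult | None, truth: GroundTruth,
                          success_max: float = 2.0,
                          slight_max: float = 5.0) -> ErrorCategory:
    """Error category against ground truth; a failed segmentation is extreme."""
    if result is None:
        return ErrorCategory("extreme", math.inf, math.inf, math.inf)
    pd_, ld = boundary_displacements(result, truth)
    disp = max(pd_, ld)
    if disp <= success_max:
        label = "success"
    elif disp <= slight_max:
        label = "slight"
    else:
        label = "extreme"
    return ErrorCategory(label, disp, pd_, ld)


@dataclass
class EvalTable:
    """Per-method pupil / iris / both boundary-success counts and percentages."""

    counts: dict            # method -> (pupil, iris, both)
    total: int

    def __post_init__(self):
        if self.total <= 0:
            raise InvalidArgumentError("total must be > 0")
        for method, (p, i, b) in self.counts.items():
            if b > min(p, i):
                raise InvalidArgumentError(
                    f"{method}: 'both' count exceeds min(pupil, iris)")

    def percentage(self, method: str, column: str) -> float:
        idx = {"pupil": 0, "iris": 1, "both": 2}[column]
        return percent(self.counts[method][idx], self.total)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for method, (p, i, b) in self.counts.items():
            rows.append({"method": method,
                         "pupil_n": p, "pupil_pct": percent(p, self.total),
                         "iris_n": i, "iris_pct": percent(i, self.total),
                         "both_n": b, "both_pct": percent(b, self.total)})
        return pd.DataFrame(rows).set_index("method")


def success_table(categories: dict[str, list[ErrorCategory]], total: int,
                  success_max: float = 2.0) -> EvalTable:
    """Count per-boundary successes (displacement <= ``success_max``) per method."""
    counts = {}
    for method, cats in categories.items():
        p = sum(c.pupil_displacement <= success_max for c in cats)
        i = sum(c.limbal_displacement <= success_max for c in cats)
        b = sum(c.pupil_displacement <= success_max
                and c.limbal_displacement <= success_max for c in cats)
        counts[method] = (p, i, b)
    return EvalTable(counts, total)


@dataclass
class HDSeparation:
    """Intra-/inter-class HD summaries and the separation interval."""

    intra_hist: np.ndarray
    inter_hist: np.ndarray
    bin_edges: np.ndarray
    max_intra: float
    min_inter: float
    n_intra: int
    n_inter: int

    @property
    def separation(self) -> tuple[float, float] | None:
        """``[max_intra, min_inter]``, or None when the classes overlap."""
        if self.max_intra < self.min_inter:
            return (self.max_intra, self.min_inter)
        return None


def hd_distributions(comparisons: list[tuple[MatchResult, bool]],
                     bin_width: float = 0.01) -> HDSeparation:
    """Histograms and separation of intra- vs inter-class HDs.

    ``comparisons`` pairs each :class:`MatchResult` with an intra-class flag
    (True = same iris).  Both classes must be represented.
    """
    intra = [m.hd for m, is_intra in comparisons if is_intra]
    inter = [m.hd for m, is_intra in comparisons if not is_intra]
    if not intra or not inter:
        raise InvalidArgumentError("need at least one comparison of each class")
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    hi, _ = np.histogram(intra, bins=edges)
    he, _ = np.histogram(inter, bins=edges)
    return HDSeparation(hi, he, edges, max(intra), min(inter),
                        len(intra), len(inter))


def plot_hd_distributions(sep: HDSeparation, path=None):
    """Overlaid intra/inter HD histograms (optional helper; needs matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    centers = 0.5 * (sep.bin_edges[:-1] + sep.bin_edges[1:])
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar(centers, sep.intra_hist, width=0.01, alpha=0.6, label="intra-class")
    ax.bar(centers, sep.inter_hist, width=0.01, alpha=0.6, label="inter-class")
    ax.set_xlabel("Hamming distance")
    ax.set_ylabel("comparisons")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


@dataclass
class DilationTable:
    """Identification success (%) per dilation level x decision criterion."""

    levels: list            # dilation labels (e.g. mm analogs), row order
    criteria: list[float]   # column order, ascending
    values: np.ndarray      # (levels, criteria) percentages
    n_comparisons: list[int]  # per level

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.levels,
                          columns=[f"{c:.2f}" for c in self.criteria])
        df["total_comparisons"] = self.n_comparisons
        return df

    def rows_monotone(self) -> bool:
        """True iff every row is non-decreasing left-to-right (criterion grows)."""
        return bool(np.all(np.diff(self.values, axis=1) >= -1e-9))


def dilation_sweep(gallery: list[IrisCode],
                   probes: dict[object, list[IrisCode]],
                   criteria: list[float],
                   max_shift: int = 8) -> DilationTable:
    """Gallery x probe identification success per dilation level and criterion.

    Each cell is ``100 * (#comparisons with hd <= criterion) / (#comparisons
    at that level)``; the comparison count per level is
    ``len(gallery) * len(probes[level])``.  Each pair's HD is computed once
    (shift search included) and thresholded at every criterion, so rows are
    monotone non-decreasing in the criterion by construction.
    """
    if not gallery or not probes or not criteria:
        raise InvalidArgumentError("gallery, probes and criteria must be non-empty")
    criteria = sorted(criteria)
    levels = list(probes.keys())
    values = np.zeros((len(levels), len(criteria)))
    n_comp = []
    for li, level in enumerate(levels):
        codes = probes[level]
        if not codes:
            raise InvalidArgumentError(f"no probes at dilation level {level!r}")
        hds = [match(g, p, max_shift=max_shift).hd for g in gallery for p in codes]
        n = len(hds)
        n_comp.append(n)
        for ci, crit in enumerate(criteria):
            values[li, ci] = percent(sum(h <= crit for h in hds), n)
    return DilationTable(levels, criteria, values, n_comp)
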