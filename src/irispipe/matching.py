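"""Iris-code comparison: masked Hamming distance with rotational shift search.

The Hamming distance (HD) between two codes is the fraction of disagreeing
bits among those valid in both masks; identical irides give HD near 0, while
independent irides give HD near 0.5 (each unmasked bit agrees by chance).
Head rotation between captures appears as a circular shift of the angular
axis, so :func:`match` minimizes the HD over shifts of the second code within
``+/- max_shift`` bit-pairs and applies the decision criterion (inclusive
boundary): two codes are declared the same iris iff ``hd <= criterion``.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidArgumentError, UndefinedComparisonError
from .types import IrisCode, MatchResult

__all__ = ["hamming_distance", "match", "decide"]


def hamming_distance(a: IrisCode, b: IrisCode) -> tuple[float, int]:
    """Masked HD: ``popcount((A ^ B) & maskA & maskB) / popcount(maskA & maskB)``.

    Returns ``(hd, valid_bits)``; raises if the codes differ in length or no
    bit is valid in both masks.
    """
    if a.bits.shape != b.bits.shape:
        raise InvalidArgumentError(
            f"code length mismatch: {a.bits.shape} vs {b.bits.shape}")
    both = a.mask & b.mask
    valid = int(both.sum())
    if valid == 0:
        raise UndefinedComparisonError("no bit is valid in both codes")
    disagree = int(((a.bits ^ b.bits) & both).sum())
    return disagree / valid, valid


def match(a: IrisCode, b: IrisCode, max_shift: int = 8,
          criterion: float = 0.40) -> MatchResult:
    """Best (minimum) HD over circular shifts of ``b`` in ``-max_shift..+max_shift``.

    Shifts are counted in bit-pairs (angular steps).  Ties keep the first
    shift encountered scanning from ``-max_shift`` upward.
    """
    if max_shift < 0:
        raise InvalidArgumentError("max_shift must be >= 0")
    best_hd, best_shift, best_valid = np.inf, 0, 0
    defined = False
    for s in range(-max_shift, max_shift + 1):
        try:
            hd, valid = hamming_distance(a, b.rolled(s) if s else b)
        except UndefinedComparisonError:
            continue
        defined = True
        if hd < best_hd:
            best_hd, best_shift, best_valid = hd, s, valid
    if not defined:
        raise UndefinedComparisonError("no shift yields any mutually valid bit")
    return MatchResult(hd=best_hd, best_shift=best_shift, valid_bits=best_valid,
                       decision=decide(best_hd, criterion), criterion=criterion)


def decide(hd: float, criterion: float) -> bool:
    """Same-iris decision: ``hd <= criterion`` (boundary inclusive)."""
    if not (0 <= hd <= 1) or not (0 <= criterion <= 1):
        raise InvalidArgumentError("hd and criterion must lie in [0, 1]")
    return hd <= criterion
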