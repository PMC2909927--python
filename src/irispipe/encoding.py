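"""Phase encoding: polar iris image -> binary iris code via 1-D log-Gabor.

Each radial row of the normalized iris is filtered along the angular direction
with a single-scale log-Gabor filter (circular convolution, since the ring is
physically closed; zero DC gain).  Amplitude is discarded: each complex
coefficient is quantized to two bits by the quadrant of its phase,
``(Re >= 0, Im >= 0)``, giving ``2 * radial_res * angular_res`` bits total.
Mask bits are cleared wherever the coefficient's own polar sample was invalid,
with a 1-pixel dilation of invalidity along the row to cover filter support.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidArgumentError
from .types import IrisCode, PolarIris

__all__ = ["log_gabor_transfer", "log_gabor_row", "encode"]


def log_gabor_transfer(freqs: np.ndarray, wavelength: float,
                       sigma_on_f: float) -> np.ndarray:
    """Log-Gabor transfer function ``exp(-(log(f/f0))^2 / (2 log(sigma_on_f)^2))``.

    ``f0 = 1 / wavelength`` (cycles per sample).  The response is defined on
    positive frequencies only (zero at DC and at negative frequencies), so the
    filtered signal is complex analytic and carries phase.
    """
    if wavelength < 2:
        raise InvalidArgumentError("wavelength must be >= 2 samples")
    if not (0 < sigma_on_f < 1):
        raise InvalidArgumentError("sigma_on_f must lie in (0, 1)")
    freqs = np.asarray(freqs, dtype=float)
    f0 = 1.0 / wavelength
    out = np.zeros_like(freqs)
    pos = freqs > 0
    out[pos] = np.exp(-(np.log(freqs[pos] / f0) ** 2)
                      / (2.0 * np.log(sigma_on_f) ** 2))
    return out


def log_gabor_row(signal: np.ndarray, wavelength: float = 18.0,
                  sigma_on_f: float = 0.5) -> np.ndarray:
    """Filter a 1-D signal with the log-Gabor filter (circular convolution).

    Returns a complex coefficient sequence of the same length; a constant
    signal maps to (numerically) zero everywhere because the DC gain is zero.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1 or signal.size < 8:
        raise InvalidArgumentError("signal must be 1-D with length >= 8")
    freqs = np.fft.fftfreq(signal.size)
    gain = log_gabor_transfer(freqs, wavelength, sigma_on_f)
    return np.fft.ifft(np.fft.fft(signal) * gain)


def encode(polar: PolarIris, wavelength: float = 18.0,
           sigma_on_f: float = 0.5) -> IrisCode:
    """Quantize log-Gabor phase into the binary iris code.

    Bit pair per coefficient: ``(Re >= 0, Im >= 0)`` (exact zeros count as 1
    so the encoding is deterministic).  Mask bits are False iff the
    coefficient's polar pixel, or one of its two angular neighbors, was
    invalid (wrap-around, matching the circular filtering).
    """
    R, A = polar.values.shape
    if A < 8:
        raise InvalidArgumentError("angular resolution too small for filtering")
    freqs = np.fft.fftfreq(A)
    gain = log_gabor_transfer(freqs, wavelength, sigma_on_f)
    coeffs = np.fft.ifft(np.fft.fft(polar.values, axis=1) * gain[None, :], axis=1)

    bits = np.empty((R, A, 2), dtype=bool)
    bits[:, :, 0] = coeffs.real >= 0
    bits[:, :, 1] = coeffs.imag >= 0

    invalid = ~polar.valid
    invalid = invalid | np.roll(invalid, 1, axis=1) | np.roll(invalid, -1, axis=1)
    mask = np.repeat((~invalid)[:, :, None], 2, axis=2)
    return IrisCode(bits, mask,
                    meta={"wavelength": wavelength, "sigma_on_f": sigma_on_f})
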