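"""Susceptibility-weighted image construction from multi-echo GRE data.

The pipeline is the standard SWI recipe: per slice and echo the wrapped
phase is background-corrected by homodyne filtering (complex division by a
k-space-centre Hamming-windowed low-pass copy of the complex image), the
residual high-pass phase is turned into a multiplicative weight with a
negative-phase linear mask raised to an integer power m, and the weighted
magnitudes are averaged across echoes.  Defaults follow a 12 x 12 Hamming
kernel and m = 4.

Filtering the wrapped phase directly in image space would smear phase
wraps; operating on the complex image sidesteps that, which is why the
homodyne construction is used here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .relaxometry import EchoSeries

__all__ = ["PhaseMaskParams", "homodyne_highpass", "phase_mask", "build_swi"]


@dataclass
class PhaseMaskParams:
    """Configuration for the phase-mask SWI weighting.

    kernel_size : in-plane size of the central Hamming window (spectral
        points); m : mask exponent; polarity : which phase sign darkens
        the image ("negative" for paramagnetic sources with this phase
        convention).
    """

    kernel_size: tuple = (12, 12)
    m: int = 4
    polarity: str = "negative"

    def __post_init__(self):
        kx, ky = self.kernel_size
        if kx <= 0 or ky <= 0:
            raise ValueError("kernel dimensions must be positive")
        if int(self.m) != self.m or self.m < 1:
            raise ValueError("mask exponent m must be an integer >= 1")
        if self.polarity not in ("negative", "positive"):
            raise ValueError("polarity must be 'negative' or 'positive'")


def homodyne_highpass(magnitude_slice: np.ndarray, phase_slice: np.ndarray,
                      kernel_size=(12, 12)) -> np.ndarray:
    """High-pass filter a 2D phase slice by homodyne demodulation.

    The complex image I = M exp(i phi) is Fourier transformed; the
    centred spectrum is multiplied by a ``kernel_size`` 2D Hamming window
    (zero outside) to form a low-pass reference L, and the output is
    arg(I conj(L)), wrapped to (-pi, pi].
    """
    mag = np.asarray(magnitude_slice, dtype=float)
    ph = np.asarray(phase_slice, dtype=float)
    if mag.shape != ph.shape or mag.ndim != 2:
        raise ValueError("magnitude and phase must be 2D arrays of equal shape")
    kx, ky = kernel_size
    if kx > mag.shape[0] or ky > mag.shape[1]:
        raise ValueError("kernel larger than in-plane matrix")
    if not mag.any():
        warnings.warn("all-zero magnitude slice; high-pass phase set to zero")
        return np.zeros_like(mag)

    img = mag * np.exp(1j * ph)
    spec = np.fft.fftshift(np.fft.fft2(img))
    win = np.outer(_centered_hamming(mag.shape[0], kx),
                   _centered_hamming(mag.shape[1], ky))
    lowpass = np.fft.ifft2(np.fft.ifftshift(spec * win))
    return np.angle(img * np.conj(lowpass))


def _centered_hamming(n: int, width: int) -> np.ndarray:
    """Hamming window of nominal ``width`` spectral points, sampled
    symmetrically about the DC bin of a centred length-``n`` spectrum.

    Symmetry about DC keeps the low-pass of a real image real, so a
    zero-phase input yields an exactly zero high-pass phase (up to the
    sign ambiguity where the low-pass goes negative); an off-centre
    window would leak spurious phase into magnitude-only structure.
    """
    d = np.arange(n) - n // 2
    half = (width - 1) / 2.0
    w = 0.54 + 0.46 * np.cos(2 * np.pi * d / (width - 1))
    return np.where(np.abs(d) <= half, w, 0.0)


def phase_mask(highpass_phase: np.ndarray, m: int = 4,
               polarity: str = "negative") -> np.ndarray:
    """Linear phase mask raised to the power m, in [0, 1].

    Negative polarity: f(phi) = 1 for phi >= 0 and (pi + phi)/pi for
    phi < 0, so phi = -pi is fully suppressed.  Positive polarity mirrors
    the ramp onto positive phase.  m = 0 is allowed at the function level
    and degenerates to a unit weight.
    """
    ph = np.asarray(highpass_phase, dtype=float)
    if polarity == "negative":
        f = np.where(ph >= 0, 1.0, (np.pi + ph) / np.pi)
    elif polarity == "positive":
        f = np.where(ph <= 0, 1.0, (np.pi - ph) / np.pi)
    else:
        raise ValueError("polarity must be 'negative' or 'positive'")
    return np.clip(f, 0.0, 1.0) ** m


def build_swi(series: EchoSeries, params: PhaseMaskParams | None = None) -> np.ndarray:
    """Build the final SWI volume from a multi-echo series.

    Per echo and slice: homodyne high-pass of the phase, phase-mask
    weighting of the magnitude; the final image is the arithmetic mean of
    the weighted magnitudes across echoes.
    """
    if params is None:
        params = PhaseMaskParams()
    if series.n_echoes == 0:
        raise ValueError("echo series is empty")
    nx, ny, nz, ne = series.magnitude.shape
    out = np.zeros((nx, ny, nz))
    for e in range(ne):
        for z in range(nz):
            mag = series.magnitude[:, :, z, e]
            hp = homodyne_highpass(mag, series.phase[:, :, z, e],
                                   params.kernel_size)
            out[:, :, z] += phase_mask(hp, params.m, params.polarity) * mag
    out /= ne
    return out
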