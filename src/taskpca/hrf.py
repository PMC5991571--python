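"""Modeled hemodynamic response and frequency power spectra.

The BOLD response to a brief neural event is modeled with the conventional
double-gamma kernel: a positive gamma density peaking ~5 s after the event
minus a weaker, later gamma accounting for the post-stimulus undershoot.  The
modeled response of a whole design is the boxcar of event on-periods convolved
with this kernel on an oversampled grid, sampled back at frame times, and
mean-centered -- the regressor against which component time courses are
correlated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design import TaskDesign

__all__ = [
    "canonical_hrf",
    "modeled_response",
    "power_spectrum",
    "ModeledResponse",
    "PowerSpectrum",
]

#: double-gamma defaults: peak delay, undershoot delay, dispersions,
#: peak:undershoot amplitude ratio and kernel support (seconds)
HRF_PEAK_DELAY = 6.0
HRF_UNDERSHOOT_DELAY = 16.0
HRF_PEAK_DISPERSION = 1.0
HRF_UNDERSHOOT_DISPERSION = 1.0
HRF_RATIO = 6.0
HRF_LENGTH = 32.0


@dataclass(frozen=True)
class ModeledResponse:
    """Mean-centered expected BOLD time course sampled at frame times."""

    values: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def n_frames(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided periodogram.

    Normalisation: ``power[k] = c_k |X_k|^2 / n`` for the DFT ``X`` of the
    mean-removed series, with ``c_k = 2`` except at DC and (for even n) the
    Nyquist bin.  Under this convention ``sum(power) == n * var(series)``.
    """

    frequencies: np.ndarray
    power: np.ndarray

    @property
    def peak_frequency(self) -> float:
        """Frequency of the largest non-DC power bin."""
        k = 1 + int(np.argmax(self.power[1:]))
        return float(self.frequencies[k])


def canonical_hrf(tr: float, oversample: int = 16) -> np.ndarray:
    """Double-gamma hemodynamic response kernel, unit peak amplitude.

    Sampled at ``tr / oversample`` over a 32 s support; the first sample is
    t = 0 where the kernel vanishes (both gamma shapes exceed one).
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if oversample < 1:
        raise ValueError("oversample must be >= 1")
    dt = tr / oversample
    t = np.arange(0.0, HRF_LENGTH + dt / 2, dt)
    peak = stats.gamma.pdf(t, HRF_PEAK_DELAY / HRF_PEAK_DISPERSION, scale=HRF_PEAK_DISPERSION)
    under = stats.gamma.pdf(
        t, HRF_UNDERSHOOT_DELAY / HRF_UNDERSHOOT_DISPERSION, scale=HRF_UNDERSHOOT_DISPERSION
    )
    kernel = peak - under / HRF_RATIO
    return kernel / kernel.max()


def modeled_response(design: TaskDesign, oversample: int = 16) -> ModeledResponse:
    """Expected BOLD response of a design, at frame resolution, mean-centered.

    The on/off boxcar is built at ``tr/oversample`` resolution, convolved with
    :func:`canonical_hrf`, truncated at scan end (no wraparound), sampled at
    the acquisition time of each frame, then mean-centered.
    """
    tr, n = design.tr, design.n_frames
    dt = tr / oversample
    n_fine = n * oversample
    boxcar = np.zeros(n_fine)
    grid = np.arange(n_fine) * dt
    for onset, dur in zip(design.onsets, design.durations):
        boxcar[(grid >= onset) & (grid < onset + dur)] = 1.0
    kernel = canonical_hrf(tr, oversample)
    fine = np.convolve(boxcar, kernel)[:n_fine] * dt
    values = fine[::oversample][:n]
    values = values - values.mean()
    return ModeledResponse(values=values, tr=tr)


def power_spectrum(series: np.ndarray, tr: float) -> PowerSpectrum:
    """One-sided periodogram of a time series sampled every ``tr`` seconds.

    The series mean is removed first, so a constant series yields all-zero
    power.  See :class:`PowerSpectrum` for the normalisation; the Parseval
    identity ``sum(power) == n * var(series)`` holds exactly.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 8:
        raise ValueError("series must be 1-D with at least 8 samples")
    n = x.size
    x = x - x.mean()
    spec = np.fft.rfft(x)
    power = np.abs(spec) ** 2 / n
    power[0] = 0.0  # mean already removed; clear fp residue at DC
    scale = np.full(power.size, 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    power *= scale
    freqs = np.fft.rfftfreq(n, d=tr)
    return PowerSpectrum(frequencies=freqs, power=power)
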