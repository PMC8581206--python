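"""Amplitude-normalised single-sided spectra and baseline spectral lines.

The spectrum here is the plain rectangular-window FFT, rescaled so that a
noise-free *on-grid* sinusoid of amplitude A shows amplitude A at its bin
(interior bins scaled by 2/N; DC and, for even N, the Nyquist bin by 1/N).
For off-grid tones the energy leaks into neighbouring bins; the two lines one
resolution Δf = f_s/N apart that straddle the tone — the baseline spectral
lines (BSSLs) — are what the ratio-based correction consumes.

`evaluate_dtft_line` evaluates the same normalised quantity at an arbitrary
off-grid frequency by direct summation; the dual-step algorithm needs this
for its second round, whose probe frequencies fall between FFT bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .signal_model import SampledSignal, wrap_phase

__all__ = [
    "AmplitudeSpectrum",
    "SpectralLine",
    "BsslPair",
    "compute_spectrum",
    "evaluate_dtft_line",
    "locate_bssl",
]

# relative amplitude difference below which neighbouring lines are a tie
_TIE_REL_TOL = 1e-12


@dataclass(frozen=True)
class SpectralLine:
    """A single spectral line: frequency, amplitude (signal units), phase."""

    frequency_hz: float
    amplitude: float
    phase_rad: float

    def __post_init__(self) -> None:
        if self.frequency_hz < 0:
            raise ValueError("frequency_hz must be non-negative")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        object.__setattr__(self, "phase_rad", wrap_phase(self.phase_rad))


@dataclass(frozen=True)
class AmplitudeSpectrum:
    """Single-sided, amplitude-normalised DFT of a :class:`SampledSignal`.

    ``lines[l]`` is the complex coefficient at frequency ``l * bin_spacing_hz``
    for ``l = 0 .. floor(N/2)``, scaled so the modulus reads directly in
    signal units of sinusoid amplitude.
    """

    lines: np.ndarray
    bin_spacing_hz: float
    source_n: int
    source_rate_hz: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.lines, dtype=complex)
        arr.setflags(write=False)
        object.__setattr__(self, "lines", arr)

    @property
    def n_lines(self) -> int:
        return int(self.lines.size)

    def frequencies(self) -> np.ndarray:
        return np.arange(self.n_lines) * self.bin_spacing_hz

    def amplitudes(self) -> np.ndarray:
        return np.abs(self.lines)

    def line(self, index: int) -> SpectralLine:
        """The spectral line at bin ``index`` as (frequency, amplitude, phase)."""
        c = self.lines[index]
        return SpectralLine(
            frequency_hz=index * self.bin_spacing_hz,
            amplitude=float(np.abs(c)),
            phase_rad=float(np.angle(c)),
        )


@dataclass(frozen=True)
class BsslPair:
    """Two spectral lines exactly one resolution apart straddling the tone."""

    left: SpectralLine
    right: SpectralLine
    spacing_hz: float

    def __post_init__(self) -> None:
        gap = self.right.frequency_hz - self.left.frequency_hz
        if not np.isclose(gap, self.spacing_hz, rtol=1e-9, atol=0.0):
            raise ValueError(
                f"line spacing {gap} Hz does not match resolution "
                f"{self.spacing_hz} Hz"
            )


def compute_spectrum(signal: SampledSignal) -> AmplitudeSpectrum:
    """Single-sided amplitude-normalised FFT (rectangular window).

    Interior bins carry 2/N so a full-period unit sinusoid reads 1.0 at its
    frequency; DC and the even-N Nyquist bin carry 1/N (they have no mirror).
    """
    x = signal.samples
    n = signal.n_samples
    coef = np.fft.rfft(x)  # negative-exponent convention
    scale = np.full(coef.size, 2.0 / n)
    scale[0] = 1.0 / n
    if n % 2 == 0:
        scale[-1] = 1.0 / n
    return AmplitudeSpectrum(
        lines=coef * scale,
        bin_spacing_hz=signal.sampling_rate_hz / n,
        source_n=n,
        source_rate_hz=signal.sampling_rate_hz,
    )


def evaluate_dtft_line(signal: SampledSignal, frequency_hz: float) -> SpectralLine:
    """Normalised spectral line at an arbitrary (generally off-grid) frequency.

    Computes the direct sum ``(2/N) * sum_n x[n] exp(-i 2 pi f n / f_s)`` —
    exactly what :func:`compute_spectrum` would report if the grid contained
    ``frequency_hz``.  O(N) per call; only a handful of lines are ever needed.
    """
    if not (0 < frequency_hz < signal.nyquist_hz):
        raise ValueError(
            f"frequency {frequency_hz} Hz must lie strictly inside "
            f"(0, {signal.nyquist_hz}) Hz"
        )
    n = np.arange(signal.n_samples)
    c = np.sum(
        signal.samples
        * np.exp(-2j * np.pi * frequency_hz * n / signal.sampling_rate_hz)
    ) * (2.0 / signal.n_samples)
    return SpectralLine(
        frequency_hz=float(frequency_hz),
        amplitude=float(np.abs(c)),
        phase_rad=float(np.angle(c)),
    )


def locate_bssl(
    spectrum: AmplitudeSpectrum,
    search_band_hz: Optional[Tuple[float, float]] = None,
) -> BsslPair:
    """Locate the baseline pair of spectral lines around the dominant tone.

    Finds the interior bin of maximum amplitude (optionally restricted to
    ``search_band_hz``) and pairs it with its larger-amplitude neighbour,
    returning the pair ordered by frequency.  When the two neighbours tie
    (on-grid tone), the right neighbour is chosen so the pair is (k, k+1).
    """
    if spectrum.n_lines < 4:
        raise ValueError("spectrum must have at least 4 lines")
    amps = spectrum.amplitudes()
    df = spectrum.bin_spacing_hz

    lo_bin, hi_bin = 1, spectrum.n_lines - 2  # interior bins only
    if search_band_hz is not None:
        lo_hz, hi_hz = search_band_hz
        if not (lo_hz < hi_hz):
            raise ValueError("search band must be a non-empty (low, high) interval")
        lo_bin = max(lo_bin, int(np.ceil(lo_hz / df)))
        hi_bin = min(hi_bin, int(np.floor(hi_hz / df)))
        if hi_bin - lo_bin < 2:
            raise ValueError(
                f"search band [{lo_hz}, {hi_hz}] Hz holds fewer than 3 "
                f"interior bins at resolution {df} Hz"
            )

    k = lo_bin + int(np.argmax(amps[lo_bin : hi_bin + 1]))
    if k - 1 < 0 or k + 1 >= spectrum.n_lines:
        raise ValueError(
            f"peak at bin {k} has no valid neighbour pair (spectrum edge)"
        )
    y_lo, y_hi = amps[k - 1], amps[k + 1]
    if abs(y_lo - y_hi) < _TIE_REL_TOL * amps[k] or y_hi >= y_lo:
        left, right = k, k + 1
    else:
        left, right = k - 1, k
    return BsslPair(
        left=spectrum.line(left), right=spectrum.line(right), spacing_hz=df
    )
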