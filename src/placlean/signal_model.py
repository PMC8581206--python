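"""Sampled-signal and harmonic-parameter types plus synthetic-signal generators.

Everything downstream (spectrum computation, ratio-based correction, artifact
removal) operates on :class:`SampledSignal` and :class:`HarmonicParams`.  The
generators here produce every input the test-bench needs — pure sinusoids
modelling the power-line artifact (PLA), white Gaussian noise at a target SNR,
and a band-limited EEG-like surrogate — so no recorded data is required.

Phase is referenced to the first sample (t = 0 at n = 0) throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

__all__ = [
    "SampledSignal",
    "HarmonicParams",
    "NoiseSpec",
    "wrap_phase",
    "generate_sinusoid",
    "add_gaussian_noise",
    "synth_eeg_surrogate",
    "compose",
]

_TWO_PI = 2.0 * math.pi


def wrap_phase(phase_rad: float) -> float:
    """Wrap an angle to the half-open interval (-pi, pi]."""
    w = float(phase_rad) % _TWO_PI  # in [0, 2*pi)
    if w > math.pi:
        w -= _TWO_PI
    return w


@dataclass(frozen=True)
class SampledSignal:
    """A finite, uniformly sampled real-valued time series.

    Parameters
    ----------
    samples
        The sample values (e.g. microvolts).  At least two finite values.
    sampling_rate_hz
        Sampling rate ``f_s`` in Hz; sample ``n`` is taken at ``t = n / f_s``.
    """

    samples: np.ndarray
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if arr.size < 2:
            raise ValueError(f"need at least 2 samples, got {arr.size}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("samples must all be finite")
        if not (float(self.sampling_rate_hz) > 0):
            raise ValueError("sampling_rate_hz must be positive")
        arr.setflags(write=False)
        object.__setattr__(self, "samples", arr)
        object.__setattr__(self, "sampling_rate_hz", float(self.sampling_rate_hz))

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def dt(self) -> float:
        """Sampling interval in seconds."""
        return 1.0 / self.sampling_rate_hz

    @property
    def nyquist_hz(self) -> float:
        return self.sampling_rate_hz / 2.0

    def times(self) -> np.ndarray:
        """Sample times ``t_n = n / f_s`` in seconds."""
        return np.arange(self.n_samples) * self.dt

    def rms(self) -> float:
        """Root-mean-square amplitude."""
        return float(np.sqrt(np.mean(self.samples**2)))


@dataclass(frozen=True)
class HarmonicParams:
    """Amplitude, frequency and phase of a sinusoid ``A*cos(2*pi*f*t + phi)``.

    These three numbers uniquely determine a harmonic component such as the
    mains interference; the estimators in :mod:`placlean.correction` return
    instances of this type.  Phase is stored wrapped to (-pi, pi].
    """

    amplitude: float
    frequency_hz: float
    phase_rad: float = 0.0

    def __post_init__(self) -> None:
        if not (self.amplitude >= 0):
            raise ValueError("amplitude must be non-negative")
        if not (self.frequency_hz > 0):
            raise ValueError("frequency_hz must be positive")
        object.__setattr__(self, "amplitude", float(self.amplitude))
        object.__setattr__(self, "frequency_hz", float(self.frequency_hz))
        object.__setattr__(self, "phase_rad", wrap_phase(self.phase_rad))


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white-Gaussian-noise specification.

    ``snr_db`` is the mean-square power ratio 10*log10(P_signal / P_noise);
    ``math.inf`` means no noise.  The seed makes realisations reproducible.
    """

    snr_db: float = math.inf
    seed: int = 0


def generate_sinusoid(
    params: HarmonicParams, sampling_rate_hz: float, n_samples: int
) -> SampledSignal:
    """Sample ``A*cos(2*pi*f*t + phi)`` at ``n_samples`` points.

    The frequency must lie strictly below the Nyquist rate.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be at least 2")
    nyq = sampling_rate_hz / 2.0
    if not (0 < params.frequency_hz < nyq):
        raise ValueError(
            f"frequency {params.frequency_hz} Hz must lie in (0, {nyq}) Hz "
            f"(Nyquist bound for sampling rate {sampling_rate_hz} Hz)"
        )
    n = np.arange(n_samples)
    x = params.amplitude * np.cos(
        _TWO_PI * params.frequency_hz * n / sampling_rate_hz + params.phase_rad
    )
    return SampledSignal(x, sampling_rate_hz)


def add_gaussian_noise(signal: SampledSignal, noise: NoiseSpec) -> SampledSignal:
    """Add seeded white Gaussian noise at the requested SNR.

    The noise standard deviation is derived from the signal's realised RMS:
    ``sigma = rms(signal) * 10**(-snr_db / 20)``, so the *expected* empirical
    SNR equals ``snr_db``.  ``snr_db = inf`` returns the input unchanged.
    """
    if math.isinf(noise.snr_db) and noise.snr_db > 0:
        return signal
    rms = signal.rms()
    if rms == 0.0:
        raise ValueError("SNR is undefined for an all-zero signal")
    sigma = rms * 10.0 ** (-noise.snr_db / 20.0)
    rng = np.random.default_rng(noise.seed)
    w = rng.normal(0.0, sigma, signal.n_samples)
    return SampledSignal(signal.samples + w, signal.sampling_rate_hz)


def synth_eeg_surrogate(
    sampling_rate_hz: float,
    n_samples: int,
    band_low_hz: float = 0.5,
    band_high_hz: float = 70.0,
    seed: int = 0,
    rms: float = 1.0,
    filter_order: int = 4,
    spectral_exponent: float = 2.0,
) -> SampledSignal:
    """Band-limited Gaussian surrogate for an EEG channel.

    White Gaussian noise is spectrally shaped to a power spectrum falling as
    ``1 / f**spectral_exponent`` (the 1/f^2 default matches the steep spectra
    of clinical scalp EEG, dominated by slow activity), then passed through a
    zero-phase Butterworth band-pass (default corners [0.5, 70] Hz, a typical
    acquisition band) and rescaled to the requested RMS.  Deterministic per
    seed.  ``spectral_exponent=0`` gives a flat in-band spectrum.  This
    emulates only the second-order statistics of EEG — see the methods note.
    """
    nyq = sampling_rate_hz / 2.0
    if not (0 < band_low_hz < band_high_hz < nyq):
        raise ValueError(
            f"band corners must satisfy 0 < low < high < Nyquist ({nyq} Hz); "
            f"got [{band_low_hz}, {band_high_hz}]"
        )
    if n_samples < 2:
        raise ValueError("n_samples must be at least 2")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n_samples)
    if spectral_exponent != 0.0:
        coef = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n_samples, 1.0 / sampling_rate_hz)
        # flat below the low corner so the shaping gain stays bounded
        coef *= np.maximum(freqs, band_low_hz) ** (-spectral_exponent / 2.0)
        white = np.fft.irfft(coef, n_samples)
    sos = _sig.butter(
        filter_order, [band_low_hz, band_high_hz], btype="bandpass",
        fs=sampling_rate_hz, output="sos",
    )
    shaped = _sig.sosfiltfilt(sos, white)
    shaped_rms = np.sqrt(np.mean(shaped**2))
    return SampledSignal(shaped * (rms / shaped_rms), sampling_rate_hz)


def compose(clean: SampledSignal, artifact: SampledSignal) -> SampledSignal:
    """Element-wise sum of two signals of equal length and rate."""
    if clean.n_samples != artifact.n_samples:
        raise ValueError(
            f"length mismatch: {clean.n_samples} vs {artifact.n_samples}"
        )
    if clean.sampling_rate_hz != artifact.sampling_rate_hz:
        raise ValueError(
            f"sampling-rate mismatch: {clean.sampling_rate_hz} vs "
            f"{artifact.sampling_rate_hz}"
        )
    return SampledSignal(clean.samples + artifact.samples, clean.sampling_rate_hz)
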