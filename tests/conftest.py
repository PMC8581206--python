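import numpy as np
import pytest

from placlean import HarmonicParams, SampledSignal, generate_sinusoid

# the worked-example operating point: unit tone at 250.05 Hz, fs = N = 1000,
# spectral resolution 1 Hz, normalised offset 0.05
WORKED_PARAMS = HarmonicParams(amplitude=1.0, frequency_hz=250.05, phase_rad=0.0)
WORKED_FS = 1000.0
WORKED_N = 1000


@pytest.fixture(scope="session")
def worked_tone() -> SampledSignal:
    """Noise-free simulated power-line tone of the worked example."""
    return generate_sinusoid(WORKED_PARAMS, WORKED_FS, WORKED_N)


def brute_force_fit(signal: SampledSignal, f_low: float, f_high: float):
    """Independent sinusoid fit: dense frequency grid + exact LSQ per frequency.

    Scans frequencies at 1e-2 * delta_f resolution over [f_low, f_high], then
    refines at 1e-4 * delta_f around the coarse optimum.  At each candidate
    frequency the amplitude/phase least-squares problem
    ``x[n] ~ a*cos(w n) + b*sin(w n)`` is solved in closed form and the
    residual sum of squares recorded.  Returns (amplitude, frequency, phase).
    """
    x = signal.samples
    n = np.arange(signal.n_samples)
    df = signal.sampling_rate_hz / signal.n_samples

    def scan(freqs):
        best = (np.inf, None, None, None)
        for f in freqs:
            w = 2 * np.pi * f / signal.sampling_rate_hz
            c, s = np.cos(w * n), np.sin(w * n)
            g = np.array([[c @ c, c @ s], [c @ s, s @ s]])
            rhs = np.array([c @ x, s @ x])
            a, b = np.linalg.solve(g, rhs)
            rss = x @ x - a * rhs[0] - b * rhs[1]
            if rss < best[0]:
                best = (rss, f, a, b)
        return best

    coarse = scan(np.arange(f_low, f_high + 1e-12, 1e-2 * df))
    f0 = coarse[1]
    lo = max(f_low, f0 - 2e-2 * df)
    hi = min(f_high, f0 + 2e-2 * df)
    _, f, a, b = scan(np.arange(lo, hi + 1e-12, 1e-4 * df))
    amplitude = float(np.hypot(a, b))
    phase = float(np.arctan2(-b, a))
    return amplitude, float(f), phase
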