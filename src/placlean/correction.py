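"""Ratio-based spectrum correction (RBSC) and the dual-step algorithm (DSCA).

RBSC turns the two baseline spectral lines (BSSLs) that straddle an off-grid
tone into estimates of the tone's amplitude, frequency and phase.  With a
rectangular window the normalised frequency offset of the tone above the left
line is recovered from the amplitude ratio alone::

    delta_k = y_r / (y_l + y_r)          in [0, 1)

and the harmonic parameters follow as::

    A   = y_l * pi*delta_k / sin(pi*delta_k)
    f   = f_l + delta_k * delta_f
    phi = arg(Y_l) - pi * delta_k * kappa

where kappa is the phase-slope factor: 1.0 is the conventional leakage model;
(N-1)/N is the exact rectangular-window value (the difference is O(pi*dk/N)).

When delta_k is small the right line sits deep in the leakage skirt and its
SNR collapses, degrading the estimate under noise.  The dual-step algorithm
(DSCA) fixes this: a first RBSC pass gives a rough frequency f1, then two
spectral lines are re-evaluated off-grid at f1 ± 0.5*delta_f — both now of
comparable, high amplitude — and a second RBSC pass refines frequency and
phase.  The final estimate keeps the amplitude from pass 1 and frequency and
phase from pass 2.  No iteration beyond these two fixed passes is performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

from .signal_model import HarmonicParams, SampledSignal, wrap_phase
from .spectral import (
    BsslPair,
    SpectralLine,
    compute_spectrum,
    evaluate_dtft_line,
    locate_bssl,
)

__all__ = [
    "EstimationRound",
    "DscaResult",
    "rbsc_delta_k",
    "rbsc_estimate",
    "rbsc_estimate_signal",
    "dsca_estimate",
]

# below this, pi*dk/sin(pi*dk) is evaluated at its limit 1 (removable
# singularity of the leakage correction factor)
_DK_SINGULARITY = 1e-12


@dataclass(frozen=True)
class EstimationRound:
    """One RBSC pass: the line pair it consumed and the parameters it produced."""

    round_index: int
    pair: BsslPair
    ratio: float
    delta_k: float
    params: HarmonicParams


@dataclass(frozen=True)
class DscaResult:
    """Both DSCA rounds plus the merged final parameters.

    The final estimate takes amplitude from round 1 and frequency and phase
    from round 2; both rounds are retained for inspection.
    """

    round1: EstimationRound
    round2: EstimationRound
    final: HarmonicParams


def rbsc_delta_k(pair: BsslPair) -> float:
    """Normalised frequency shift of the tone above the left line, in bins.

    ``delta_k = y_r / (y_l + y_r) = (f_c - f_l) / delta_f``, in [0, 1).
    """
    y_l, y_r = pair.left.amplitude, pair.right.amplitude
    if y_l + y_r <= 0:
        raise ValueError("both line amplitudes are zero: no tone to correct")
    return y_r / (y_l + y_r)


def _sinc_correction(delta_k: float) -> float:
    if abs(delta_k) < _DK_SINGULARITY:
        return 1.0
    return math.pi * delta_k / math.sin(math.pi * delta_k)


def rbsc_estimate(pair: BsslPair, phase_slope_factor: float = 1.0) -> HarmonicParams:
    """Harmonic parameters from one BSSL pair (single RBSC pass).

    ``phase_slope_factor`` is the kappa in ``phi = arg(Y_l) - pi*dk*kappa``;
    the default 1.0 is the conventional correction, (N-1)/N the exact one.
    """
    dk = rbsc_delta_k(pair)
    amplitude = pair.left.amplitude * _sinc_correction(dk)
    frequency = pair.left.frequency_hz + dk * pair.spacing_hz
    phase = wrap_phase(
        pair.left.phase_rad - math.pi * dk * phase_slope_factor
    )
    return HarmonicParams(amplitude=amplitude, frequency_hz=frequency,
                          phase_rad=phase)


def _round_from_pair(
    index: int, pair: BsslPair, phase_slope_factor: float
) -> EstimationRound:
    dk = rbsc_delta_k(pair)
    ratio = pair.left.amplitude / pair.right.amplitude if pair.right.amplitude > 0 \
        else math.inf
    return EstimationRound(
        round_index=index,
        pair=pair,
        ratio=ratio,
        delta_k=dk,
        params=rbsc_estimate(pair, phase_slope_factor),
    )


def rbsc_estimate_signal(
    signal: SampledSignal,
    search_band_hz: Optional[Tuple[float, float]] = None,
    phase_slope_factor: float = 1.0,
) -> EstimationRound:
    """Single-pass RBSC on a signal: FFT, peak-pair location, ratio correction."""
    spectrum = compute_spectrum(signal)
    pair = locate_bssl(spectrum, search_band_hz)
    return _round_from_pair(1, pair, phase_slope_factor)


def dsca_estimate(
    signal: SampledSignal,
    search_band_hz: Optional[Tuple[float, float]] = None,
    exact_phase_slope: bool = False,
) -> DscaResult:
    """Dual-step spectrum correction on a signal.

    Round 1 runs RBSC on the FFT grid.  Round 2 re-evaluates two spectral
    lines at ``f1 -/+ 0.5*delta_f`` (generally off-grid, both of high
    amplitude) and runs RBSC on that pair, referencing frequency to the lower
    off-grid line.  Final parameters: amplitude from round 1, frequency and
    phase from round 2.
    """
    kappa = (signal.n_samples - 1) / signal.n_samples if exact_phase_slope else 1.0
    spectrum = compute_spectrum(signal)
    pair1 = locate_bssl(spectrum, search_band_hz)
    round1 = _round_from_pair(1, pair1, kappa)

    df = spectrum.bin_spacing_hz
    f1 = round1.params.frequency_hz
    f_lo, f_hi = f1 - 0.5 * df, f1 + 0.5 * df
    if f_lo <= 0:
        raise ValueError(
            f"round-2 left line at {f_lo} Hz is non-positive; "
            "first-round frequency too close to the band edge"
        )
    pair2 = BsslPair(
        left=evaluate_dtft_line(signal, f_lo),
        right=evaluate_dtft_line(signal, f_hi),
        spacing_hz=df,
    )
    round2 = _round_from_pair(2, pair2, kappa)

    final = HarmonicParams(
        amplitude=round1.params.amplitude,
        frequency_hz=round2.params.frequency_hz,
        phase_rad=round2.params.phase_rad,
    )
    return DscaResult(round1=round1, round2=round2, final=final)
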