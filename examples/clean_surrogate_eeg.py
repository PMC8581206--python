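"""Remove a mains tone from an EEG-like record: subtraction vs notch filter.

Emulates a contaminated clinical recording — a band-limited 1/f^2 surrogate
EEG (200 Hz, 5 s, acquisition band [0.5, 70] Hz) plus a strong 50.05 Hz
power-line sinusoid of amplitude 50 (EEG-to-artifact power ratio ~3.4 dB) —
then cleans it two ways and compares each result with the known clean EEG.
"""

import math

from placlean import (
    HarmonicParams,
    compose,
    generate_sinusoid,
    remove_pla,
    snr_db_between,
    synth_eeg_surrogate,
)

fs, n = 200.0, 1000
pla_params = HarmonicParams(amplitude=50.0, frequency_hz=50.05, phase_rad=0.0)
eeg_rms = pla_params.amplitude / math.sqrt(2) * 10 ** (3.43 / 20)

eeg = synth_eeg_surrogate(fs, n, 0.5, 70.0, seed=7, rms=eeg_rms)
pla = generate_sinusoid(pla_params, fs, n)
noisy = compose(eeg, pla)
print(f"EEG-to-artifact power ratio: {snr_db_between(eeg, pla):.2f} dB")

dsca = remove_pla(noisy, method="dsca", reference=eeg)
print(f"estimated artifact: A={dsca.estimate.amplitude:.3f}  "
      f"f={dsca.estimate.frequency_hz:.3f} Hz  "
      f"phi={dsca.estimate.phase_rad:.3f} rad")
print(f"subtractive cleaning: corr={dsca.correlation_vs_reference:.4f}  "
      f"residual RMS={dsca.residual_rms:.3f}")

notch = remove_pla(noisy, method="notch", reference=eeg, notch_center_hz=50.0)
print(f"causal 50 Hz notch:   corr={notch.correlation_vs_reference:.4f}  "
      f"residual RMS={notch.residual_rms:.3f}")
# The subtracted compensation signal cancels only the estimated sinusoid, so
# the cleaned record stays essentially identical to the true EEG (corr ~1);
# the notch filter's start-up transient and stop-band distort the waveform,
# which shows up as a lower correlation and larger residual.
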