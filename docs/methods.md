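# Methods

## Signal model and assumptions

A contaminated recording is modelled as `x[n] = eeg[n] + A·cos(2π f n/f_s + φ)`
for `n = 0 … N−1`: one additive mains sinusoid whose parameters are constant
over the record, plus arbitrary physiological content. Phase is referenced to
the first sample (t = 0 at n = 0) everywhere, and all returned phases are
wrapped to (−π, π]. The estimators assume a single dominant tone inside the
search band; harmonics of the mains (100/150 Hz …) are not modelled jointly —
callers can run the removal repeatedly, once per harmonic.

## Spectrum convention

`compute_spectrum` is the rectangular-window real FFT with negative-exponent
convention, scaled single-sided: interior bins by 2/N, the DC bin and (for
even N) the Nyquist bin by 1/N. With this scaling a noise-free on-grid
sinusoid of amplitude A reads exactly A at its bin, so line amplitudes are in
signal units. `evaluate_dtft_line` computes the identical quantity at an
arbitrary frequency by the direct O(N) sum `(2/N)·Σ x[n]·e^(−i2πfn/f_s)`; it
is exact at any frequency and cheaper than zero-padding, since the dual-step
algorithm only ever needs two off-grid lines.

## The estimators

Single-pass correction (RBSC): locate the interior spectrum peak (optionally
inside a search band), pair it with its larger neighbour, and apply

- offset: `Δk = y_r / (y_l + y_r)` ∈ [0, 1)
- amplitude: `A = y_l · πΔk / sin(πΔk)`, with the removable singularity at
  Δk → 0 evaluated as 1 (threshold 1e−12)
- frequency: `f = f_l + Δk·Δf`
- phase: `φ = arg(Y_l) − π·Δk·κ`

κ is the phase-slope factor. The exact rectangular-window value is
(N−1)/N; the conventional approximation is 1. The default is κ = 1, with
`exact_phase_slope=True` switching to (N−1)/N — the difference is O(πΔk/N),
about 1.6e−4 rad in the worked example.

Dual-step (DSCA): run RBSC on the grid (round 1), then build a second line
pair at `f⁽¹⁾ ± 0.5Δf` via `evaluate_dtft_line` and run RBSC on it, with the
frequency referenced to the lower off-grid line (round 2). Merge: amplitude
from round 1, frequency and phase from round 2. Exactly two passes; no
iteration. Round 2's pair is symmetric around f⁽¹⁾, so both lines carry
~64% of the tone amplitude regardless of the original Δk — this is what
restores the estimate's noise robustness when Δk is small.

When the two neighbours of the peak tie to within 1e−12 (relative), the
(k, k+1) pair is chosen; Δk = 0 then yields f = f_k either way, the rule
just makes results deterministic.

Default search band for EEG cleaning: 45–65 Hz (mains nominal 50/60 Hz plus
a few Hz of grid drift), preventing lock-on to EEG rhythms; parameter
estimation on generic signals defaults to the full band. Both overridable.

## Noise-free accuracy limit

Only the single-sided spectrum is used, so the negative-frequency image of
the tone perturbs every measured line by roughly
`1/(N·sin(π(f_s − 2f)/f_s))` bins' worth of amplitude — about 1.3e−3–1.7e−3
(relative to A) for f ∈ (100, 400) Hz at N = 1000. Propagated through the
ratio, this puts a floor of order 1e−3·Δf on the noise-free frequency error.
Measured over 2000 random tones: worst-case frequency error 4.3e−3·Δf for
the single pass and 1.3e−3·Δf for the dual step; amplitude errors stay below
0.05% and phase errors below 0.008 rad. Unit-test tolerances (5e−3·Δf and
2e−3·Δf) are small multiples of this analytic scale. Per tone, either method
can win by a hair on noise-free data — both sit on the same image-term
floor — but the dual step's worst case and RMS over an ensemble are strictly
better, and under noise its advantage at small Δk is large (about five-fold
in frequency RMSE at SNR 0 dB, Δk = 0.05).

## Synthetic data

- Tones: exact closed-form sampling of `A·cos(2πf n/f_s + φ)`; frequencies
  strictly below Nyquist are enforced.
- Noise: white Gaussian, σ derived from the clean signal's realised RMS as
  `σ = rms·10^(−SNR/20)`, so SNR is a mean-square power ratio in dB. Every
  stochastic function takes an explicit integer seed; there is no hidden
  global random state.
- EEG surrogate: white Gaussian noise spectrally shaped to a `1/f²` in-band
  power spectrum, passed forward-backward through a 4th-order Butterworth
  band-pass (default [0.5, 70] Hz) and scaled to a requested RMS. The 1/f²
  exponent reflects the steep spectra of clinical scalp EEG, which is
  dominated by slow activity and nearly empty near 50 Hz; a flat in-band
  spectrum (`spectral_exponent=0`) would place ~9% relative contamination on
  the artifact's spectral lines at the case-study operating point — far more
  than any real recording shows — and correspondingly exaggerate estimator
  error. The surrogate emulates second-order statistics only: no alpha
  peak, no non-stationarity, no transients or physiological artifacts. Tests
  that pass on it therefore demonstrate correct estimation and subtraction
  against band-limited 1/f-type background, not robustness to every feature
  of clinical EEG.
- Case-study emulation: 200 Hz sampling, 1000 samples, artifact amplitude
  50 at 50.05 Hz (a mains-like tone with half-bin offset Δk = 0.25 at
  Δf = 0.2 Hz), surrogate RMS chosen so the EEG-to-artifact power ratio is
  3.43 dB.

## Removal and the notch baseline

Subtractive cleaning synthesises the estimated sinusoid over the full record
and subtracts it; cleaned + compensation reconstructs the input to floating-
point rounding (~1e−14 relative). The comparison baseline is a second-order
IIR notch (`scipy.signal.iirnotch`, default Q = 30) applied causally —
forward only — so its start-up transient is visible at the record's left
edge, the characteristic time-domain distortion subtraction avoids. Reports
carry Pearson correlation against a clean reference plus residual RMS, since
correlation saturates near 1.

## Monte-Carlo benchmark

`run_monte_carlo` sweeps an SNR × Δk grid; each cell derives its tone
frequency as `(⌊f_base/Δf⌋ + Δk)·Δf` and its RNG stream from
`SeedSequence(master_seed, spawn_key=(snr_index, dk_index))`, making the
whole table reproducible from one integer while keeping cells independent.
Estimator failures in a trial (e.g. peak mislocation at very low SNR) are
counted and excluded from the moments; cells with >1% failures are flagged.
Phase error is the wrapped difference in (−π, π]. Default problem sizes
(500 trials per cell, N = 1000) run in well under a minute.

## Design choices on genuinely open points

- The printed form of the ratio formula in the source material is
  sign-inconsistent with its own worked numbers; the implementation uses
  `Δk = y_r/(y_l + y_r)`, the form that reproduces the worked values.
- Off-grid lines are computed by direct summation rather than zero-padded
  FFT: exact, O(N), and only two lines are needed per estimate.
- Round 2's Δk is measured from the lower off-grid line
  (`f⁽²⁾ = f⁽¹⁾ − 0.5Δf + Δk₂·Δf`) — the only reading consistent with a
  pair constructed symmetrically around f⁽¹⁾.
- The amplitude/phase formulas are applied unchanged in round 2 even though
  Δk₂ ≈ 0.5 there; the sinc correction is well-conditioned in that regime.
- Benchmark tables are plain pandas DataFrames written as TSV, one row per
  (SNR, Δk, method) cell.

## Known limitations

- Single-tone model: multiple simultaneous interferers, or strong narrowband
  EEG rhythms inside the search band, violate the peak-location assumption.
- Amplitude and frequency are assumed constant over the record; slow mains
  drift within a record biases the estimate toward an average tone.
- The negative-frequency image term bounds noise-free accuracy at
  ~1e−3 bins (see above); records much shorter than N = 1000 widen it.
- The EDF reader handles single channels read via mne only; BDF/BrainVision
  and multi-channel batch processing are out of scope.
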