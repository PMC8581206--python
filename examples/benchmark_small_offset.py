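"""When does the second correction round help?  A small Monte-Carlo sweep.

Runs both estimators on noisy tones (SNR 0 dB) at two normalised offsets:
delta_k = 0.05, where one baseline spectral line is buried in noise, and
delta_k = 0.5, where both lines are strong.  Prints the frequency RMSE of
each method and their ratio.
"""

from placlean import BenchmarkConfig, HarmonicParams, run_monte_carlo, summarize

config = BenchmarkConfig(
    snr_grid_db=[0.0],
    delta_k_grid=[0.05, 0.5],
    trials_per_cell=300,
    base_params=HarmonicParams(1.0, 250.0, 0.0),
    sampling_rate_hz=1000.0,
    n_samples=1000,
    master_seed=2,
)
table = run_monte_carlo(config)
summary = summarize(table)

for _, row in summary.iterrows():
    print(f"delta_k={row['delta_k']:.2f}:  "
          f"RMSE(f) single-pass={row['rmse_frequency_hz_rbsc']:.4f} Hz  "
          f"dual-step={row['rmse_frequency_hz_dsca']:.4f} Hz  "
          f"ratio={row['rmse_frequency_hz_ratio_dsca_rbsc']:.3f}")
# At delta_k = 0.05 the dual step cuts the frequency RMSE several-fold; at
# delta_k = 0.5 the two methods coincide (ratio ~1), matching the intuition
# that the second round only adds value when the first pair was lopsided.
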