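import math

import numpy as np
import pytest

from placlean import (
    BsslPair,
    HarmonicParams,
    NoiseSpec,
    SpectralLine,
    add_gaussian_noise,
    compute_spectrum,
    dsca_estimate,
    generate_sinusoid,
    locate_bssl,
    rbsc_delta_k,
    rbsc_estimate,
    rbsc_estimate_signal,
    wrap_phase,
)
from conftest import brute_force_fit


def _pair(y_l, y_r, f_l=250.0, df=1.0, phase_l=0.0):
    return BsslPair(
        left=SpectralLine(f_l, y_l, phase_l),
        right=SpectralLine(f_l + df, y_r, 0.0),
        spacing_hz=df,
    )


class TestRbscDeltaK:
    @pytest.mark.parametrize("y_l,y_r,expected", [
        (0.996, 0.052, 0.05),   # the worked example, 2-decimal precision
        (1.0, 0.0, 0.0),        # tone exactly on the left line
        (0.7, 0.7, 0.5),        # symmetric leakage
    ])
    def test_ratio_formula(self, y_l, y_r, expected):
        assert round(rbsc_delta_k(_pair(y_l, y_r)), 2) == expected

    def test_zero_pair_rejected(self):
        with pytest.raises(ValueError, match="no tone"):
            rbsc_delta_k(_pair(0.0, 0.0))


class TestRbscEstimate:
    def test_worked_example_noise_free_recovery(self, worked_tone):
        """Unit 250.05 Hz tone: RBSC recovers (1, 250.05, 0) at printed precision."""
        round1 = rbsc_estimate_signal(worked_tone)
        assert round(round1.params.amplitude, 2) == 1.0
        assert round(round1.params.frequency_hz, 2) == 250.05
        assert round(round1.params.phase_rad, 2) == 0.0

    def test_on_grid_tone_passes_through(self):
        pair = _pair(0.8, 0.0, f_l=100.0, phase_l=0.25)
        est = rbsc_estimate(pair)
        assert est.amplitude == pytest.approx(0.8)
        assert est.frequency_hz == pytest.approx(100.0)
        assert est.phase_rad == pytest.approx(0.25)

    def test_random_noise_free_tones_recovered(self):
        """100 random tones recovered to the single-sided-spectrum error floor.

        The only noise-free error source is the negative-frequency image,
        whose line magnitude is about 1/(N*sin(pi*(fs-2f)/fs)) in bins —
        at most ~1.7e-3 over f in (100, 400) at N = 1000.  The frequency
        bound 5e-3*df is a small multiple of that scale.
        """
        rng = np.random.default_rng(2024)
        fs, n = 1000.0, 1000
        df = fs / n
        for _ in range(100):
            truth = HarmonicParams(
                amplitude=rng.uniform(0.2, 5.0),
                frequency_hz=rng.uniform(100.0, 400.0),
                phase_rad=rng.uniform(-3.0, 3.0),
            )
            sig = generate_sinusoid(truth, fs, n)
            est = rbsc_estimate_signal(sig).params
            assert abs(est.frequency_hz - truth.frequency_hz) < 5e-3 * df
            assert abs(est.amplitude / truth.amplitude - 1) < 1e-2
            assert abs(wrap_phase(est.phase_rad - truth.phase_rad)) < 2e-2

    def test_exact_phase_slope_option_changes_little(self, worked_tone):
        nominal = rbsc_estimate_signal(worked_tone).params
        exact = rbsc_estimate_signal(
            worked_tone, phase_slope_factor=999 / 1000
        ).params
        # difference is O(pi*dk/N): tiny but nonzero
        diff = abs(wrap_phase(nominal.phase_rad - exact.phase_rad))
        assert 0 < diff < 1e-3


class TestDscaEstimate:
    def test_worked_example_final_parameters(self, worked_tone):
        result = dsca_estimate(worked_tone)
        assert round(result.final.amplitude, 2) == 1.0
        assert round(result.final.frequency_hz, 2) == 250.05
        assert round(result.final.phase_rad, 2) == 0.0

    def test_merge_rule(self, worked_tone):
        """Final = amplitude of round 1, frequency and phase of round 2."""
        r = dsca_estimate(worked_tone)
        assert r.final.amplitude == r.round1.params.amplitude
        assert r.final.frequency_hz == r.round2.params.frequency_hz
        assert r.final.phase_rad == r.round2.params.phase_rad

    def test_round2_pair_straddles_at_half_bin(self):
        """On-grid tone: round 2's lines sit at f±0.5df, so delta_k2 = 0.5."""
        sig = generate_sinusoid(HarmonicParams(1.0, 250.0, 0.1), 1000.0, 1000)
        r = dsca_estimate(sig)
        assert r.round2.delta_k == pytest.approx(0.5, abs=1e-3)
        # residual error is the negative-frequency image term, ~1e-4 bins here
        assert abs(r.final.frequency_hz - 250.0) < 1e-3 * 1.0

    def test_round2_geometry_for_off_grid_tones(self):
        """Round-2 delta_k stays near 0.5 when round 1 is accurate."""
        rng = np.random.default_rng(77)
        for _ in range(30):
            truth = HarmonicParams(1.0, rng.uniform(100.0, 400.0), 0.0)
            sig = generate_sinusoid(truth, 1000.0, 1000)
            r = dsca_estimate(sig)
            assert abs(r.round1.params.frequency_hz - truth.frequency_hz) < 0.1
            assert 0.4 <= r.round2.delta_k <= 0.6

    def test_noise_free_dsca_no_worse_in_aggregate(self):
        """Over an ensemble of noise-free tones the dual step dominates.

        Per-tone either method can win by a hair (both sit on the same
        negative-frequency-image error floor), but DSCA's second-round lines
        are always high-amplitude, so its worst case and RMS error over an
        ensemble are no worse than single-pass RBSC's.
        """
        rng = np.random.default_rng(31)
        err_rbsc, err_dsca = [], []
        for _ in range(60):
            truth = HarmonicParams(1.0, rng.uniform(100.0, 400.0), 0.5)
            sig = generate_sinusoid(truth, 1000.0, 1000)
            err_rbsc.append(abs(
                rbsc_estimate_signal(sig).params.frequency_hz
                - truth.frequency_hz
            ))
            err_dsca.append(abs(
                dsca_estimate(sig).final.frequency_hz - truth.frequency_hz
            ))
        assert max(err_dsca) <= max(err_rbsc)
        assert np.sqrt(np.mean(np.square(err_dsca))) <= np.sqrt(
            np.mean(np.square(err_rbsc))
        )

    def test_oracle_equivalence_noise_free(self):
        """DSCA matches the dense-grid + least-squares brute-force fit.

        The 2e-3*df frequency tolerance is the dual-step image-leakage
        ceiling (the oracle itself is exact to 1e-4*df).
        """
        rng = np.random.default_rng(55)
        fs, n = 1000.0, 1000
        df = fs / n
        for _ in range(8):
            truth = HarmonicParams(
                rng.uniform(0.5, 3.0), rng.uniform(150.0, 350.0),
                rng.uniform(-2.0, 2.0),
            )
            sig = generate_sinusoid(truth, fs, n)
            est = dsca_estimate(sig).final
            a_o, f_o, p_o = brute_force_fit(
                sig, truth.frequency_hz - df, truth.frequency_hz + df
            )
            assert abs(est.frequency_hz - f_o) < 2e-3 * df
            assert abs(est.amplitude / a_o - 1) < 1e-2
            assert abs(wrap_phase(est.phase_rad - p_o)) < 2e-2

    def test_phase_always_wrapped(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            truth = HarmonicParams(
                1.0, rng.uniform(100.0, 400.0), rng.uniform(-math.pi, math.pi)
            )
            sig = generate_sinusoid(truth, 1000.0, 1000)
            r = dsca_estimate(sig)
            for p in (r.round1.params, r.round2.params, r.final):
                assert -math.pi < p.phase_rad <= math.pi

    def test_dsca_beats_rbsc_at_small_offset_under_noise(self):
        """SNR 0 dB, delta_k = 0.05: dual-step frequency RMSE <= single-pass."""
        truth = HarmonicParams(1.0, 250.05, 0.0)
        tone = generate_sinusoid(truth, 1000.0, 1000)
        err_rbsc, err_dsca = [], []
        for seed in range(200):
            noisy = add_gaussian_noise(tone, NoiseSpec(snr_db=0.0, seed=seed))
            err_rbsc.append(
                rbsc_estimate_signal(noisy).params.frequency_hz - 250.05
            )
            err_dsca.append(dsca_estimate(noisy).final.frequency_hz - 250.05)
        rmse_rbsc = np.sqrt(np.mean(np.square(err_rbsc)))
        rmse_dsca = np.sqrt(np.mean(np.square(err_dsca)))
        assert rmse_dsca <= rmse_rbsc

    def test_noisy_estimates_are_realization_specific(self):
        """Without a fixed seed, noisy-run outputs differ between realizations."""
        truth = HarmonicParams(1.0, 250.05, 0.0)
        tone = generate_sinusoid(truth, 1000.0, 1000)
        a = dsca_estimate(add_gaussian_noise(tone, NoiseSpec(0.0, seed=1)))
        b = dsca_estimate(add_gaussian_noise(tone, NoiseSpec(0.0, seed=2)))
        assert a.final.frequency_hz != b.final.frequency_hz
        assert a.round1.pair.left.amplitude != b.round1.pair.left.amplitude
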