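"""Reconvolution fitter: forward model, initial guesses, exact and
statistical parameter recovery, χ² calibration, and grid-oracle agreement."""

import numpy as np
import pytest

import tausense as ts
from tausense.reconvolution import initial_guess, reduced_chi_square
from tausense.synthetic import decay_expectation

from .conftest import make_delta_irf, reseed

MONO = ts.DecayModelParams(kind="mono", a=5.0, b1=1.0, tau1=3.086)
BI = ts.DecayModelParams(kind="bi", a=5.0, b1=1.0, tau1=1.0, b2=1.0, tau2=4.183)


def noiseless(params, irf, config):
    return ts.simulate_decay(params, irf, config, noise=False, quantize=False)


class TestConvolveModel:
    def test_delta_kernel_is_identity(self, mini_config, delta_irf):
        """With a one-channel prompt the expectation is the bare model + A."""
        exp = ts.convolve_model(delta_irf, MONO)
        t = mini_config.times - mini_config.times[0]
        np.testing.assert_allclose(exp, MONO.a + np.exp(-t / 3086.0), rtol=1e-12)

    def test_linear_in_amplitude(self, mini_irf):
        p1 = ts.DecayModelParams(kind="mono", a=3.0, b1=1.0, tau1=2.5)
        p2 = ts.DecayModelParams(kind="mono", a=3.0, b1=2.0, tau1=2.5)
        e1 = ts.convolve_model(mini_irf, p1)
        e2 = ts.convolve_model(mini_irf, p2)
        np.testing.assert_allclose(e2 - 3.0, 2.0 * (e1 - 3.0), rtol=1e-12)

    def test_hand_convolution_16_channels(self):
        """Prompt (0.25, 0.5, 0.25) at channels 2–4, mono τ = 5 channel
        widths, against an explicit by-hand convolution."""
        w = 100.0
        cfg = ts.InstrumentConfig(n_channels=16, channel_width=w, peak_target=1000,
                                  irf_center=3 * w, seed=0)
        irf_counts = np.zeros(16, dtype=np.int64)
        irf_counts[2:5] = [250, 500, 250]
        irf = ts.DecayHistogram(times=cfg.times, counts=irf_counts, role="prompt")
        tau = 5 * w / 1e3  # ns
        params = ts.DecayModelParams(kind="mono", a=2.0, b1=10.0, tau1=tau)
        exp = ts.convolve_model(irf, params)
        t = cfg.times - cfg.times[0]
        decay = 10.0 * np.exp(-t / (5 * w))
        hand = np.full(16, 2.0)
        for k in range(16):
            for j, wt in [(2, 0.25), (3, 0.5), (4, 0.25)]:
                if k - j >= 0:
                    hand[k] += wt * decay[k - j]
        np.testing.assert_allclose(exp, hand, rtol=1e-12)

    def test_all_zero_prompt_rejected(self, mini_config):
        with pytest.raises(ValueError):
            ts.DecayHistogram(times=mini_config.times,
                              counts=np.zeros(mini_config.n_channels, dtype=int))


class TestInitialGuess:
    def test_noiseless_mono_tau_within_5pct(self, mini_config, delta_irf):
        # lifetime short enough that the tail reaches the background floor
        # inside the 14 ns mini window, so the log-linear regression is clean
        params = ts.DecayModelParams(kind="mono", a=5.0, b1=1.0, tau1=1.5)
        hist = noiseless(params, delta_irf, mini_config)
        guess = initial_guess(hist, "mono")
        assert guess.tau1 == pytest.approx(1.5, rel=0.05)

    def test_flat_histogram_rejected(self, mini_config):
        flat = ts.DecayHistogram(
            times=mini_config.times,
            counts=np.full(mini_config.n_channels, 100, dtype=np.int64),
        )
        with pytest.raises(ValueError):
            initial_guess(flat)

    def test_baseline_recovered_from_noisy_data(self, ref_config, ref_irf):
        """The pre-rise baseline estimate lands within the Poisson error of
        the true background."""
        params = ts.DecayModelParams(kind="mono", a=50.0, b1=1.0, tau1=3.457)
        hist = ts.simulate_decay(params, ref_irf, reseed(ref_config, 1))
        guess = initial_guess(hist, "mono")
        n_baseline = int(2000.0 / 109.73) - 2  # channels before the prompt rise
        assert guess.a == pytest.approx(50.0, abs=3 * np.sqrt(50.0 / n_baseline))


class TestExactRecovery:
    """On noise-free data with a delta prompt both models are identifiable
    exactly; the optimizer must reach the truth to ≤1e-6 relative."""

    def test_mono(self, mini_config, delta_irf):
        hist = noiseless(MONO, delta_irf, mini_config)
        res = ts.fit_monoexponential(hist, delta_irf)
        assert res.converged
        assert res.params.tau1 == pytest.approx(3.086, rel=1e-6)

    def test_bi(self, mini_config, delta_irf):
        hist = noiseless(BI, delta_irf, mini_config)
        res = ts.fit_biexponential(hist, delta_irf)
        assert res.converged
        assert res.params.tau1 == pytest.approx(1.0, rel=1e-4)
        assert res.params.tau2 == pytest.approx(4.183, rel=1e-4)

    def test_bi_with_fixed_tau1(self, mini_config, delta_irf):
        """Clamping τ1 at truth leaves τ2 recovery unchanged and removes one
        free parameter."""
        hist = noiseless(BI, delta_irf, mini_config)
        free = ts.fit_biexponential(hist, delta_irf)
        fixed = ts.fit_biexponential(hist, delta_irf, fixed_tau1=1.0)
        assert fixed.params.tau2 == pytest.approx(4.183, rel=1e-6)
        assert "tau1" in fixed.fixed_mask
        assert "tau1" not in fixed.stderr
        assert len(fixed.stderr) == len(free.stderr) - 1


class TestFixedMask:
    def test_mono_fixed_tau_reports_free_only(self, mini_config, delta_irf):
        hist = ts.simulate_decay(MONO, delta_irf, reseed(mini_config, 3))
        res = ts.fit_monoexponential(hist, delta_irf, fixed={"tau1": 3.086})
        assert res.params.tau1 == 3.086
        assert "tau1" not in res.stderr
        assert res.params.b1 > 0
        assert set(res.stderr) == {"a", "b1", "shift"}


class TestStatisticalRecovery:
    def test_mono_reference_scale(self, ref_config, ref_irf):
        """Poisson decays at the reference settings: fitted τ lands within
        3 reported standard errors of the generating 3.457 ns and the
        reduced χ² of the fit sits in the calibrated band."""
        params = ts.DecayModelParams(kind="mono", a=50.0, b1=1.0, tau1=3.457)
        res = ts.fit_monoexponential(
            ts.simulate_decay(params, ref_irf, reseed(ref_config, 42)), ref_irf
        )
        assert res.converged
        assert abs(res.params.tau1 - 3.457) < 3 * res.stderr["tau1"]
        assert 0.8 <= res.chi2_red <= 1.2

    def test_bi_tau2_bias_and_coverage(self, ref_config, ref_irf):
        """Over 100 Poisson replicates at the reference settings with fixed
        τ1: relative bias of τ2 below 0.5% and ±2·stderr covers the truth
        for 88–99% of replicates."""
        params = ts.DecayModelParams(
            kind="bi", a=50.0, b1=1.0, tau1=1.0, b2=1.0, tau2=4.183
        )
        taus, ses = [], []
        for s in range(100):
            hist = ts.simulate_decay(params, ref_irf, reseed(ref_config, s))
            res = ts.fit_biexponential(hist, ref_irf, fixed_tau1=1.0)
            assert res.converged
            taus.append(res.params.tau2)
            ses.append(res.stderr["tau2"])
        taus, ses = np.array(taus), np.array(ses)
        assert abs(taus.mean() - 4.183) / 4.183 < 0.005
        coverage = np.mean(np.abs(taus - 4.183) < 2 * ses)
        assert 0.88 <= coverage <= 0.99

    def test_chi2_calibration_over_seeds(self, ref_config, ref_irf):
        """Reduced χ² of the generating model stays in [0.8, 1.2] in ≥95% of
        seeds at the full 1023-channel scale."""
        params = ts.DecayModelParams(kind="mono", a=50.0, b1=1.0, tau1=3.457)
        exp = decay_expectation(params, ref_irf, ref_config)
        in_band = 0
        n_seeds = 40
        for s in range(n_seeds):
            obs = ts.simulate_decay(params, ref_irf, reseed(ref_config, s)).counts
            chi2 = reduced_chi_square(obs, exp, 0)
            in_band += 0.8 <= chi2 <= 1.2
        assert in_band / n_seeds >= 0.95

    def test_label_convention_tau1_le_tau2(self, ref_config, ref_irf):
        params = ts.DecayModelParams(
            kind="bi", a=50.0, b1=1.0, tau1=1.0, b2=1.0, tau2=4.183
        )
        for s in range(5):
            hist = ts.simulate_decay(params, ref_irf, reseed(ref_config, s))
            res = ts.fit_biexponential(hist, ref_irf)
            assert res.params.tau1 <= res.params.tau2

    def test_bi_on_mono_data_collapses_with_warning(self, ref_config, ref_irf):
        """Fitting the two-component model to single-exponential data drives
        it degenerate; τ2 still tracks the generating lifetime."""
        params = ts.DecayModelParams(kind="mono", a=50.0, b1=1.0, tau1=3.457)
        hist = ts.simulate_decay(params, ref_irf, reseed(ref_config, 11))
        res = ts.fit_biexponential(hist, ref_irf)
        assert res.warnings
        assert res.params.tau2 == pytest.approx(3.457, rel=0.05)


class TestReducedChiSquare:
    def test_perfect_agreement_is_zero(self):
        obs = np.arange(1.0, 50.0)
        assert reduced_chi_square(obs, obs, 3) == 0.0

    def test_unit_residuals(self):
        """obs = exp + √exp on 100 channels with p=2: direct arithmetic gives
        Σ exp/(exp+√exp) / 98 — just under 100/98 because the weights use the
        observed counts."""
        exp = np.linspace(10, 1000, 100)
        obs = exp + np.sqrt(exp)
        val = reduced_chi_square(obs, exp, 2)
        assert val == pytest.approx(float(np.sum(exp / obs)) / 98, rel=1e-12)
        assert val == pytest.approx(100 / 98, rel=0.06)

    def test_too_many_params_rejected(self):
        with pytest.raises(ValueError):
            reduced_chi_square(np.ones(5), np.ones(5), 5)


class TestGridOracle:
    def test_optimizer_never_loses_to_oracle(self, mini_config, mini_irf):
        """Over 20 seeded small instances the optimizer's objective never
        exceeds the exhaustive grid minimum by more than grid-resolution
        slack."""
        params = ts.DecayModelParams(kind="mono", a=5.0, b1=1.0, tau1=3.0)
        grid = np.arange(0.5, 6.0, 0.05)
        for s in range(20):
            hist = ts.simulate_decay(params, mini_irf, reseed(mini_config, s))
            res = ts.fit_monoexponential(hist, mini_irf, fixed={"shift": 0.0})
            obs = np.asarray(hist.counts, float)
            fit_obj = float(
                np.sum(
                    (obs - ts.convolve_model(mini_irf, res.params)) ** 2
                    / np.maximum(obs, 1.0)
                )
            )
            _, oracle_obj = ts.grid_oracle_fit(hist, mini_irf, grid)
            assert fit_obj <= oracle_obj * (1 + 1e-6) + 1.0

    def test_oracle_finds_truth_on_noiseless_toy(self, mini_config, delta_irf):
        hist = noiseless(
            ts.DecayModelParams(kind="mono", a=5.0, b1=1.0, tau1=3.1),
            delta_irf, mini_config,
        )
        best, _ = ts.grid_oracle_fit(hist, delta_irf, np.arange(0.5, 6.0, 0.05))
        assert best.tau1 == pytest.approx(3.1, abs=0.051)

    def test_bi_toy_agreement_within_one_grid_step(self, mini_config, delta_irf):
        hist = ts.simulate_decay(BI, delta_irf, reseed(mini_config, 4))
        res = ts.fit_biexponential(hist, delta_irf, fixed={"shift": 0.0})
        grid = np.arange(0.5, 6.0, 0.05)
        best, _ = ts.grid_oracle_fit(hist, delta_irf, grid, grid)
        assert abs(res.params.tau1 - best.tau1) <= 0.101
        assert abs(res.params.tau2 - best.tau2) <= 0.101

    def test_oversized_grid_rejected(self, mini_config, delta_irf):
        hist = ts.simulate_decay(BI, delta_irf, reseed(mini_config, 4))
        big = np.linspace(0.5, 6.0, 1001)
        with pytest.raises(ValueError, match="grid"):
            ts.grid_oracle_fit(hist, delta_irf, big, big)


def test_mismatched_axes_rejected(mini_config, ref_irf):
    hist = ts.simulate_decay(MONO, make_delta_irf(mini_config), mini_config)
    with pytest.raises(ValueError, match="time axis"):
        ts.fit_monoexponential(hist, ref_irf)
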