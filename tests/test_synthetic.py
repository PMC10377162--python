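"""Generator correctness: IRF discretization, forward convolution,
Poisson noise statistics, titration construction and seeding."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import norm

import tausense as ts
from tausense.isotherms import predict_hill
from tausense.synthetic import (
    REFERENCE_HILL_1X,
    decay_expectation,
    default_concentration_grid,
    simulate_selectivity_panel,
)
from .conftest import make_delta_irf, reseed


class TestMakeIrf:
    def test_peak_at_center(self):
        cfg = ts.InstrumentConfig(irf_fwhm=500.0, irf_center=5000.0, seed=0)
        irf = ts.make_irf(cfg)
        assert irf.peak_channel == int(5000.0 / 109.73)
        assert irf.counts.max() == cfg.peak_target
        assert irf.normalized().sum() == pytest.approx(1.0, abs=1e-9)

    def test_narrow_fwhm_collapses_to_delta(self):
        cfg = ts.InstrumentConfig(
            n_channels=64, irf_fwhm=1e-6, irf_center=10.5 * 109.73, seed=0
        )
        irf = ts.make_irf(cfg)
        assert np.count_nonzero(irf.counts) == 1
        assert irf.peak_channel == 10

    def test_bin_weights_match_quadrature_oracle(self):
        """Channel weights equal the Gaussian integral over each bin,
        checked against numerical quadrature (FWHM = 2 channels, center on
        a channel boundary)."""
        w = 100.0
        cfg = ts.InstrumentConfig(
            n_channels=16, channel_width=w, irf_fwhm=2 * w, irf_center=8 * w,
            peak_target=100000, seed=0,
        )
        sigma = 2 * w / (2 * np.sqrt(2 * np.log(2)))
        oracle = np.array(
            [
                quad(lambda t: norm.pdf(t, loc=8 * w, scale=sigma), i * w, (i + 1) * w)[0]
                for i in range(16)
            ]
        )
        oracle /= oracle.sum()
        irf = ts.make_irf(cfg)
        np.testing.assert_allclose(irf.normalized(), oracle, atol=2e-5)

    def test_truncated_prompt_rejected(self):
        cfg = ts.InstrumentConfig(n_channels=64, irf_center=64 * 109.73 + 1, seed=0)
        with pytest.raises(ValueError, match="window"):
            ts.make_irf(cfg)


class TestSimulateDecay:
    def test_mono_delta_irf_is_bare_exponential(self, mini_config):
        """With a one-channel prompt the expectation is the exponential law
        itself, peaking in the first channel."""
        delta = make_delta_irf(mini_config)
        params = ts.DecayModelParams(kind="mono", a=0.0, b1=1.0, tau1=3.086)
        hist = ts.simulate_decay(params, delta, mini_config, noise=False, quantize=False)
        t = mini_config.times - mini_config.times[0]
        expected = np.exp(-t / 3086.0)
        expected *= hist.counts[0] / expected[0]
        np.testing.assert_allclose(hist.counts, expected, rtol=1e-9)
        assert hist.peak_channel == 0

    def test_counts_conserved_under_convolution(self, mini_config, mini_irf):
        """Total expected counts equal the sum of the convolved series
        computed independently (double loop)."""
        params = ts.DecayModelParams(
            kind="bi", a=0.0, b1=2.0, tau1=1.0, b2=1.0, tau2=4.183
        )
        exp = decay_expectation(params, mini_irf, mini_config)
        kernel = mini_irf.normalized()
        decay = params.evaluate(mini_config.times)
        n = mini_config.n_channels
        manual = np.zeros(n)
        for k in range(n):
            for j in range(k + 1):
                manual[k] += kernel[j] * decay[k - j]
        manual *= mini_config.peak_target / manual.max()
        np.testing.assert_allclose(exp, manual, rtol=1e-6)

    def test_expectation_matches_hand_convolution_16ch(self):
        """3-channel prompt against a by-hand convolution on a 16-channel
        miniature instrument."""
        w = 109.73
        cfg = ts.InstrumentConfig(
            n_channels=16, channel_width=w, peak_target=1000,
            irf_fwhm=500.0, irf_center=3.5 * w, seed=0,
        )
        irf_counts = np.zeros(16, dtype=np.int64)
        irf_counts[2:5] = [250, 500, 250]
        irf = ts.DecayHistogram(times=cfg.times, counts=irf_counts, role="prompt")
        params = ts.DecayModelParams(
            kind="bi", a=0.0, b1=1.0, tau1=1.0, b2=1.0, tau2=4.183
        )
        exp = decay_expectation(params, irf, cfg)
        t = cfg.times
        decay = np.exp(-t / 1000.0) + np.exp(-t / 4183.0)
        hand = np.zeros(16)
        for k in range(16):
            for j, wt in [(2, 0.25), (3, 0.5), (4, 0.25)]:
                if k - j >= 0:
                    hand[k] += wt * decay[k - j]
        hand *= cfg.peak_target / hand.max()
        np.testing.assert_allclose(exp, hand, rtol=1e-9)

    def test_noiseless_peak_hits_target(self, mini_config, mini_irf):
        params = ts.DecayModelParams(kind="mono", a=5.0, b1=1.0, tau1=4.0)
        hist = ts.simulate_decay(params, mini_irf, mini_config, noise=False)
        assert hist.counts.max() == mini_config.peak_target

    def test_counts_are_nonnegative_integers(self, mini_config, mini_irf):
        params = ts.DecayModelParams(kind="mono", a=2.0, b1=1.0, tau1=4.0)
        hist = ts.simulate_decay(params, mini_irf, reseed(mini_config, 5))
        assert np.issubdtype(hist.counts.dtype, np.integer)
        assert np.all(hist.counts >= 0)

    def test_seed_determinism_and_sensitivity(self, mini_config, mini_irf):
        params = ts.DecayModelParams(kind="mono", a=2.0, b1=1.0, tau1=4.0)
        a = ts.simulate_decay(params, mini_irf, reseed(mini_config, 7))
        b = ts.simulate_decay(params, mini_irf, reseed(mini_config, 7))
        c = ts.simulate_decay(params, mini_irf, reseed(mini_config, 8))
        assert np.array_equal(a.counts, b.counts)
        assert not np.array_equal(a.counts, c.counts)

    def test_poisson_mean_matches_expectation(self, mini_config, mini_irf):
        """Mean of 200 Poisson realizations tracks the noiseless expectation
        within 3·√(expectation/200) per channel."""
        params = ts.DecayModelParams(kind="mono", a=5.0, b1=1.0, tau1=4.0)
        exp = decay_expectation(params, mini_irf, mini_config)
        acc = np.zeros_like(exp)
        n_rep = 200
        for s in range(n_rep):
            acc += ts.simulate_decay(params, mini_irf, reseed(mini_config, s)).counts
        mean = acc / n_rep
        tol = 3.0 * np.sqrt(exp / n_rep)
        assert np.all(np.abs(mean - exp) <= np.maximum(tol, 1e-9))

    def test_under_resolved_lifetime_warns(self, mini_config, mini_irf):
        params = ts.DecayModelParams(kind="mono", a=0.0, b1=1.0, tau1=0.001)
        with pytest.warns(UserWarning, match="under-resolved"):
            decay_expectation(params, mini_irf, mini_config)


class TestDecayTitration:
    template = ts.DecayModelParams(
        kind="bi", a=10.0, b1=1.0, tau1=1.0, b2=1.0, tau2=4.183
    )

    def test_generating_tau2_follows_hill(self, mini_config, mini_irf):
        """τ₂ at EC50 is the midpoint 4.083 ns; far above EC50 it saturates
        at 3.983 ns; at vanishing analyte it returns the blank 4.183 ns."""
        assert predict_hill(REFERENCE_HILL_1X, 18e-12) == pytest.approx(4.083, abs=1e-12)
        assert predict_hill(REFERENCE_HILL_1X, 1e-20) == pytest.approx(4.183, abs=1e-6)
        assert predict_hill(REFERENCE_HILL_1X, 150e-9) == pytest.approx(3.983, abs=1e-4)

    def test_titration_decays_encode_hill_tau2(self, mini_config, mini_irf):
        concs = [1e-13, 18e-12, 150e-9]
        out = ts.simulate_decay_titration(
            REFERENCE_HILL_1X, concs, self.template, mini_irf, mini_config, noise=False
        )
        assert [c for c, _ in out] == concs
        # the 150 nM decay is strictly faster than the 100 fM decay in the tail
        tail = slice(mini_config.n_channels // 2, None)
        assert out[2][1].counts[tail].sum() < out[0][1].counts[tail].sum()

    def test_distinct_child_seeds(self, mini_config, mini_irf):
        out = ts.simulate_decay_titration(
            REFERENCE_HILL_1X, [1e-12, 1e-12 * (1 + 1e-9)], self.template,
            mini_irf, mini_config,
        )
        assert not np.array_equal(out[0][1].counts, out[1][1].counts)

    def test_empty_concentrations_rejected(self, mini_config, mini_irf):
        with pytest.raises(ValueError, match="empty"):
            ts.simulate_decay_titration(
                REFERENCE_HILL_1X, [], self.template, mini_irf, mini_config
            )


class TestResponseTitration:
    def test_langmuir_midpoint(self):
        """At x = k the noise-free Langmuir response is the plateau
        midpoint (34399 + 23103)/2 = 28751 rfu."""
        series = ts.simulate_response_titration(
            ts.LangmuirParams(start=34399, end=23103, k=30e-12),
            [1e-15, 30e-12, 1e-9, 1e-7],
            noise_sd=0.0,
            replicates=1,
            seed=0,
        )
        assert series.responses[1][0] == pytest.approx(28751.0, abs=1e-9)
        assert series.response_kind == "intensity"

    def test_zero_analyte_limit_is_start(self):
        series = ts.simulate_response_titration(
            ts.LangmuirParams(start=34399, end=23103, k=30e-12),
            [1e-30, 30e-12, 1e-9, 1e-7],
            noise_sd=0.0,
            replicates=1,
            seed=0,
        )
        assert series.responses[0][0] == pytest.approx(34399.0, abs=1e-6)

    def test_noise_sd_is_calibrated(self):
        """Pointwise replicate scatter matches the requested sd (Monte Carlo
        over many replicates)."""
        series = ts.simulate_response_titration(
            REFERENCE_HILL_1X, default_concentration_grid(),
            noise_sd=0.009, replicates=400, seed=3,
        )
        sds = np.array([r.std(ddof=1) for r in series.responses])
        np.testing.assert_allclose(sds, 0.009, rtol=0.15)

    def test_seeded_reproducibility(self):
        a = ts.simulate_response_titration(
            REFERENCE_HILL_1X, default_concentration_grid(), 0.009, 3, seed=9
        )
        b = ts.simulate_response_titration(
            REFERENCE_HILL_1X, default_concentration_grid(), 0.009, 3, seed=9
        )
        for x, y in zip(a.responses, b.responses):
            np.testing.assert_array_equal(x, y)


class TestSelectivityPanel:
    def test_construction_values(self):
        """Template row follows the Hill curve (4.083 ns at EC50); all
        non-binders sit at the blank lifetime."""
        panel = simulate_selectivity_panel(
            REFERENCE_HILL_1X, ["BSA", "HTR", "ovalbumin", "lysozyme"],
            concentration=18e-12, seed=0, noise_sd=0.0,
        )
        hsa = panel[panel.label == "HSA"]["tau2_ns"]
        assert np.allclose(hsa, 4.083)
        for name in ["BSA", "HTR", "ovalbumin", "lysozyme"]:
            assert np.allclose(panel[panel.label == name]["tau2_ns"], 4.183)

    def test_empty_nonbinder_list(self):
        panel = simulate_selectivity_panel(
            REFERENCE_HILL_1X, [], concentration=18e-12, seed=0, replicates=1
        )
        assert set(panel.label) == {"blank", "HSA"}

    def test_drift_is_additive(self):
        panel = simulate_selectivity_panel(
            REFERENCE_HILL_1X, ["BSA"], concentration=18e-12, seed=0,
            noise_sd=0.0, drift={"BSA": 0.01},
        )
        assert np.allclose(panel[panel.label == "BSA"]["tau2_ns"], 4.193)


@given(
    n=st.floats(0.2, 6.0),
    ec50=st.floats(1e-13, 1e-9),
    span=st.floats(0.01, 0.5),
)
def test_generating_hill_curve_is_monotone_nonincreasing(n, ec50, span):
    """A quenching isotherm (τ₂_max < τ₂₀, n > 0) never increases with
    concentration."""
    p = ts.HillParams(tau2_0=4.183, tau2_max=4.183 - span, ec50=ec50, n=n)
    x = np.logspace(-15, -6, 200)
    y = predict_hill(p, x)
    assert np.all(np.diff(y) <= 1e-15)
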