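import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flimfret.decay import (DecayHistogram, IRFModel, MultiExpModel, fit_decay,
                            mean_lifetime, model_decay, reduced_chi_square,
                            runs_test, select_model)
from flimfret.errors import InvalidInputError
from flimfret.synthetic import make_decay

from conftest import M1_AMPLITUDES, M1_LIFETIMES


class TestModelDecay:
    def test_background_only_is_constant(self):
        h = DecayHistogram.empty(64, 50.0)
        m = MultiExpModel(np.array([1.0]), np.array([3.0]), background=4.5,
                          scale=0.0)
        np.testing.assert_allclose(model_decay(m, IRFModel(0.15), h), 4.5)

    def test_matches_closed_form_bin_integral(self):
        # delta IRF, no wrap (period >> lifetime): expected counts are the
        # analytic integral of exp(-t/tau)/tau over each bin
        tau = 3.2
        h = DecayHistogram.empty(1000, 500.0)
        m = MultiExpModel(np.array([1.0]), np.array([tau]), scale=1e6)
        expected = model_decay(m, IRFModel(0.0, 0.0), h)
        e = h.bin_edges_ns
        analytic = 1e6 * (np.exp(-e[:-1] / tau) - np.exp(-e[1:] / tau))
        # per-bin probability mass agrees to 1e-10 of the total signal
        np.testing.assert_allclose(expected / 1e6, analytic / 1e6, atol=1e-10,
                                   rtol=0)

    def test_wrap_factor_is_geometric_series(self):
        # at 80 MHz (12.5 ns period) a 3.2 ns decay folds back; the first bin
        # exceeds the unwrapped value by 1/(1 - exp(-T/tau))
        tau, period = 3.2, 12.5
        h = DecayHistogram.empty(1000, period)
        m = MultiExpModel(np.array([1.0]), np.array([tau]), scale=1e6)
        expected = model_decay(m, IRFModel(0.0, 0.0), h)
        unwrapped = 1e6 * (1.0 - np.exp(-h.bin_width_ns / tau))
        assert expected[0] / unwrapped == pytest.approx(
            1.0 / (1.0 - np.exp(-period / tau)), rel=1e-12)

    def test_count_conservation_with_wrap(self, m1_triple, gen_irf):
        h = DecayHistogram.empty(1024, 50.0)
        m = MultiExpModel(m1_triple.amplitudes, m1_triple.lifetimes_ns,
                          background=2.0, scale=1e6)
        expected = model_decay(m, gen_irf, h)
        assert expected.sum() == pytest.approx(1e6 + 2.0 * 1024, rel=1e-3)

    def test_unresolvable_lifetime_warns(self):
        h = DecayHistogram.empty(64, 50.0)
        m = MultiExpModel(np.array([1.0]), np.array([1e-3]), scale=100.0)
        with pytest.warns(UserWarning, match="unresolvable"):
            model_decay(m, IRFModel(0.15), h)


class TestReducedChiSquare:
    def test_zero_on_perfect_agreement(self):
        obs = np.arange(1.0, 101.0)
        assert reduced_chi_square(obs, obs.copy(), 3) == 0.0

    def test_near_one_for_poisson_data_under_true_model(self):
        rng = np.random.default_rng(7)
        vals = []
        for _ in range(10):
            lam = np.full(10_000, 120.0)
            obs = rng.poisson(lam)
            vals.append(reduced_chi_square(obs, lam, 1))
        assert np.mean(vals) == pytest.approx(1.0, abs=0.1)

    def test_one_sigma_systematic_gives_unit_chi2(self):
        obs = np.arange(10.0, 1010.0)
        exp = obs + np.sqrt(obs)
        n, p = obs.size, 4
        assert reduced_chi_square(obs, exp, p) == pytest.approx(n / (n - p))

    def test_insufficient_dof_rejected(self):
        with pytest.raises(InvalidInputError):
            reduced_chi_square(np.ones(3), np.ones(3), 3)


class TestRunsTest:
    def test_alternating_signs_rejected(self):
        r = np.resize([1.0, -1.0], 60)
        assert runs_test(r) < 1e-6

    def test_two_blocks_rejected(self):
        r = np.concatenate([np.ones(10), -np.ones(10)])
        assert runs_test(r) < 1e-3

    def test_all_same_sign_returns_zero(self):
        assert runs_test(np.ones(30)) == 0.0

    def test_null_distribution_is_uniform(self):
        # p-values of i.i.d. symmetric noise should look uniform
        from scipy.stats import kstest
        rng = np.random.default_rng(11)
        ps = [runs_test(rng.standard_normal(200)) for _ in range(500)]
        assert kstest(ps, "uniform").pvalue > 0.01


class TestMeanLifetime:
    def test_tandem_triple_matches_printed_mean(self, m1_triple):
        # 0.372*3.0 + 0.464*2.0 + 0.164*0.6 against the printed 2.13 ns
        assert mean_lifetime(m1_triple) == pytest.approx(2.13, abs=0.02)

    def test_single_component_identity(self):
        m = MultiExpModel(np.array([1.0]), np.array([3.20]))
        assert mean_lifetime(m) == 3.20

    def test_equal_amplitudes_arithmetic_mean(self):
        m = MultiExpModel(np.array([0.5, 0.5]), np.array([4.0, 2.0]))
        assert mean_lifetime(m) == pytest.approx(3.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.1, 10.0), min_size=2, max_size=4, unique=True))
    def test_invariant_under_component_reordering(self, taus):
        taus = np.sort(np.asarray(taus))[::-1]
        amps = np.ones(taus.size) / taus.size
        m = MultiExpModel(amps, taus)
        assert mean_lifetime(m) == pytest.approx(float(np.mean(taus)), rel=1e-12)


class TestFitDecay:
    def test_noiseless_mono_self_consistency(self):
        # acceptor-like 1.56 ns decay, negligible IRF, no noise: rounding the
        # expectation to integer counts is the only perturbation
        tau = 1.56
        h0 = DecayHistogram.empty(1024, 50.0)
        m = MultiExpModel(np.array([1.0]), np.array([tau]), scale=1e7)
        expected = model_decay(m, IRFModel(1e-4, 2.0), h0)
        h = DecayHistogram(h0.bin_edges_ns, np.rint(expected).astype(np.int64),
                           50.0)
        fit = fit_decay(h, 1, IRFModel(1e-4))
        assert fit.converged
        assert fit.model.lifetimes_ns[0] == pytest.approx(tau, rel=1e-4)
        assert fit.chi2_reduced < 0.01

    def test_forward_inverse_consistency_biexponential(self):
        # noiseless roundtrip for well-separated lifetimes (ratio >= 2)
        truth = MultiExpModel(np.array([0.6, 0.4]), np.array([3.2, 1.0]),
                              scale=1e7)
        h0 = DecayHistogram.empty(1024, 50.0)
        expected = model_decay(truth, IRFModel(0.15, 2.0), h0)
        h = DecayHistogram(h0.bin_edges_ns, np.rint(expected).astype(np.int64),
                           50.0)
        fit = fit_decay(h, 2, IRFModel(0.15))
        np.testing.assert_allclose(fit.model.lifetimes_ns, truth.lifetimes_ns,
                                   rtol=1e-3)
        np.testing.assert_allclose(fit.model.amplitudes, truth.amplitudes,
                                   atol=1e-3)

    def test_poisson_mono_recovery(self, gen_irf, fit_irf):
        m = MultiExpModel(np.array([1.0]), np.array([3.20]), scale=1e6)
        hist, _ = make_decay(m, gen_irf, 1e6, 1024, 50.0, seed=3)
        fit = fit_decay(hist, 1, fit_irf)
        assert fit.model.lifetimes_ns[0] == pytest.approx(3.20, rel=0.01)
        assert 0.8 < fit.chi2_reduced < 1.2
        assert fit.runs_test_p > 1e-3

    def test_all_zero_histogram_rejected(self, fit_irf):
        h = DecayHistogram.empty(256, 50.0)
        with pytest.raises(InvalidInputError):
            fit_decay(h, 1, fit_irf)

    def test_degenerate_components_flagged(self, gen_irf, fit_irf):
        m = MultiExpModel(np.array([1.0]), np.array([2.5]), scale=1e6)
        hist, _ = make_decay(m, gen_irf, 1e6, 512, 50.0, seed=5)
        with pytest.warns(UserWarning, match="ratio"):
            fit = fit_decay(hist, 2, fit_irf)
        assert fit.degenerate

    def test_graceful_degradation_at_low_counts(self, m1_triple, gen_irf,
                                                fit_irf):
        # documented benchmark: at 1e4 counts the triexponential lifetime
        # estimates stay within 15%
        hist, _ = make_decay(m1_triple, gen_irf, 1e4, 512, 50.0, seed=0)
        fit = fit_decay(hist, 3, fit_irf, min_counts=1000)
        np.testing.assert_allclose(fit.model.lifetimes_ns,
                                   m1_triple.lifetimes_ns, rtol=0.15)


class TestSelectModel:
    def test_mono_data_selects_mono(self, gen_irf, fit_irf):
        m = MultiExpModel(np.array([1.0]), np.array([3.0]), scale=1e6)
        hist, _ = make_decay(m, gen_irf, 1e6, 1024, 50.0, seed=1)
        sel = select_model(hist, fit_irf, max_components=3)
        assert sel.n_components == 1

    def test_tandem_triple_selects_tri(self, m1_histogram, fit_irf):
        hist, _ = m1_histogram
        sel = select_model(hist, fit_irf, max_components=3)
        assert sel.n_components == 3

    def test_chi2_ladder_decreases_to_true_order(self, m1_histogram, fit_irf):
        hist, _ = m1_histogram
        sel = select_model(hist, fit_irf, max_components=3)
        chi2 = [c.chi2_reduced for c in sel.candidates]
        assert chi2[0] > chi2[1] > chi2[2]
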