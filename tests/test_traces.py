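"""Trace-level procedures: peaks, tail fits, inactivation statistic,
reversal estimation, relative inhibition."""

import numpy as np
import pandas as pd
import pytest

from kflux import biophys, traces
from kflux.simulate import TraceModelConfig, default_protocol, gen_tevc_trace
from kflux.traces import Recording, Segment, TailFitResults


def tail_noise_for_snr(cfg, snr_db):
    """Noise sd giving the requested SNR vs the clean tail-window RMS."""
    import dataclasses
    clean_cfg = dataclasses.replace(cfg, noise_sd=0.0)
    rec, _ = gen_tevc_trace(clean_cfg)
    seg = rec.segment("tail")
    tail = rec.segment_data("tail")
    t = tail["time_s"].to_numpy() - seg.t_start
    y = tail["current"].to_numpy()
    win = (t >= 7.5e-3) & (t <= 0.97 * seg.duration())
    rms = float(np.sqrt(np.mean(y[win] ** 2)))
    return rms * 10 ** (-snr_db / 20.0)


def _flat_recording(value=1.0, n=100):
    t = np.linspace(0.0, 1.0, n, endpoint=False)
    return Recording(
        pd.DataFrame({"sweep": 0, "time_s": t, "current": value}),
        [Segment("hold", 0.0, 0.5, -100.0), Segment("depol", 0.5, 1.0, 60.0)],
        sample_rate=n)


class TestPeakCurrent:
    def test_constant_segment(self):
        assert traces.peak_current(_flat_recording(1.0), "depol") == 1.0

    def test_all_zero(self):
        assert traces.peak_current(_flat_recording(0.0), "depol") == 0.0

    def test_programmed_peak_of_rising_sagging_trace(self):
        cfg = TraceModelConfig(noise_sd=0.0)
        rec, truth = gen_tevc_trace(cfg)
        assert traces.peak_current(rec, "depol") == pytest.approx(
            truth["peak_depol"], rel=1e-9)

    def test_missing_segment_rejected(self):
        with pytest.raises(KeyError):
            traces.peak_current(_flat_recording(), "nope")


class TestSubtractUnspecific:
    def test_identity_and_arithmetic(self):
        assert np.allclose(traces.subtract_unspecific([1.0], [0.0]), [1.0])
        assert np.allclose(traces.subtract_unspecific([1.0], [0.1]), [0.9])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            traces.subtract_unspecific([1.0, 2.0], [0.1])

    def test_programmed_leak_removed(self):
        clean, _ = gen_tevc_trace(TraceModelConfig(leak_current=0.0))
        leaky, _ = gen_tevc_trace(TraceModelConfig(leak_current=0.15))
        corrected = traces.subtract_unspecific(
            leaky.sweeps["current"].to_numpy(), 0.15)
        assert np.allclose(corrected, clean.sweeps["current"].to_numpy(),
                           atol=1e-12)


class TestTailFit:
    def test_noiseless_three_component_recovery(self):
        rec, truth = gen_tevc_trace(TraceModelConfig(noise_sd=0.0))
        fit = traces.fit_tail_multiexp(rec, "tail", 3, auto_fallback=False)
        got = sorted(fit.components, key=lambda c: c[1])
        want = sorted(truth["tail_components"], key=lambda c: c[1])
        for (a, tau), (a_t, tau_t) in zip(got, want):
            assert a == pytest.approx(a_t, rel=0.02)
            assert tau == pytest.approx(tau_t, rel=0.02)

    def test_single_exponential_nested_in_two(self):
        t = np.arange(0.0, 2.0, 1e-3)
        y = -1.5 * np.exp(-t / 0.3)
        rec = Recording(pd.DataFrame({"sweep": 0, "time_s": t, "current": y}),
                        [Segment("tail", 0.0, 2.0, -100.0)], 1000.0)
        fit = traces.fit_tail_multiexp(rec, "tail", 2, cursors=(0.0, 1.94))
        amps = np.abs(fit.amplitudes)
        assert amps.min() < 0.01 * amps.max()  # extra component ~ 0
        dom = int(np.argmax(amps))
        assert fit.taus[dom] == pytest.approx(0.3, rel=1e-3)

    def test_default_cursor_window(self):
        rec, _ = gen_tevc_trace(TraceModelConfig())
        fit = traces.fit_tail_multiexp(rec, "tail", 3)
        seg = rec.segment("tail")
        assert fit.window[0] == pytest.approx(7.5e-3)
        assert fit.window[1] == pytest.approx(0.97 * seg.duration())

    def test_three_component_fit_of_two_component_truth_falls_back(self):
        # nested-model consistency: negligible third amplitude triggers
        # the documented 2-component fallback
        t = np.arange(0.0, 2.0, 5e-4)
        y = (-1.2 * np.exp(-t / 0.15) - 0.8 * np.exp(-t / 0.5))
        rec = Recording(pd.DataFrame({"sweep": 0, "time_s": t, "current": y}),
                        [Segment("tail", 0.0, 2.0, -100.0)], 2000.0)
        fit = traces.fit_tail_multiexp(rec, "tail", 3)
        if fit.n_components == 3:
            assert np.abs(fit.amplitudes).min() < 0.01 * np.abs(
                fit.amplitudes).sum()
        else:
            assert fit.n_components == 2


class TestFractionalInactivation:
    def test_pure_decay_gives_zero(self):
        fit = TailFitResults(0.0, [-1.2, -0.8], [0.15, 0.5], (0.0075, 1.94),
                             np.array([0.0]), np.array([-2.0]), None, True)
        assert traces.fractional_inactivation(fit) == 0.0

    def test_constructed_ratio(self):
        # hook of +0.6 on a -2.0 inward tail: X=-1.4, Y=-2.0 -> 0.30
        fit = TailFitResults(0.0, [0.6, -1.2, -0.8], [0.03, 0.15, 0.5],
                             (0.0075, 1.94), np.array([0.0]),
                             np.array([-1.4]), None, True)
        assert fit.Y == pytest.approx(-2.0)
        assert fit.X() == pytest.approx(-1.4)
        assert traces.fractional_inactivation(fit) == pytest.approx(0.30)

    def test_zero_total_rejected(self):
        fit = TailFitResults(0.0, [1.0, -1.0], [0.1, 0.1], (0.0, 1.0),
                             np.array([0.0]), np.array([0.0]), None, True)
        with pytest.raises(ZeroDivisionError):
            traces.fractional_inactivation(fit)

    def test_noiseless_generator_recovery(self):
        rec, truth = gen_tevc_trace(
            TraceModelConfig(inactivation_fraction=0.35, noise_sd=0.0))
        fit = traces.fit_tail_multiexp(rec, "tail", 3, auto_fallback=False)
        frac = traces.fractional_inactivation(fit)
        assert frac == pytest.approx(0.35, abs=1e-3)

    @pytest.mark.parametrize("target", [0.0, 0.1, 0.2, 0.3, 0.4, 0.5])
    def test_programmed_fraction_recovered_at_30dB(self, target):
        cfg = TraceModelConfig(inactivation_fraction=target,
                               seed=int(target * 10))
        cfg.noise_sd = tail_noise_for_snr(cfg, 30.0)
        rec, truth = gen_tevc_trace(cfg)
        fit = traces.fit_tail_multiexp(rec, "tail", 3)
        frac = traces.fractional_inactivation(fit)
        assert frac == pytest.approx(target, abs=0.02)


class TestInactivationSeries:
    def test_single_recording_single_row(self):
        tab = traces.inactivation_series([(-40.0, 0.25)])
        assert len(tab) == 1
        assert tab["fraction_mean"].iloc[0] == 0.25

    def test_duplicate_axis_values_aggregated(self):
        tab = traces.inactivation_series(
            [(-40.0, 0.2), (-40.0, 0.3), (0.0, 0.5)])
        row = tab[tab["prepulse_voltage"] == -40.0].iloc[0]
        assert row["fraction_mean"] == pytest.approx(0.25)
        assert row["n"] == 2
        assert row["fraction_sem"] == pytest.approx(0.05)

    def test_programmed_voltage_dependence_monotone(self):
        rows = []
        for k, target in enumerate([0.1, 0.2, 0.3, 0.4, 0.5]):
            rec, _ = gen_tevc_trace(TraceModelConfig(
                inactivation_fraction=target, noise_sd=0.01, seed=k))
            fit = traces.fit_tail_multiexp(rec, "tail", 3,
                                           auto_fallback=False)
            rows.append((-80.0 + 20 * k,
                         traces.fractional_inactivation(fit)))
        tab = traces.inactivation_series(rows)
        assert np.all(np.diff(tab["fraction_mean"]) > 0)


class TestDeltaIRel:
    def test_identical_is_zero(self):
        assert traces.delta_I_rel(1.0, 0.5, 1.0, 0.5).delta_I_rel == 0.0

    def test_less_inhibited_mutant(self):
        res = traces.delta_I_rel(1.0, 0.8, 1.0, 0.5)
        assert res.delta_I_rel == pytest.approx(-0.3)

    def test_potentiated_mutant(self):
        res = traces.delta_I_rel(1.0, 1.2, 1.0, 0.5)
        assert res.delta_I_rel == pytest.approx(-0.7)

    def test_antisymmetric_under_swap(self):
        a = traces.delta_I_rel(1.0, 0.8, 1.0, 0.5).delta_I_rel
        b = traces.delta_I_rel(1.0, 0.5, 1.0, 0.8).delta_I_rel
        assert a == pytest.approx(-b)

    def test_zero_reference_rejected(self):
        with pytest.raises(ZeroDivisionError):
            traces.delta_I_rel(0.0, 0.5, 1.0, 0.5)


class TestEstimateReversal:
    def test_symmetric_crossing(self):
        assert traces.estimate_reversal([-10.0, 10.0], [-1.0, 1.0]) == 0.0

    def test_ghk_reversal_matches_nernst(self):
        v = np.arange(-120.0, -79.0, 10.0)
        i = np.asarray(biophys.ghk_flux(1e-4, 108.0, 2.0, v))
        erev = traces.estimate_reversal(v, i)
        assert erev == pytest.approx(biophys.nernst_potential(108.0, 2.0),
                                     abs=0.5)

    def test_no_sign_change_rejected(self):
        with pytest.raises(ValueError):
            traces.estimate_reversal([0.0, 10.0, 20.0], [1.0, 2.0, 3.0])


class TestLinearFit:
    def test_exact_line(self):
        x = np.arange(5.0)
        slope, intercept, r = traces.linear_fit_with_correlation(x, 2 * x + 1)
        assert (slope, intercept, r) == pytest.approx((2.0, 1.0, 1.0))

    def test_constant_y_flagged(self):
        slope, intercept, r = traces.linear_fit_with_correlation(
            [0.0, 1.0, 2.0], [3.0, 3.0, 3.0])
        assert slope == 0.0 and np.isnan(r)

    def test_zero_x_variance_rejected(self):
        with pytest.raises(ValueError):
            traces.linear_fit_with_correlation([1.0, 1.0, 1.0],
                                               [0.0, 1.0, 2.0])

    def test_noisy_line_recovery_within_stderr(self):
        rng = np.random.default_rng(2)
        x = np.linspace(0, 10, 40)
        y = -0.5 * x + 2.0 + rng.normal(0, 0.3, x.size)
        slope, intercept, r = traces.linear_fit_with_correlation(x, y)
        assert slope == pytest.approx(-0.5, abs=0.1)
        assert r < -0.9
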