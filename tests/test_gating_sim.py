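"""Ramp waveforms, gating model, and cohort generation."""

import numpy as np
import pytest
from pydantic import ValidationError

import thermoramp as tr
from thermoramp.gating_sim import _sensitized_fraction


def max_slope(t, temp):
    return float(np.max(np.diff(temp) / np.diff(t)))


class TestRampProtocol:
    def test_linear_ramp_slope_is_span_over_rise(self):
        p = tr.RampProtocol(shape="linear", T_base=25, T_peak=55, rise_ms=1500)
        t, temp = tr.make_protocol(p)
        assert max_slope(t, temp) == pytest.approx(20.0, rel=0.01)

    def test_default_exp_ramp_reaches_configured_max_speed(self):
        t, temp = tr.make_protocol(tr.RampProtocol())
        assert max_slope(t, temp) == pytest.approx(35.0, rel=0.01)
        assert temp.max() == pytest.approx(57.0, abs=0.01)

    def test_sweep_peaks_evenly_spaced_and_boundaries_at_base(self):
        p = tr.RampProtocol(n_sweeps=3, inter_sweep_s=3.0)
        t, temp = tr.make_protocol(p)
        n = len(t) // 3
        peaks = [t[k * n + np.argmax(temp[k * n:(k + 1) * n])] for k in range(3)]
        assert np.allclose(np.diff(peaks), 3.0, atol=1e-3)
        for k in range(3):
            assert temp[k * n] == pytest.approx(25.0, abs=0.01)

    def test_invalid_configurations_rejected(self):
        with pytest.raises(ValidationError):
            tr.RampProtocol(rise_ms=0)
        with pytest.raises(ValidationError):
            tr.RampProtocol(sample_rate_hz=-1)
        with pytest.raises(ValidationError):
            tr.RampProtocol(T_peak=20.0)  # below T_base
        with pytest.raises(ValidationError):
            tr.RampProtocol(max_speed=10.0)  # cannot reach peak in time

    def test_configured_speed_holds_across_settings(self):
        for speed in (25.0, 35.0, 50.0):
            p = tr.RampProtocol(max_speed=speed)
            t, temp = tr.make_protocol(p)
            assert max_slope(t, temp) == pytest.approx(speed, rel=0.01)


class TestOpenProbability:
    def test_midpoint_probability_is_half(self):
        assert tr.open_probability(330e3 / 995.0, 330.0, 995.0) == pytest.approx(0.5)

    def test_printed_midpoint_400_over_1p22(self):
        mid = 400e3 / 1220.0
        assert mid == pytest.approx(327.9, abs=0.1)  # ~54.7 °C
        assert tr.open_probability(mid, 400.0, 1220.0) == pytest.approx(0.5, abs=1e-6)

    def test_monotone_in_temperature_and_bounded(self):
        T = np.linspace(280, 360, 500)
        po = tr.open_probability(T, 330.0, 995.0)
        assert np.all(np.diff(po) > 0)
        assert po.min() >= 0 and po.max() <= 1

    def test_agonist_strictly_increases_po(self):
        T = np.linspace(290, 340, 100)
        assert np.all(
            tr.open_probability(T, 330.0, 995.0, 10.0)
            > tr.open_probability(T, 330.0, 995.0)
        )

    def test_low_po_limit_q10_matches_analytic_expression(self):
        # below ~1e-3 open probability, Q10 of Po -> exp(10*dH/(R*T1*T2))
        dH, dS = 330.0, 995.0
        T1, T2 = 300.0, 301.0
        po1 = float(tr.open_probability(T1, dH, dS))
        po2 = float(tr.open_probability(T2, dH, dS))
        assert po2 < 1e-3
        q10_num = (po2 / po1) ** (10.0 / (T2 - T1))
        q10_analytic = np.exp(10 * dH * 1e3 / (tr.R_GAS * T1 * T2))
        assert q10_num == pytest.approx(q10_analytic, rel=0.02)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            tr.open_probability(-5.0, 330.0, 995.0)


class TestSensitizedFraction:
    def test_stays_zero_below_onset_and_grows_above(self):
        t = np.linspace(0, 1, 1000)
        below = np.full_like(t, 48.0)
        s = _sensitized_fraction(t, below, 50.0, 1.0)
        assert np.all(s == 0)
        above = np.full_like(t, 53.0)
        s = _sensitized_fraction(t, above, 50.0, 1.0)
        assert np.all(np.diff(s) > 0)

    def test_never_decreases_on_any_trajectory(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 5, 3000)
        temp = 40 + 20 * np.abs(np.sin(t)) + rng.normal(0, 0.5, t.size)
        for soft in (None, 5.0):
            s = _sensitized_fraction(t, temp, 50.0, 0.7, softness=soft)
            assert np.all(np.diff(s) >= 0)
            assert 0 <= s[0] and s[-1] <= 1

    def test_softness_reduces_to_linear_drive_in_the_large_scale_limit(self):
        t = np.linspace(0, 2, 2000)
        temp = np.linspace(45, 56, t.size)
        lin = _sensitized_fraction(t, temp, 50.0, 0.5)
        soft = _sensitized_fraction(t, temp, 50.0, 0.5, softness=1e6)
        assert np.allclose(lin, soft, atol=1e-9)


class TestSimulateCell:
    def test_quiet_cell_at_base_temperature_shows_leak_only(self, noiseless_params):
        proto = tr.RampProtocol(T_peak=57.0)
        trace = tr.simulate_cell(noiseless_params, proto)[0]
        pre_ramp = trace.current[trace.temp < 25.01][:1]
        leak = noiseless_params.leak_g * (-70.0)
        assert pre_ramp == pytest.approx(leak, rel=1e-3)
        po = tr.open_probability(298.15, noiseless_params.dH, noiseless_params.dS)
        assert po < 1e-5

    def test_locked_open_follows_pure_conductance_law(self):
        params = tr.GatingParams(locked_open=True, N_g_max=28.0, leak_g=0.0,
                                 sub_g=0.0, noise_sd=0.0)
        proto = tr.RampProtocol(T_peak=57.0)
        trace = tr.simulate_cell(params, proto)[0]
        pred = 28.0 * 1.3 ** ((trace.temp - 25.0) / 10.0) * (-70.0)
        ss_res = np.sum((trace.current - pred) ** 2)
        ss_tot = np.sum((trace.current - trace.current.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.999

    def test_same_seed_bit_reproducible(self):
        params = tr.GatingParams(noise_sd=20.0, seed=11)
        proto = tr.RampProtocol(T_peak=57.0, n_sweeps=2)
        a = tr.simulate_cell(params, proto)
        b = tr.simulate_cell(params, proto)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.current, tb.current)

    def test_agonist_sweep_flag_recorded_and_potentiates(self):
        params = tr.GatingParams(agonist_dG=25.0, noise_sd=0.0, sub_g=0.0,
                                 leak_g=0.0)
        proto = tr.RampProtocol(T_peak=40.0, n_sweeps=2,
                                agonist_sweeps=frozenset({1}))
        sweeps = tr.simulate_cell(params, proto)
        assert not sweeps[0].agonist and sweeps[1].agonist
        # agonist-potentiated current at 40 °C is much larger
        i0 = np.abs(sweeps[0].current).max()
        i1 = np.abs(sweeps[1].current).max()
        assert i1 > 5 * i0

    def test_sensitization_requires_suprathreshold_sweep(self, noiseless_params):
        t, temp = tr.make_protocol(tr.RampProtocol(T_peak=48.0, n_sweeps=1))
        s = _sensitized_fraction(t, temp, noiseless_params.sens_T,
                                 noiseless_params.sens_rate)
        assert np.all(s == 0)
        t, temp = tr.make_protocol(tr.RampProtocol(T_peak=57.0, n_sweeps=1))
        s = _sensitized_fraction(t, temp, noiseless_params.sens_T,
                                 noiseless_params.sens_rate)
        assert s[-1] > 0 and np.all(np.diff(s) >= 0)


class TestGatingParamsValidation:
    def test_sensitized_mode_must_be_softer_and_lower(self):
        with pytest.raises(ValidationError):
            tr.GatingParams(dH=300.0, dH_sens=320.0)
        with pytest.raises(ValidationError):
            # sensitized midpoint above naive midpoint
            tr.GatingParams(dH=330.0, dS=995.0, dH_sens=248.0, dS_sens=700.0)

    def test_negative_entropy_rejected(self):
        with pytest.raises(ValidationError):
            tr.GatingParams(dS=-10.0)


class TestMakeCohort:
    def test_unknown_preset_raises(self):
        with pytest.raises(KeyError):
            tr.make_cohort("no_such_phenotype", 3, 0)

    def test_seed_determinism(self):
        a = tr.make_cohort("wild_type", 4, 99)
        b = tr.make_cohort("wild_type", 4, 99)
        for ca, cb in zip(a, b):
            for ta, tb in zip(ca, cb):
                assert np.array_equal(ta.current, tb.current)

    def test_wild_type_steep_segments_fall_in_45_60C(self, wt_cohort):
        tlows = []
        for cell in wt_cohort:
            fit = tr.fit_sweep(cell[0])
            tlows.append(fit.T_low)
        assert all(45.0 <= T <= 60.0 for T in tlows)

    def test_sensitized_chimera_has_tonic_room_temperature_current(self):
        proto = tr.RampProtocol(T_peak=57.0)
        wt = tr.make_cohort("wild_type", 6, 5, protocol=proto)
        ch = tr.make_cohort("sensitized_chimera", 6, 5, protocol=proto)

        def tonic(cohort):
            vals = []
            for cell in cohort:
                trc = cell[0]
                vals.append(np.abs(trc.current[trc.temp < 25.01]).mean())
            return np.mean(vals)

        assert tonic(ch) > 5 * tonic(wt)

    def test_doubling_sample_rate_barely_changes_binned_output(self):
        # zero-noise single cell, same thermodynamics at 1 and 2 kHz
        for rate in (1000.0, 2000.0):
            proto = tr.RampProtocol(T_peak=57.0, sample_rate_hz=rate)
            params = tr.GatingParams(
                dH=330.0, dS=330.0e3 / (58.5 + tr.ZERO_C),
                dH_sens=248.0, dS_sens=248.0e3 / (56.5 + tr.ZERO_C),
                N_g_max=19.0, leak_g=0.35, noise_sd=0.0, sens_rate=0.62,
            )
            trace = tr.simulate_cell(params, proto)[0]
            b = tr.binned_rising_phase(trace)
            if rate == 1000.0:
                ref = b
            else:
                common = np.intersect1d(ref.bin_centers, b.bin_centers)[1:-1]
                ia = np.isin(ref.bin_centers, common)
                ib = np.isin(b.bin_centers, common)
                rel = np.abs(b.mean_current[ib] - ref.mean_current[ia]) \
                    / ref.mean_current[ia]
                assert np.max(rel) < 0.005
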