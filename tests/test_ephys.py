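import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from chanprox.ephys import (BoltzmannFit, FitError, IVSeries,
                            SingleChannelTrace, activation_threshold,
                            compute_npo, conductance_from_iv,
                            fit_activation_tau, fit_boltzmann,
                            nernst_potential, subtract_traces)
from chanprox.synthetic import (generate_gv_dataset,
                                generate_single_channel_trace)

# the four printed activation parameter sets (Vmid mV, slope mV)
PARAM_SETS = {
    "CaV1.3": (-37.0, 4.0),
    "CaV2.2": (-2.0, 4.0),
    "BK+CaV1.3": (-17.0, 12.0),
    "BK+CaV2.2": (16.0, 12.3),
}


class TestNernst:
    def test_calcium_reversal_room_temperature(self):
        e = nernst_potential(2, 2e-3, 100e-9, 295.15)
        assert e == pytest.approx(126.0, abs=0.5)

    def test_equal_concentrations_zero(self):
        assert nernst_potential(1, 5.0, 5.0) == 0.0

    @given(c_out=st.floats(1e-9, 1.0), c_in=st.floats(1e-9, 1.0))
    @settings(max_examples=25, deadline=None)
    def test_antisymmetry_and_valence_scaling(self, c_out, c_in):
        e1 = nernst_potential(1, c_out, c_in)
        assert nernst_potential(1, c_in, c_out) == pytest.approx(-e1, abs=1e-9)
        assert nernst_potential(2, c_out, c_in) == pytest.approx(e1 / 2, abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            nernst_potential(0, 1.0, 1.0)
        with pytest.raises(ValueError):
            nernst_potential(2, -1.0, 1.0)


class TestConductance:
    def test_point_conversion(self):
        series = IVSeries([-37.0], [-163.0])
        gv = conductance_from_iv(series, 126.0)
        assert gv.conductance_nS[0] == pytest.approx(1.0)

    def test_zero_current_zero_conductance(self):
        gv = conductance_from_iv(IVSeries([0.0], [0.0]), 126.0)
        assert gv.conductance_nS[0] == 0.0

    def test_matches_elementwise_quotient(self, rng):
        v = np.sort(rng.uniform(-80, 40, 20))
        v = np.unique(v)
        i = rng.normal(0, 100, v.size)
        gv = conductance_from_iv(IVSeries(v, i), 126.0)
        np.testing.assert_allclose(gv.conductance_nS,
                                   [ii / (vv - 126.0) for vv, ii in zip(v, i)])

    def test_point_at_reversal_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="reversal"):
            gv = conductance_from_iv(IVSeries([-10.0, 0.0, 10.0],
                                              [1.0, 2.0, 3.0]), 0.0)
        assert list(gv.voltages_mV) == [-10.0, 10.0]
        assert gv.excluded_voltages_mV == [0.0]


class TestBoltzmannFit:
    @pytest.mark.parametrize("name,params", PARAM_SETS.items())
    def test_noiseless_recovery_exact(self, name, params):
        vmid, slope = params
        erev = 126.0 if name.startswith("CaV") else -106.0
        v = np.arange(-80.0, 41.0, 2.0)
        series = generate_gv_dataset(vmid, slope, 1.0, erev, v)
        fit = fit_boltzmann(conductance_from_iv(series, erev))
        assert fit.vmid_mV == pytest.approx(vmid, abs=1e-6)
        assert fit.slope_mV == pytest.approx(slope, abs=1e-6)
        assert fit.gmax == pytest.approx(1.0, abs=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            fit_boltzmann(np.array([-10.0, 0.0, 10.0]), np.array([0.1, 0.5, 0.9]))

    def test_low_noise_bias_small(self):
        vm, sl = [], []
        v = np.arange(-80.0, 41.0, 5.0)
        for seed in range(40):
            series = generate_gv_dataset(-37.0, 4.0, 1.0, 126.0, v,
                                         noise_sd=0.05 * 163.0, seed=seed)
            fit = fit_boltzmann(conductance_from_iv(series, 126.0))
            vm.append(fit.vmid_mV)
            sl.append(fit.slope_mV)
        assert abs(np.mean(vm) + 37.0) < 1.0
        assert abs(np.mean(sl) - 4.0) < 0.5


class TestActivationThreshold:
    def test_level_half_is_vmid(self):
        assert activation_threshold((-37.0, 4.0), 0.5) == pytest.approx(-37.0)

    @pytest.mark.parametrize("params,expected", [
        (PARAM_SETS["CaV1.3"], -48.8),
        (PARAM_SETS["CaV2.2"], -13.8),
        (PARAM_SETS["BK+CaV1.3"], -52.3),
        (PARAM_SETS["BK+CaV2.2"], -20.2),
    ])
    def test_five_percent_thresholds(self, params, expected):
        assert activation_threshold(params, 0.05) == pytest.approx(expected,
                                                                   abs=0.05)

    def test_closed_form_equals_numeric_inversion(self):
        fit = BoltzmannFit(vmid_mV=-17.0, slope_mV=12.0, gmax=2.5,
                           residual_sum=0.0)
        for level in (0.01, 0.05, 0.3, 0.7):
            closed = activation_threshold(fit, level)
            numeric = brentq(lambda v: fit(v) / fit.gmax - level, -300, 300,
                             xtol=1e-12)
            assert closed == pytest.approx(numeric, abs=1e-9)

    def test_invalid_level(self):
        with pytest.raises(ValueError):
            activation_threshold((-37.0, 4.0), 1.0)


class TestTraceArithmetic:
    def test_subtraction_identities(self, rng):
        a = rng.normal(0, 1, 100)
        np.testing.assert_array_equal(subtract_traces(a, a), np.zeros(100))
        np.testing.assert_array_equal(subtract_traces(a, np.zeros(100)), a)
        b = rng.normal(0, 1, 100)
        np.testing.assert_allclose(subtract_traces(a, b), a - b)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            subtract_traces(np.zeros(5), np.zeros(6))


class TestActivationTau:
    @pytest.mark.parametrize("tau", [0.7, 4.5, 8.0, 18.0])
    def test_noiseless_recovery(self, tau):
        t = np.arange(0.0, 80.0, 0.1)
        i = 50.0 + 400.0 * (1.0 - np.exp(-t / tau))
        fit = fit_activation_tau(t, i)
        assert fit.tau_ms == pytest.approx(tau, rel=1e-6)
        assert fit.baseline == pytest.approx(50.0, abs=1e-6)

    def test_baseline_shift_invariance(self):
        t = np.arange(0.0, 50.0, 0.1)
        i = 200.0 * (1.0 - np.exp(-t / 8.0))
        tau0 = fit_activation_tau(t, i).tau_ms
        tau1 = fit_activation_tau(t, i + 500.0).tau_ms
        assert tau1 == pytest.approx(tau0, rel=1e-6)

    def test_window_outside_trace_rejected(self):
        t = np.arange(0.0, 10.0, 0.1)
        with pytest.raises(ValueError, match="window"):
            fit_activation_tau(t, t, window=(5.0, 20.0))


class TestNPo:
    def test_half_open_single_channel(self):
        samples = np.r_[np.zeros(500), np.full(500, 8.0)]
        tr = SingleChannelTrace(samples)
        assert compute_npo(tr, 8.0).npo == pytest.approx(0.5)

    def test_two_channels_always_open(self):
        tr = SingleChannelTrace(np.full(1000, 16.0))
        assert compute_npo(tr, 8.0).npo == pytest.approx(2.0)

    def test_baseline_and_scaling_invariance(self, rng):
        tr = generate_single_channel_trace(3, 0.6, 8.0, 0.4, 500.0, seed=2)
        base = compute_npo(tr, 8.0).npo
        shifted = SingleChannelTrace(tr.samples_pA + 3.0, tr.dt_ms)
        assert compute_npo(shifted, 8.0, baseline_pA=3.0).npo == base
        scaled = SingleChannelTrace(tr.samples_pA * 2.5, tr.dt_ms)
        assert compute_npo(scaled, 8.0 * 2.5).npo == base

    def test_estimate_matches_generator_truth(self):
        tr = generate_single_channel_trace(4, 0.9, 8.0, 0.5, 10_000.0,
                                           dwell_ms=10.0, seed=7)
        res = compute_npo(tr, 8.0)
        # idealization-level truth at moderate noise
        assert res.npo == pytest.approx(tr.idealization.mean(), abs=0.02)
        # law of large numbers toward N*Po
        assert res.npo == pytest.approx(3.6, abs=0.15)

    def test_noise_dominated_trace_rejected(self):
        tr = SingleChannelTrace(np.zeros(100))
        with pytest.warns(UserWarning, match="noise"):
            with pytest.raises(ValueError):
                compute_npo(tr, 1.0, noise_sd_pA=0.8, strict=True)
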