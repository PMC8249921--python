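"""Neural-mass EEG model: sigmoid, synaptic kernels, integration, cortex."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.optimize import fsolve
from scipy.signal import welch
from scipy.stats import kendalltau

from cmcsim.nmm import (IntentionSchedule, NMMParams, RPConfig, psp_kernel,
                        rp_kernel, sigmoid_rate, simulate_cortex,
                        simulate_single_nmm, _drive_series)


class TestSigmoid:
    @pytest.mark.parametrize("v, expected", [
        (6.0, 2.5),                 # midpoint fires at e0
        (1e6, 5.0),                 # saturation at 2*e0
        (0.0, 5.0 / (1.0 + math.exp(0.56 * 6.0))),  # 0.16785 1/s
    ])
    def test_reference_points(self, v, expected):
        assert sigmoid_rate(v, NMMParams.low()) == pytest.approx(expected,
                                                                 rel=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(-500, 500), st.floats(-500, 500))
    def test_monotone_and_bounded(self, v1, v2):
        par = NMMParams.low()
        z1, z2 = sigmoid_rate(v1, par), sigmoid_rate(v2, par)
        assert 0.0 < z1 <= 2 * par.e0  # open above mathematically; floats saturate
        if v1 < v2:
            assert z1 <= z2

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            sigmoid_rate(float("nan"), NMMParams.low())


class TestPSPKernel:
    def test_zero_for_non_positive_time(self):
        assert psp_kernel("excitatory", 3.25, 100.0, -0.1) == 0.0
        assert psp_kernel("excitatory", 3.25, 100.0, 0.0) == 0.0

    def test_peak_at_inverse_rate(self):
        gain, rate = 3.25, 100.0
        t = np.linspace(0, 0.1, 100001)
        k = psp_kernel("excitatory", gain, rate, t)
        assert t[np.argmax(k)] == pytest.approx(1.0 / rate, abs=1e-5)
        assert k.max() == pytest.approx(gain / math.e, rel=1e-6)

    def test_integrates_to_gain_over_rate(self):
        gain, rate = 22.0, 50.0
        val, _ = quad(lambda t: psp_kernel("inhibitory", gain, rate, t),
                      0, 2.0)
        assert val == pytest.approx(gain / rate, rel=1e-6)

    def test_non_positive_rate_rejected(self):
        with pytest.raises(ValueError):
            psp_kernel("excitatory", 1.0, 0.0, 0.1)


class TestRPKernel:
    def test_shape(self):
        rp = RPConfig()
        assert rp_kernel(-2.0, rp) == 0.0
        assert rp_kernel(0.0, rp) == pytest.approx(rp.amplitude)
        # continuous at onset, recovers toward zero
        assert rp_kernel(1e-9, rp) == pytest.approx(rp.amplitude, rel=1e-6)
        assert abs(rp_kernel(5.0, rp)) < abs(rp.amplitude) * 1e-4


class TestSingleMass:
    def test_zero_input_converges_to_algebraic_fixed_point(self):
        par = NMMParams.medium()
        C = par.C

        def steady(y):
            y0, y1, y2, y3 = y
            v0 = C["C2"] * y1 - C["C4"] * y2 - C["C7"] * y3
            z = lambda v: sigmoid_rate(v, par)
            return [par.A / par.a1 * z(v0) - y0,
                    par.A / par.a1 * z(C["C1"] * y0) - y1,
                    par.B / par.b1 * z(C["C3"] * y0) - y2,
                    par.G / par.g1 * z(C["C5"] * y0 - C["C6"] * y2) - y3]

        y = fsolve(steady, np.zeros(4))
        v0_fix = C["C2"] * y[1] - C["C4"] * y[2] - C["C7"] * y[3]
        v = simulate_single_nmm(par, np.zeros(3000), 1000.0)
        assert v[-1] == pytest.approx(v0_fix, abs=1e-6)

    def test_classic_parameterization_oscillates_in_alpha_band(self):
        # excitatory/slow-inhibitory loop only, constant drive
        par = NMMParams(A=3.25, B=22.0, G=1.0, a1=100.0, b1=50.0, g1=500.0,
                        m=220.0, sigma2=0.0,
                        C={"C1": 135.0, "C2": 108.0, "C3": 33.75,
                           "C4": 33.75, "C5": 0.0, "C6": 0.0, "C7": 0.0})
        v = simulate_single_nmm(par, np.full(10000, 220.0), 1000.0)
        f, p = welch(v[2000:] - v[2000:].mean(), fs=1000.0, nperseg=4096)
        assert 8.0 <= f[np.argmax(p)] <= 12.0

    def test_step_refinement_changes_output_below_1e3_mv_rms(self):
        par = NMMParams.medium()
        p = np.full(2000, par.m)
        coarse = simulate_single_nmm(par, p, 1000.0, substeps=1)
        fine = simulate_single_nmm(par, p, 1000.0, substeps=2)
        rms = np.sqrt(np.mean((coarse - fine) ** 2))
        assert rms < 1e-3

    def test_divergence_reported_with_location(self):
        with pytest.raises(FloatingPointError, match="sample"):
            simulate_single_nmm(NMMParams.low(), np.zeros(10), 1000.0,
                                initial=np.full(8, 1e7))

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_single_nmm(NMMParams.low(), np.zeros(10), 250.0)


class TestCortex:
    def test_single_weight_reduces_to_single_mass(self):
        schedule = IntentionSchedule(total_duration=2.0, task_window=(0.5, 1.5),
                                     seed=11)
        full = simulate_cortex(schedule=schedule, rp=RPConfig(enabled=False),
                               weights=(1.0, 0.0, 0.0), seed=11)
        par = NMMParams.low()
        child = np.random.SeedSequence(11).spawn(3)[0]
        p = _drive_series(par, schedule, 1000.0, np.random.default_rng(child))
        alone = simulate_single_nmm(par, p, 1000.0)
        np.testing.assert_allclose(full.data[0], alone, atol=1e-12)

    def test_same_seed_bit_reproducible(self):
        a = simulate_cortex(seed=3)
        b = simulate_cortex(seed=3)
        np.testing.assert_array_equal(a.data, b.data)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rp_produces_pre_onset_negativity(self, seed):
        rp = RPConfig()
        schedule = IntentionSchedule(total_duration=10.0, task_window=(5.0, 8.0))
        with_rp = simulate_cortex(schedule=schedule, rp=rp, seed=seed)
        fs = with_rp.fs
        onset = 5.0
        ramp = with_rp.data[0, int((onset - rp.rise_duration) * fs):int(onset * fs)]
        base = with_rp.data[0, int((onset - 2 * rp.rise_duration) * fs):
                            int((onset - rp.rise_duration) * fs)]
        assert ramp.mean() < base.mean()

    def test_output_carries_energy_in_all_rhythm_bands(self):
        sig = simulate_cortex(schedule=IntentionSchedule(
            total_duration=10.0, task_window=(4.0, 6.0)), seed=5)
        f, p = welch(sig.data[0] - sig.data[0].mean(), fs=sig.fs, nperseg=4096)
        floor = p[(f >= 60) & (f <= 100)].mean()
        for lo, hi in [(2, 8), (8, 16), (16, 40)]:
            assert p[(f >= lo) & (f < hi)].mean() > 3 * floor

    def test_stationary_when_rp_disabled(self):
        # no monotone trend beyond chance (Kendall tau at alpha = 0.01)
        hits = 0
        reps = 20
        for seed in range(reps):
            sig = simulate_cortex(
                schedule=IntentionSchedule(total_duration=3.0,
                                           task_window=(0.0, 3.0),
                                           task_gain=1.0),
                rp=RPConfig(enabled=False), seed=seed)
            # drop the settle-in from the zero initial state
            coarse = sig.data[0, 1000:].reshape(-1, 10).mean(axis=1)
            _, pval = kendalltau(np.arange(coarse.size), coarse)
            hits += pval < 0.01
        assert hits <= 4  # expected 0.2 false positives over 20 runs


class TestSchedule:
    def test_window_validation(self):
        with pytest.raises(ValueError):
            IntentionSchedule(total_duration=5.0, task_window=(4.0, 6.0))
        with pytest.raises(ValueError):
            IntentionSchedule(total_duration=5.0, task_window=(3.0, 2.0))

    def test_drive_mean_doubles_inside_task_window(self):
        par = NMMParams.low()
        schedule = IntentionSchedule(total_duration=4.0, task_window=(2.0, 4.0))
        p = _drive_series(par, schedule, 1000.0, np.random.default_rng(0))
        assert p[:2000].mean() == pytest.approx(par.m, abs=1.0)
        assert p[2000:].mean() == pytest.approx(2 * par.m, abs=1.0)

    def test_table_defaults_match_reference_columns(self):
        low, med, high = (NMMParams.low(), NMMParams.medium(),
                          NMMParams.high())
        assert (low.A, low.B, low.G) == (2.7, 3.2, 20.8)
        assert (med.a1, med.b1, med.g1) == (85.0, 30.0, 350.0)
        assert (high.m, high.sigma2) == (115.9, 69.0)
        assert med.m == -20.6
        assert low.C["C1"] == 135.0 and low.C["C6"] == 13.5
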