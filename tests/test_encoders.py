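import itertools

import numpy as np
import pytest

import qrpop
from qrpop import (
    ExpKernelSum,
    NeuronModel,
    Trace,
    encode_eme1,
    encode_eme2,
    encode_qr,
    encode_renewal,
    steady_activity_curve,
)

ALL_ENCODERS = {
    "renewal": encode_renewal,
    "qr": encode_qr,
    "eme1": encode_eme1,
    "eme2": encode_eme2,
}


def const_h(value, duration, dt=0.5):
    return Trace(dt, np.full(int(round(duration / dt)), float(value)), unit="")


class TestPoissonCollapse:
    @pytest.mark.parametrize("name", sorted(ALL_ENCODERS))
    def test_no_sap_gives_exponential_rate(self, poisson_model, name):
        # with eta == 0 every theory reduces to A = lam0 e^h; the survival
        # solvers carry only the per-bin O(lam*dt) factor, negligible here
        hv = poisson_model.h_infinity(20.0)
        expected = poisson_model.lambda0 * np.exp(hv)
        assert expected * 0.5 < 3e-3  # rates low enough for the bin factor
        a = ALL_ENCODERS[name](poisson_model, const_h(hv, 3000.0))
        assert a.values[-1] == pytest.approx(expected, rel=1e-3)

    def test_eme_poisson_collapse_is_exact(self, poisson_model):
        hv = poisson_model.h_infinity(40.0)
        expected = poisson_model.lambda0 * np.exp(hv)
        a = encode_eme1(poisson_model, const_h(hv, 1000.0))
        assert np.allclose(a.values, expected, rtol=1e-12)


class TestRenewal:
    def test_absolute_block_closed_form(self, blocked_model):
        # hazard lam above an absolute block Delta: A = lam / (1 + lam*Delta)
        lam = blocked_model.lambda0
        delta = blocked_model.eta.absolute_block
        a = encode_renewal(blocked_model, const_h(0.0, 10_000.0, dt=0.25))
        assert a.values[-1] == pytest.approx(lam / (1 + lam * delta), rel=5e-3)

    def test_matches_exhaustive_enumeration_on_three_bins(self):
        # brute-force oracle: enumerate all spike configurations of one
        # neuron over 3 bins, weighting each by its per-bin emission
        # probabilities 1-exp(-lam*dt); expected spikes/bin/dt == A(t)
        dt = 0.5
        model = NeuronModel(
            lambda0=0.004,
            kappa=ExpKernelSum(((0.008, 10.0),)),
            eta=ExpKernelSum(((-1.5, 20.0),)),
        )
        h = Trace(dt, np.array([0.3, 0.8, 0.1]))

        def hazard(k, last):
            s = 0.0 if last is None else model.eta.eval((k - last) * dt)
            return model.lambda0 * np.exp(h.values[k] + s)

        expected = np.zeros(3)
        for pattern in itertools.product([0, 1], repeat=3):
            prob = 1.0
            last = None
            for k in range(3):
                p = -np.expm1(-hazard(k, last) * dt)
                if pattern[k]:
                    prob *= p
                    last = k
                else:
                    prob *= 1 - p
            expected += prob * np.array(pattern)
        expected /= dt

        a = encode_renewal(model, h)
        assert np.allclose(a.values, expected, atol=1e-9)

    def test_steady_level_too_high_for_adapting_neurons(self, model, step_h):
        # renewal theory misses adaptation: its plateau exceeds both the QR
        # plateau and the true (simulated) steady state
        ar = encode_renewal(model, step_h)
        aq = encode_qr(model, step_h)
        assert ar.values[-1] > 1.5 * aq.values[-1]


class TestQR:
    def test_equals_renewal_with_zero_past_activity(self, model):
        # before any activity has accumulated the adaptation factor is zero
        h = Trace(0.5, np.linspace(0.0, 2.0, 20))
        ar = encode_renewal(model, h)
        aq = encode_qr(model, h)
        assert aq.values[0] == ar.values[0]

    def test_plateau_matches_stationary_fixed_point(self, model):
        a = encode_qr(model, const_h(model.h_infinity(70.0), 20_000.0))
        sol = qrpop.steady_rate(model, I_const=70.0)
        assert a.values[-1] == pytest.approx(sol.A_inf, rel=0.01)

    def test_conservation_residual_below_tolerance(self, model, step_h):
        for enc in (encode_qr, encode_renewal):
            _, info = enc(model, step_h, full_output=True)
            assert info["max_conservation_residual"] <= 1e-3

    def test_causality_bit_identical(self, model):
        rng = np.random.default_rng(0)
        base = rng.normal(1.0, 1.0, 2000)
        h1 = Trace(0.5, base.copy())
        h2 = Trace(0.5, np.concatenate([base[:1000], base[1000:] + 5.0]))
        for enc in (encode_renewal, encode_qr, encode_eme1):
            a1 = enc(model, h1).values
            a2 = enc(model, h2).values
            assert np.array_equal(a1[:1000], a2[:1000])
            assert not np.array_equal(a1[1000:], a2[1000:])

    def test_survival_state_invariants(self, model, step_h):
        _, info = encode_qr(model, step_h, full_output=True)
        state = info["state"]
        assert np.all(state.S >= 0)
        assert np.all(state.K >= 0)
        assert state.free_mass >= 0
        assert state.conservation_residual() <= 1e-3


class TestEME:
    def test_eme1_plateau_matches_lambert_gain(self, model):
        a = encode_eme1(model, const_h(model.h_infinity(40.0), 30_000.0))
        gain = qrpop.eme1_gain(model, I_const=40.0)
        assert a.values[-1] == pytest.approx(gain, rel=1e-3)

    def test_weak_sap_eme1_tracks_qr(self, model):
        # small-coupling limit: both truncations agree on a step response.
        # coupling is weak when the SAP is small AND the ISIs stay long
        # compared to the refractory time constant, hence a moderate step.
        weak = model.with_eta_scaled(0.1)
        current = qrpop.step_current(10.0, 30.0, 500.0, 3000.0, 0.5)
        h = qrpop.filtered_input(current, weak.kappa)
        a1 = encode_eme1(weak, h).values
        aq = encode_qr(weak, h).values
        mask = aq > 0.1 * aq.max()
        assert np.max(np.abs(a1[mask] - aq[mask]) / aq[mask]) < 0.02

    def test_eme2_zero_correction_is_eme1_bit_for_bit(self, model, step_h):
        a1 = encode_eme1(model, step_h)
        a2 = encode_eme2(model, step_h, zero_correction=True)
        assert np.array_equal(a1.values, a2.values)

    def test_eme2_lookup_isi_density_normalized(self, model):
        from qrpop.encoders import _renewal_isi

        for hv in (-1.0, 1.0, 4.0):
            ages, p0, rate = _renewal_isi(model, hv, 2.0, 4000.0)
            assert np.trapezoid(p0, ages) == pytest.approx(1.0, abs=1e-3)

    def test_divergence_guard(self, poisson_model):
        big = poisson_model.h_infinity(250.0)
        with pytest.raises(qrpop.EncoderDivergence):
            encode_eme1(poisson_model, const_h(big, 100.0))


class TestSteadyCurve:
    def test_poisson_curve_is_exponential(self, poisson_model):
        pts = steady_activity_curve(poisson_model, [10.0, 30.0], method="eme1")
        for I, a, conv in pts:
            assert conv
            expected = poisson_model.lambda0 * np.exp(poisson_model.h_infinity(I))
            assert a == pytest.approx(expected, rel=1e-6)

    def test_qr_curve_matches_inverse_mean_isi(self, model):
        # two independent routes: time-domain solver plateau vs the
        # stationary fixed point 1/mean-ISI
        pts = steady_activity_curve(model, [30.0, 70.0], method="qr")
        for I, a, conv in pts:
            assert conv
            assert a == pytest.approx(qrpop.steady_rate(model, I_const=I).A_inf, rel=0.01)

    def test_adapting_ordering_renewal_above_qr(self, model):
        for I in (40.0, 70.0):
            (_, a_ren, _), = steady_activity_curve(model, [I], method="renewal")
            (_, a_qr, _), = steady_activity_curve(model, [I], method="qr")
            assert a_ren > a_qr > 0

    def test_unknown_method_rejected(self, model):
        with pytest.raises(ValueError):
            steady_activity_curve(model, [10.0], method="fokker-planck")


class TestGridConvergence:
    @pytest.mark.parametrize("name", sorted(ALL_ENCODERS))
    def test_halving_dt_changes_output_below_one_percent_l2(self, model, name):
        current = qrpop.step_current(10.0, 50.0, 500.0, 4000.0, 0.5)
        h05 = qrpop.filtered_input(current, model.kappa)
        current25 = qrpop.step_current(10.0, 50.0, 500.0, 4000.0, 0.25)
        h025 = qrpop.filtered_input(current25, model.kappa)
        a_coarse = ALL_ENCODERS[name](model, h05).values
        a_fine = ALL_ENCODERS[name](model, h025).values[::2]
        num = np.linalg.norm(a_coarse - a_fine)
        den = np.linalg.norm(a_fine)
        assert num / den < 0.01
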