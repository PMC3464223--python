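import numpy as np
import pytest
from scipy import stats

import qrpop
from qrpop import (
    ExpKernelSum,
    NeuronModel,
    Trace,
    autocorrelation,
    averaged_hazard,
    eme1_gain,
    isi_density,
    steady_rate,
)


class TestAveragedHazard:
    def test_poisson_flat(self, poisson_model):
        ages = np.arange(0.0, 500.0, 0.5)
        lam = averaged_hazard(poisson_model, 1.2, 0.0, ages)
        assert np.allclose(lam, poisson_model.lambda0 * np.exp(1.2))

    def test_zero_activity_gives_pure_renewal_hazard(self, model):
        ages = np.arange(0.0, 2000.0, 0.5)
        lam = averaged_hazard(model, 0.8, 0.0, ages)
        expected = model.lambda0 * np.exp(0.8 + model.eta.eval(ages))
        assert np.allclose(lam, expected, rtol=1e-10)

    def test_large_age_limit_recovers_unadapted_rate(self, model):
        # the adaptation factor integrates the kernel over spikes BEFORE the
        # last one; when the last spike is ancient, so are all earlier
        # spikes, and the averaged hazard returns to lam0*e^h
        ages = np.arange(0.0, 30_000.0, 1.0)
        lam = averaged_hazard(model, 1.0, 0.005, ages)
        assert lam[-1] == pytest.approx(model.lambda0 * np.exp(1.0), rel=1e-6)
        # at age zero the full adaptation discount applies on top of eta(0)
        g = model.eta.adaptation_integral()
        assert np.log(lam[0] / model.lambda0) == pytest.approx(
            1.0 + model.eta.eval(0.0) - 0.005 * g, abs=5e-3
        )

    def test_negative_activity_rejected(self, model):
        with pytest.raises(ValueError):
            averaged_hazard(model, 0.0, -1.0, np.arange(0.0, 10.0, 0.5))


class TestISIDensity:
    def test_poisson_exponential(self, poisson_model):
        ages = np.arange(0.0, 4000.0, 0.5)
        lam = poisson_model.lambda0 * np.exp(1.0)
        p0 = isi_density(poisson_model, 1.0, 0.0, ages)
        assert np.allclose(p0, lam * np.exp(-lam * ages), rtol=1e-6)

    def test_zero_inside_absolute_block(self, blocked_model):
        ages = np.arange(0.0, 1000.0, 0.5)
        p0 = isi_density(blocked_model, 0.0, 0.0, ages)
        blk = blocked_model.eta.absolute_block
        assert np.all(p0[ages < blk] == 0.0)
        assert p0[ages >= blk].max() > 0

    def test_matches_simulated_isi_distribution(self, model):
        # Monte-Carlo cross-check at a constant 60 pA once the population has
        # reached its stationary state (Kolmogorov-Smirnov distance < 0.03)
        h = Trace(0.5, np.full(50_000, model.h_infinity(60.0)), unit="")
        sim = qrpop.simulate_population(model, h=h, n_neurons=400, seed=21)
        isis = np.concatenate(
            [np.diff(t[t > 10_000.0]) for t in sim.raster.spike_trains()]
        )
        sol = steady_rate(model, I_const=60.0)
        cdf_grid = np.cumsum(sol.isi_density) * sol.dt
        cdf_grid /= cdf_grid[-1]

        def cdf(x):
            return np.interp(x, sol.ages, cdf_grid)

        d, _ = stats.kstest(isis, cdf)
        assert isis.size > 5000
        assert d < 0.03


class TestSteadyRate:
    def test_poisson_rate(self, poisson_model):
        sol = steady_rate(poisson_model, I_const=40.0)
        expected = poisson_model.lambda0 * np.exp(poisson_model.h_infinity(40.0))
        # quadrature of the mean ISI is O((lam*dt)^2) accurate
        assert sol.A_inf == pytest.approx(expected, rel=1e-4)

    def test_absolute_block_closed_form(self, blocked_model):
        # a finer age grid resolves the hazard discontinuity at the block edge
        sol = steady_rate(blocked_model, I_const=0.0, dt=0.125)
        lam = blocked_model.lambda0
        assert sol.A_inf == pytest.approx(lam / (1 + lam * 50.0), rel=2e-3)

    def test_solution_invariants(self, model):
        for I in (10.0, 40.0, 70.0):
            sol = steady_rate(model, I_const=I)
            assert sol.isi_normalization == pytest.approx(1.0, abs=1e-3)
            assert sol.A_inf * sol.mean_isi == pytest.approx(1.0, abs=1e-3)
            assert np.all(sol.isi_density >= 0)

    def test_monotone_in_input(self, model):
        rates = [steady_rate(model, I_const=I).A_inf for I in (0.0, 20.0, 40.0, 60.0)]
        assert np.all(np.diff(rates) > 0)

    def test_three_routes_agree(self, model):
        # time-domain QR plateau, stationary fixed point, and (weak SAP)
        # the closed-form Lambert-W gain
        weak = model.with_eta_scaled(0.1)
        sol = steady_rate(weak, I_const=30.0)
        h = Trace(0.5, np.full(30_000, weak.h_infinity(30.0)), unit="")
        plateau = qrpop.encode_qr(weak, h).values[-1]
        gain = eme1_gain(weak, I_const=30.0)
        assert plateau == pytest.approx(sol.A_inf, rel=0.01)
        assert gain == pytest.approx(sol.A_inf, rel=0.03)


class TestAutocorrelation:
    def test_poisson_flat_at_rate_squared(self, poisson_model):
        lags, c, delta_w, sol = autocorrelation(poisson_model, I_const=40.0)
        assert delta_w == pytest.approx(sol.A_inf)
        assert np.allclose(c, sol.A_inf**2, rtol=5e-3)

    def test_decorrelation_at_long_lags(self, model):
        lags, c, _, sol = autocorrelation(model, I_const=60.0, max_lag=4000.0)
        tail = c[lags > 3000.0]
        assert np.allclose(tail, sol.A_inf**2, rtol=0.02)

    def test_refractory_dip_at_short_lags(self, model):
        lags, c, _, sol = autocorrelation(model, I_const=60.0)
        assert c[0] < 0.2 * sol.A_inf**2

    def test_matches_empirical_autocorrelation(self, model):
        # scaled-down Monte-Carlo referent: binned spike-count correlations
        # of the stationary population match A*m(s) within MC error bands
        h = Trace(0.5, np.full(60_000, model.h_infinity(70.0)), unit="")
        sim = qrpop.simulate_population(
            model, h=h, n_neurons=400, seed=5, record_spikes=False
        )
        counts = sim.counts[20_000:]  # stationary part
        n = 400
        dt = 0.5
        rate = counts.sum() / (counts.size * n * dt)
        lags_bins = np.array([40, 100, 200, 400, 800])  # 20..400 ms
        emp, se = [], []
        for L in lags_bins:
            x, y = counts[:-L], counts[L:]
            # E[x y] / (n^2 dt^2) estimates A*m + A^2 cross terms absorbed
            prod = x.astype(float) * y
            emp.append(prod.mean() / (n * dt) ** 2)
            se.append(prod.std() / np.sqrt(prod.size) / (n * dt) ** 2)
        lags, c, _, sol = autocorrelation(model, I_const=70.0, lags=lags_bins * dt)
        # empirical product includes the same-neuron term A*m plus the
        # across-neuron contribution (n-1)/n * A^2 from independent neurons
        theory = c / n + (n - 1) / n * sol.A_inf**2
        for e, s, t in zip(emp, se, theory):
            assert e == pytest.approx(t, abs=4 * s)


class TestEME1Gain:
    def test_no_sap_limit(self, poisson_model):
        g = eme1_gain(poisson_model, I_const=25.0)
        expected = poisson_model.lambda0 * np.exp(poisson_model.h_infinity(25.0))
        assert g == pytest.approx(expected, rel=1e-12)

    def test_matches_converged_eme1_plateau(self, model):
        h = Trace(0.5, np.full(30_000, model.h_infinity(50.0)), unit="")
        plateau = qrpop.encode_eme1(model, h).values[-1]
        assert eme1_gain(model, I_const=50.0) == pytest.approx(plateau, rel=1e-3)

    def test_monotone_in_h_and_concave_in_drive(self, model):
        hs = np.linspace(-1.0, 6.0, 30)
        a = np.array([eme1_gain(model, h_inf=h) for h in hs])
        assert np.all(np.diff(a) > 0)
        # Lambert-W property: concave as a function of the exponentiated
        # drive x = lam0 e^h (uniform grid in x)
        xs = np.linspace(0.001, 0.2, 40)
        ax = np.array([eme1_gain(model, h_inf=np.log(x / model.lambda0)) for x in xs])
        assert np.all(np.diff(ax, 2) < 1e-12)
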