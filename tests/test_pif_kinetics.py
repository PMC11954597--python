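"""Plasma input functions and compartment models against independent oracles."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from pafpdd import (ABY029_PIF, IRDYE680LT_PIF, BiexpPIF, KineticParams,
                    PulsatileConfig, TimeSeries, eval_pif, modulate_pif,
                    one_compartment, tumor_model)


class TestBiexpPIF:
    @pytest.mark.parametrize("pif,expected", [
        (ABY029_PIF, 0.95 + 0.48),
        (IRDYE680LT_PIF, 5.2 + 0.35),
    ])
    def test_peak_is_sum_of_amplitudes(self, pif, expected):
        assert pif(0.0) == pytest.approx(expected)
        assert pif.peak == pytest.approx(expected)

    def test_scalar_evaluation_matches_closed_form(self):
        # direct scalar evaluation at t = 10 min
        expected = 0.95 * np.exp(-2.3) + 0.48 * np.exp(-0.026)
        assert ABY029_PIF(10.0) == pytest.approx(expected, rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            ABY029_PIF(np.array([-1.0, 0.0]))
        with pytest.raises(ValueError):
            eval_pif(ABY029_PIF, np.arange(-5.0, 5.0))

    def test_fast_component_must_come_first(self):
        with pytest.raises(ValueError):
            BiexpPIF(1.0, 0.01, 1.0, 0.5)

    def test_eval_pif_on_uniform_grid(self):
        t = np.arange(0.0, 60.0, 0.5)
        ts = eval_pif(ABY029_PIF, t)
        assert isinstance(ts, TimeSeries)
        np.testing.assert_allclose(ts.values, ABY029_PIF(t))


class TestModulatePIF:
    def _const(self, c=2.0, dt_s=0.05, minutes=5.0):
        n = int(minutes * 60 / dt_s) + 1
        return TimeSeries(0.0, dt_s / 60.0, np.full(n, c), time_unit="min")

    def test_zero_alpha_is_identity(self):
        cfg = PulsatileConfig(alpha=0.0, duration_min=5.0)
        cp = self._const()
        out = modulate_pif(cp, cfg)
        np.testing.assert_array_equal(out.values, cp.values)

    def test_mean_over_integer_periods_unchanged(self):
        cfg = PulsatileConfig(alpha=0.2, duration_min=5.0)
        out = modulate_pif(self._const(c=3.0), cfg)
        # 5 min = 300 cardiac periods at 60 bpm; drop the last sample to
        # cover an integer number of periods
        assert out.values[:-1].mean() == pytest.approx(3.0, rel=1e-12)

    def test_peak_to_trough_excursion(self):
        c, alpha = 2.5, 0.3
        cfg = PulsatileConfig(alpha=alpha, duration_min=5.0)
        out = modulate_pif(self._const(c=c), cfg)
        assert out.values.max() - out.values.min() == pytest.approx(c * alpha, rel=1e-3)

    def test_grid_mismatch_rejected(self):
        cfg = PulsatileConfig(dt_s=0.05, duration_min=5.0)
        bad = TimeSeries(0.0, 0.1, np.ones(100), time_unit="s")
        with pytest.raises(ValueError):
            modulate_pif(bad, cfg)

    def test_nyquist_guard(self):
        with pytest.raises(ValueError):
            PulsatileConfig(heart_rate_bpm=60.0, dt_s=0.6)


class TestOneCompartment:
    def test_zero_influx_gives_zero(self, minute_grid):
        kp = KineticParams(K1=0.0, k2=0.08)
        cf = one_compartment(ABY029_PIF, kp, minute_grid)
        np.testing.assert_array_equal(cf.values, 0.0)

    def test_steady_state_for_constant_plasma(self):
        # effectively constant plasma level via a vanishing decay rate
        c = 2.0
        pif = BiexpPIF(1e-12, 1.0, c, 1e-12)
        kp = KineticParams(K1=0.1, k2=0.08)
        t = np.arange(0.0, 500.0, 1.0)
        cf = one_compartment(pif, kp, t)
        assert cf.values[-1] == pytest.approx(kp.K1 * c / kp.k2, rel=1e-3)

    def test_against_ode_integration(self, minute_grid):
        kp = KineticParams(K1=0.1, k2=0.08)
        cf = one_compartment(ABY029_PIF, kp, minute_grid)

        sol = solve_ivp(lambda t, y: kp.K1 * ABY029_PIF(t) - kp.k2 * y[0],
                        (0, 300), [0.0], t_eval=minute_grid,
                        rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(cf.values[1:], sol.y[0][1:], rtol=1e-3)
        assert cf.values[0] == 0.0
        assert np.all(cf.values >= 0)

    def test_linear_in_pif_amplitude(self, minute_grid):
        kp = KineticParams(K1=0.1, k2=0.08)
        base = one_compartment(ABY029_PIF, kp, minute_grid).values
        doubled_pif = BiexpPIF(2 * 0.95, 0.23, 2 * 0.48, 0.0026)
        doubled = one_compartment(doubled_pif, kp, minute_grid).values
        np.testing.assert_allclose(doubled, 2 * base, rtol=1e-12)

    def test_nonuniform_grid_rejected(self):
        kp = KineticParams(K1=0.1, k2=0.08)
        with pytest.raises(ValueError):
            one_compartment(ABY029_PIF, kp, np.array([0.0, 1.0, 3.0]))


def _rk4_oracle(pif, kp, t_end=300.0, dt=0.01):
    """Fixed-step classic RK4 integration of the two-compartment system."""
    def rhs(tt, y):
        cf, cb = y
        bind = kp.kon * (kp.Bmax - cb) * cf
        return np.array([kp.K1 * pif(tt) - kp.k2 * cf - bind + kp.koff * cb,
                         bind - kp.koff * cb])

    n = int(round(t_end / dt))
    y = np.zeros(2)
    out = [y.copy()]
    for i in range(n):
        tt = i * dt
        k1 = rhs(tt, y)
        k2 = rhs(tt + dt / 2, y + dt / 2 * k1)
        k3 = rhs(tt + dt / 2, y + dt / 2 * k2)
        k4 = rhs(tt + dt, y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        out.append(y.copy())
    return np.array(out)


class TestTumorModel:
    def test_reduction_to_one_compartment_when_kon_zero(self, minute_grid, kinetics):
        kp = kinetics.without_binding()
        cf, cb = tumor_model(ABY029_PIF, kp, minute_grid)
        np.testing.assert_array_equal(cb.values, 0.0)
        ref = one_compartment(ABY029_PIF, kp, minute_grid)
        np.testing.assert_allclose(cf.values[1:], ref.values[1:], rtol=1e-4)

    def test_bound_pool_saturates_below_bmax(self, minute_grid, kinetics):
        _, cb = tumor_model(ABY029_PIF, kinetics, minute_grid)
        assert cb.values.max() <= kinetics.Bmax
        assert cb.values[0] == 0.0

    def test_against_fixed_step_rk4(self, kinetics):
        t = np.arange(0.0, 301.0, 1.0)
        cf, cb = tumor_model(ABY029_PIF, kinetics, t)
        oracle = _rk4_oracle(ABY029_PIF, kinetics)[::100]  # every 1 min
        total = cf.values + cb.values
        total_oracle = oracle[:, 0] + oracle[:, 1]
        err = np.abs(total[1:] - total_oracle[1:]) / np.abs(total_oracle[1:])
        assert err.max() < 1e-3

    def test_not_linear_in_pif_amplitude(self, minute_grid, kinetics):
        cf, cb = tumor_model(ABY029_PIF, kinetics, minute_grid)
        big_pif = BiexpPIF(5 * 0.95, 0.23, 5 * 0.48, 0.0026)
        cf5, cb5 = tumor_model(big_pif, kinetics, minute_grid)
        total, total5 = cf.values + cb.values, cf5.values + cb5.values
        # saturable binding breaks homogeneity
        assert np.abs(total5[1:] / total[1:] - 5.0).max() > 0.05

    def test_non_negative_outputs(self, minute_grid, kinetics):
        cf, cb = tumor_model(IRDYE680LT_PIF, kinetics, minute_grid)
        assert np.all(cf.values >= 0) and np.all(cb.values >= 0)
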