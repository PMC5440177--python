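"""Compartmental forward model and weighted Nelder-Mead fitting."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from petquant import (CompartmentalParams, PlasmaInputFunction, fit_2kbv,
                      fit_4kbv, simulate_tissue_tac, vt_from_params)
from conftest import TRUE_4K


class TestVT:
    def test_one_tissue(self):
        assert vt_from_params(CompartmentalParams(0.1, 0.05)) == pytest.approx(2.0)

    def test_two_tissue(self):
        p = CompartmentalParams(0.1, 0.05, 0.03, 0.01)
        assert vt_from_params(p) == pytest.approx(8.0)

    def test_k3_zero_reduces_to_one_tissue(self):
        p2 = CompartmentalParams(0.1, 0.05)
        p4 = CompartmentalParams(0.1, 0.05, 0.0, 0.01)
        assert vt_from_params(p4) == pytest.approx(vt_from_params(p2))

    def test_zero_k2_rejected(self):
        with pytest.raises(ValueError):
            vt_from_params(CompartmentalParams(0.1, 0.0))


class TestForwardModel:
    def test_zero_k1_gives_pure_blood_signal(self, ppif, schedule):
        p = CompartmentalParams(0.0, 0.05, bv=0.04)
        tac = simulate_tissue_tac(p, ppif, schedule)
        from petquant._conv import frame_average
        blood = frame_average(ppif.whole_blood, ppif.time,
                              schedule.frame_start, schedule.frame_end)
        np.testing.assert_allclose(tac.activity, 0.04 * blood, rtol=1e-12)

    def test_integrator_limit(self, ppif, schedule):
        # k2 -> 0, bv = 0: tissue accumulates K1 * integral of ppIF
        p = CompartmentalParams(0.1, 1e-12, bv=0.0)
        tac = simulate_tissue_tac(p, ppif, schedule)
        from scipy.integrate import cumulative_trapezoid
        integral = cumulative_trapezoid(ppif.parent_plasma, ppif.time, initial=0)
        from petquant._conv import frame_average
        expected = 0.1 / 60.0 * frame_average(integral, ppif.time,
                                              schedule.frame_start,
                                              schedule.frame_end)
        np.testing.assert_allclose(tac.activity, expected, rtol=1e-6)

    def test_matches_ode_oracle(self, ppif, schedule):
        """Convolution solution vs direct stiff ODE integration of the
        two-tissue system."""
        p = CompartmentalParams(0.1, 0.05, 0.03, 0.01, 0.0)

        def rhs(t, y):
            cp = np.interp(t, ppif.time, ppif.parent_plasma)
            c1, c2 = y
            return [p.K1 / 60 * cp - (p.k2 + p.k3) / 60 * c1 + p.k4 / 60 * c2,
                    p.k3 / 60 * c1 - p.k4 / 60 * c2]

        sol = solve_ivp(rhs, (0, schedule.total_duration), [0, 0],
                        t_eval=ppif.time, rtol=1e-10, atol=1e-12, method="LSODA")
        from petquant._conv import frame_average
        oracle = frame_average(sol.y.sum(axis=0), ppif.time,
                               schedule.frame_start, schedule.frame_end)
        tac = simulate_tissue_tac(p, ppif, schedule)
        np.testing.assert_allclose(tac.activity[2:], oracle[2:], rtol=1e-3)
        assert np.max(np.abs(tac.activity - oracle)) <= 1e-3 * oracle.max()

    def test_linear_in_input_amplitude(self, ppif, schedule):
        p = TRUE_4K
        scaled = PlasmaInputFunction(ppif.time, 2.5 * ppif.parent_plasma,
                                     2.5 * ppif.whole_blood)
        t1 = simulate_tissue_tac(p, ppif, schedule)
        t2 = simulate_tissue_tac(p, scaled, schedule)
        np.testing.assert_allclose(t2.activity, 2.5 * t1.activity, rtol=1e-12)


class TestFitting:
    def test_2kbv_noiseless_recovery(self, ppif, schedule, equal_weights):
        p = CompartmentalParams(0.1, 0.05, bv=0.05)
        tac = simulate_tissue_tac(p, ppif, schedule)
        res = fit_2kbv(tac, ppif, equal_weights)
        assert res.converged
        assert res.vt_or_bp == pytest.approx(2.0, rel=0.01)

    def test_4kbv_noiseless_recovery(self, tac_4k, ppif, equal_weights):
        res = fit_4kbv(tac_4k, ppif, equal_weights)
        assert res.converged
        assert res.vt_or_bp == pytest.approx(8.0, rel=0.02)

    def test_4kbv_on_one_tissue_data_nests(self, ppif, schedule, equal_weights):
        p = CompartmentalParams(0.1, 0.05, bv=0.0)
        tac = simulate_tissue_tac(p, ppif, schedule)
        res = fit_4kbv(tac, ppif, equal_weights)
        assert res.vt_or_bp == pytest.approx(2.0, rel=0.02)

    def test_rss_at_truth_beats_start(self, tac_4k, ppif, schedule, equal_weights):
        from petquant.compartmental import START_4KBV, _weighted_rss
        start = CompartmentalParams(START_4KBV["K1"], START_4KBV["k2"],
                                    START_4KBV["k3"], START_4KBV["k4"],
                                    START_4KBV["bv"])
        sim_start = simulate_tissue_tac(start, ppif, schedule)
        w = equal_weights.values
        rss_truth = _weighted_rss(tac_4k.activity,
                                  simulate_tissue_tac(TRUE_4K, ppif,
                                                      schedule).activity, w)
        rss_start = _weighted_rss(tac_4k.activity, sim_start.activity, w)
        assert rss_truth < rss_start

    def test_vt_invariant_to_input_rescaling(self, tac_4k, ppif, schedule,
                                             equal_weights):
        from petquant import TimeActivityCurve
        c = 3.0
        scaled_if = PlasmaInputFunction(ppif.time, c * ppif.parent_plasma,
                                        c * ppif.whole_blood)
        scaled_tac = TimeActivityCurve(schedule, c * tac_4k.activity)
        res = fit_4kbv(scaled_tac, scaled_if, equal_weights)
        assert res.vt_or_bp == pytest.approx(8.0, rel=0.02)

    def test_noisy_replicates_median_vt(self, tac_4k, ppif, schedule,
                                        equal_weights):
        """Count-scaled noise, many replicates: the median fitted VT stays
        within 5% of the generating value."""
        rng = np.random.default_rng(11)
        lam = schedule.decay_constant
        decay = np.exp(-lam * schedule.frame_mid)
        ndc = tac_4k.activity * decay
        # region-level noise: count-statistics scaling, ~1% at late frames
        sd = np.sqrt(np.maximum(ndc, 1e-3 * ndc.max())
                     / (schedule.frame_duration * 40.0))
        from petquant import TimeActivityCurve
        vts = []
        for _ in range(100):
            noisy = (ndc + sd * rng.standard_normal(24)) / decay
            res = fit_4kbv(TimeActivityCurve(schedule, noisy), ppif,
                           equal_weights)
            vts.append(res.vt_or_bp)
        assert np.median(vts) == pytest.approx(8.0, rel=0.05)
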