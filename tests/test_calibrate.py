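"""Calibration, correction, alpha2M subtraction and failure detection."""

import numpy as np
import pytest

from tgedge import (
    ConditionMeta,
    KineticParams,
    make_calibrator_well,
    simulate_fluorescence,
    simulate_free_thrombin,
)
from tgedge.calibrate import (
    ActivityCurve,
    CorrectionSpec,
    FailureStatus,
    FailureThresholds,
    ThrombinCurve,
    cat_correct,
    detect_failure,
    fit_calibrator,
    internal_linear,
    subtract_alpha2m,
)
from tgedge.plate import Well, ROLE_CALIBRATOR, ROLE_SAMPLE
from tgedge.smoothing import RateCurve, SmootherSpec, differentiate
from tgedge.simulate import ife_inverse


def _linear_calibrator(b=120.0, c=50.0, n=61):
    t = np.linspace(0, 30, n)
    return Well("C1", ROLE_CALIBRATOR, ConditionMeta(), t, c + b * t)


class TestFitCalibrator:
    def test_linear_calibrator_slope_and_vanishing_high_orders(self):
        w = _linear_calibrator(b=120.0)
        m = fit_calibrator(w, order=3, activity=100.0)
        assert m.slope0 == pytest.approx(120.0, abs=1e-6)
        coeffs = m.poly.convert().coef
        assert np.allclose(coeffs[2:], 0.0, atol=1e-6)
        assert m.monotone_ok

    def test_saturating_calibrator_initial_slope_matches_analytic(
        self, noiseless_optics
    ):
        cond = ConditionMeta()
        w, _ = make_calibrator_well(noiseless_optics, cond)
        m = fit_calibrator(w, order=4)
        # analytic: gain * Phi'(0) * kcat (E/1000) S0/(Km+S0)
        v0 = (
            noiseless_optics.gain
            * cond.kcat * (cond.calibrator_activity / 1000.0)
            * cond.substrate_total / (cond.Km + cond.substrate_total)
        )
        assert m.slope0 == pytest.approx(v0, rel=0.02)

    def test_quartic_residual_not_worse_than_cubic(self, noiseless_optics):
        w, _ = make_calibrator_well(noiseless_optics, ConditionMeta())
        y = w.rfu - w.rfu[0]
        r3 = np.sum((fit_calibrator(w, 3).poly(w.times) - y) ** 2)
        r4 = np.sum((fit_calibrator(w, 4).poly(w.times) - y) ** 2)
        assert r4 <= r3 + 1e-9

    def test_rejects_sample_role_and_flat_wells(self):
        t = np.linspace(0, 30, 61)
        s = Well("S1", ROLE_SAMPLE, ConditionMeta(), t, t * 2)
        with pytest.raises(ValueError, match="not a calibrator"):
            fit_calibrator(s)
        flat = Well("C1", ROLE_CALIBRATOR, ConditionMeta(), t,
                    np.full_like(t, 5.0))
        with pytest.raises(ValueError, match="slope"):
            fit_calibrator(flat)


class TestInternalLinear:
    def test_calibrator_rate_maps_to_assigned_activity(self):
        m = fit_calibrator(_linear_calibrator(b=120.0), activity=100.0)
        rate = RateCurve(np.linspace(0, 30, 61),
                         np.full(61, 120.0))
        out = internal_linear(rate, m)
        assert np.allclose(out.amidolytic, 100.0, atol=1e-6)

    def test_zero_rate_maps_to_zero(self):
        m = fit_calibrator(_linear_calibrator(), activity=100.0)
        rate = RateCurve(np.linspace(0, 30, 61), np.zeros(61))
        assert np.allclose(internal_linear(rate, m).amidolytic, 0.0)

    def test_ife_suppresses_uncorrected_peak_monotonically(
        self, ife_spike_plate
    ):
        # uncorrected peaks shrink as the spiked fluorophore grows
        tphs = []
        for s in (0.0, 47.0, 70.0, 102.0, 200.0):
            lab = f"spike{s:g}_fviii1"
            well = ife_spike_plate.sample_wells(lab)[0]
            cal = ife_spike_plate.calibrator_wells(lab)[0]
            m = fit_calibrator(cal, 3)
            rate = differentiate(well, SmootherSpec("none"))
            tphs.append(internal_linear(rate, m).amidolytic.max())
        assert np.all(np.diff(tphs) < 0)


class TestCatCorrect:
    def test_linear_regime_equals_internal_linear(self, linear_regime_plate):
        well = linear_regime_plate.sample_wells("lin")[0]
        cal = linear_regime_plate.calibrator_wells("lin")[0]
        m = fit_calibrator(cal, 3)
        spec = CorrectionSpec(poly_order=3, smoother=SmootherSpec("none"))
        ac = cat_correct(well, m, spec)
        il = internal_linear(differentiate(well, SmootherSpec("none")), m)
        scale = il.amidolytic.max()
        assert np.max(np.abs(ac.amidolytic - il.amidolytic)) / scale < 0.01

    def test_calibrator_self_correction_is_flat(self, noiseless_optics):
        # the corrected calibrator sits flat at its assigned activity
        w, _ = make_calibrator_well(noiseless_optics, ConditionMeta())
        m = fit_calibrator(w, 3)
        ac = cat_correct(
            w, m, CorrectionSpec(poly_order=3,
                                 smoother=SmootherSpec("none"))
        )
        dev = np.abs(ac.amidolytic - m.activity) / m.activity
        assert dev.max() < 0.02

    def test_corrected_sample_tracks_ground_truth(self, noiseless_optics):
        cond = ConditionMeta(label="x")
        truth = simulate_free_thrombin(KineticParams(), cond)
        well = simulate_fluorescence(truth, noiseless_optics, cond)
        calw, _ = make_calibrator_well(noiseless_optics, cond)
        m = fit_calibrator(calw, 3)
        ac = cat_correct(
            well, m,
            CorrectionSpec(poly_order=3, smoother=SmootherSpec("none")),
        )
        resid = ac.amidolytic - truth.amidolytic
        assert np.sqrt(np.mean(resid**2)) / truth.amidolytic.max() < 0.03

    def test_matches_brute_force_optics_inversion(self, noiseless_optics):
        # oracle: undo the IFE transform and Michaelis factor directly
        # from the simulator's own optics and substrate trajectory
        cond = ConditionMeta(label="x")
        truth = simulate_free_thrombin(KineticParams(), cond)
        well = simulate_fluorescence(truth, noiseless_optics, cond)
        calw, _ = make_calibrator_well(noiseless_optics, cond)
        m = fit_calibrator(calw, 3)
        ac = cat_correct(
            well, m,
            CorrectionSpec(poly_order=3, smoother=SmootherSpec("none")),
        )
        x = ife_inverse(
            (well.rfu - noiseless_optics.dark_offset)
            / noiseless_optics.gain,
            noiseless_optics.ife_K,
        )
        P = x - cond.amc_spike
        S = cond.substrate_total - P
        dP = np.gradient(P, well.times)
        E_oracle = 1000.0 * dP * (cond.Km + S) / (cond.kcat * S)
        resid = (ac.amidolytic - E_oracle)[2:-2]
        assert np.sqrt(np.mean(resid**2)) / E_oracle.max() < 0.03

    def test_refuse_policy_aborts_out_of_range_spike(self, ife_spike_plate):
        lab = "spike200_fviii1"
        well = ife_spike_plate.sample_wells(lab)[0]
        cal = ife_spike_plate.calibrator_wells(lab)[0]
        m = fit_calibrator(cal, 3)
        ac = cat_correct(well, m, CorrectionSpec(range_policy="refuse"))
        assert ac.status.code == "no_curve"
        assert np.all(np.isnan(ac.amidolytic))

    def test_extrapolate_policy_caps_and_flags(self, ife_spike_plate):
        lab = "spike200_fviii1"
        well = ife_spike_plate.sample_wells(lab)[0]
        cal = ife_spike_plate.calibrator_wells(lab)[0]
        m = fit_calibrator(cal, 3)
        spec = CorrectionSpec(range_policy="extrapolate", max_gain=20.0)
        ac = cat_correct(well, m, spec)
        assert ac.status.code == "nonphysical"
        assert np.all(np.isfinite(ac.amidolytic))

    def test_gauge_invariance_under_rfu_rescaling(self, noiseless_optics):
        # multiplying the optical gain rescales every RFU but leaves
        # calibrated activities unchanged
        cond = ConditionMeta(label="x")
        truth = simulate_free_thrombin(KineticParams(), cond)
        well = simulate_fluorescence(truth, noiseless_optics, cond)
        calw, _ = make_calibrator_well(noiseless_optics, cond)
        spec = CorrectionSpec(poly_order=3, smoother=SmootherSpec("none"))
        c = 3.7
        well2 = Well(well.well_id, well.role, cond, well.times,
                     well.rfu * c)
        calw2 = Well(calw.well_id, calw.role, cond, calw.times,
                     calw.rfu * c)
        a1 = cat_correct(well, fit_calibrator(calw, 3), spec).amidolytic
        a2 = cat_correct(well2, fit_calibrator(calw2, 3), spec).amidolytic
        assert np.allclose(a1, a2, rtol=1e-9, atol=1e-9)
        r1 = internal_linear(
            differentiate(well, SmootherSpec("none")),
            fit_calibrator(calw, 3),
        ).amidolytic
        r2 = internal_linear(
            differentiate(well2, SmootherSpec("none")),
            fit_calibrator(calw2, 3),
        ).amidolytic
        assert np.allclose(r1, r2, rtol=1e-9, atol=1e-9)


def _forward_construct(t, T_true, k):
    E = np.empty_like(T_true)
    acc = 0.0
    E[0] = T_true[0]
    dt = np.diff(t)
    for i in range(1, t.size):
        acc += T_true[i - 1] * dt[i - 1]
        E[i] = T_true[i] + k * acc
    return E


class TestAlpha2mSubtraction:
    t = np.arange(0, 60.0001, 0.5)
    T_true = 300.0 * (t / 5.0) ** 3 * np.exp(-t / 1.8)

    def test_zero_k_is_identity(self):
        ac = ActivityCurve(self.t, self.T_true.copy())
        tc = subtract_alpha2m(ac, "fixed_k", k=0.0)
        assert np.array_equal(tc.free_thrombin, self.T_true)

    def test_fixed_k_inverts_forward_construction(self):
        k = 0.05
        E = _forward_construct(self.t, self.T_true, k)
        tc = subtract_alpha2m(ActivityCurve(self.t, E), "fixed_k", k=k)
        err = np.max(np.abs(tc.free_thrombin - self.T_true))
        assert err / self.T_true.max() < 1e-6

    def test_auto_k_recovers_capture_rate(self):
        k = 0.05
        E = _forward_construct(self.t, self.T_true, k)
        tc = subtract_alpha2m(ActivityCurve(self.t, E), "auto_k")
        assert tc.k_a2m_used == pytest.approx(k, rel=0.05)
        tail = np.abs(np.mean(tc.free_thrombin[-12:]))
        assert tail < 0.005 * self.T_true.max()

    def test_infeasible_tail_falls_back_with_warning(self):
        E = -np.ones_like(self.t)
        tc = subtract_alpha2m(ActivityCurve(self.t, E), "auto_k")
        assert tc.k_a2m_used == 0.0
        assert "auto_k infeasible" in tc.status.detail

    def test_no_curve_propagates(self):
        ac = ActivityCurve(self.t, np.full_like(self.t, np.nan),
                           status=FailureStatus(code="no_curve"))
        tc = subtract_alpha2m(ac, "auto_k")
        assert tc.status.code == "no_curve"


class TestDetectFailure:
    def test_clean_hemophilia_like_curve_is_ok(self):
        t = np.arange(0, 60.0001, 0.5)
        v = 40.0 * (t / 8.0) ** 3 * np.exp(-t / 2.5)
        st = detect_failure(ThrombinCurve(t, v), activity=100.0)
        assert st.code == "ok"
        assert np.isfinite(st.noise_amplification)

    def test_depletion_second_peak_flagged(self):
        t = np.arange(0, 60.0001, 0.5)
        peak = 300.0 * np.exp(-((t - 8.0) ** 2) / 6.0)
        tail = np.where(t > 40, (t - 40.0) ** 2 * 1.2, 0.0)
        st = detect_failure(ThrombinCurve(t, peak + tail), activity=100.0)
        assert st.code == "nonphysical"
        assert "re-ascends" in st.detail

    def test_activity_cap_flagged(self):
        t = np.arange(0, 60.0001, 0.5)
        v = 2000.0 * np.exp(-((t - 10.0) ** 2) / 8.0)
        st = detect_failure(
            ThrombinCurve(t, v), activity=100.0,
            thresholds=FailureThresholds(cap_mult=10.0),
        )
        assert st.code == "nonphysical"

    def test_no_curve_propagates(self):
        t = np.arange(0, 10.0, 0.5)
        tc = ThrombinCurve(t, np.full_like(t, np.nan),
                           status=FailureStatus(code="no_curve"))
        assert detect_failure(tc, 100.0).code == "no_curve"
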