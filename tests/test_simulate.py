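"""Forward-simulator tests: kinetics ODEs, substrate consumption, optics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tgedge import (
    ConditionMeta,
    KineticParams,
    OpticsParams,
    generate_plate,
    ife_transform,
    make_calibrator_well,
    simulate_fluorescence,
    simulate_free_thrombin,
    spike_preconsumption_percent,
)
from tgedge.simulate import integrate_first_order


class TestThrombinKinetics:
    def test_zero_drive_gives_zero_everywhere(self):
        g = simulate_free_thrombin(
            KineticParams(gen_amplitude=0.0), ConditionMeta(duration=20)
        )
        assert np.all(g.free_thrombin == 0)
        assert np.all(g.a2m_thrombin == 0)
        assert np.all(g.amidolytic == 0)

    def test_constant_drive_no_decay_grows_linearly(self):
        delta, n, c = 0.02, 1501, 80.0
        T = integrate_first_order(np.full(n, c), delta, 0.0)
        t = np.arange(n) * delta
        assert np.allclose(T, c * t, atol=1e-9)

    def test_constant_drive_with_decay_matches_closed_form(self):
        # dT/dt = c - kT  =>  T = (c/k)(1 - e^{-kt})
        delta, n, c, k = 0.025, 2401, 100.0, 0.3
        t = np.arange(n) * delta
        T = integrate_first_order(np.full(n, c), delta, k)
        closed = c / k * (1.0 - np.exp(-k * t))
        rel = np.abs(T[1:] - closed[1:]) / closed.max()
        assert rel.max() < 1e-4

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            simulate_free_thrombin(
                KineticParams(gen_tau=-1.0), ConditionMeta()
            )
        with pytest.raises(ValueError):
            simulate_free_thrombin(
                KineticParams(at_fraction=1.5), ConditionMeta()
            )
        with pytest.raises(ValueError):
            simulate_free_thrombin(
                KineticParams(gen_amplitude=float("nan")), ConditionMeta()
            )

    def test_hemophilia_peak_far_below_normal(self):
        cond1 = ConditionMeta(fviii_level=1.0)
        cond0 = ConditionMeta(fviii_level=0.0)
        k = KineticParams()
        tph1 = simulate_free_thrombin(k, cond1).free_thrombin.max()
        tph0 = simulate_free_thrombin(k, cond0).free_thrombin.max()
        assert tph0 < 0.3 * tph1

    @given(
        amp=st.floats(10.0, 1000.0),
        k_at=st.floats(0.0, 2.0),
        k_a2m=st.floats(0.0, 0.2),
        frac=st.floats(0.0, 1.0),
    )
    def test_trajectories_nonnegative_and_complex_monotone(
        self, amp, k_at, k_a2m, frac
    ):
        kin = KineticParams(
            gen_amplitude=amp, k_at=k_at, k_a2m=k_a2m,
            a2m_amidolytic_fraction=frac,
        )
        g = simulate_free_thrombin(kin, ConditionMeta(duration=30))
        assert np.all(g.free_thrombin >= 0)
        assert np.all(g.a2m_thrombin >= 0)
        assert np.all(np.diff(g.a2m_thrombin) >= -1e-12)


class TestSubstrateAndOptics:
    def test_dead_well_is_flat_dark_offset(self):
        cond = ConditionMeta(duration=20)
        truth = simulate_free_thrombin(
            KineticParams(gen_amplitude=0.0), cond
        )
        opt = OpticsParams(noise_sd=0.0)
        w = simulate_fluorescence(truth, opt, cond)
        assert np.allclose(w.rfu, opt.dark_offset, atol=1e-9)

    def test_first_order_limit_matches_exponential_decay(self):
        # Km >> S0 and constant E: S = S0 exp(-kcat (E/1000) t / Km)
        cond = ConditionMeta(
            substrate_total=100.0, Km=1e6, kcat=60000.0,
            calibrator_activity=100.0, duration=30,
        )
        opt = OpticsParams(ife_K=None, noise_sd=0.0)
        w, truth = make_calibrator_well(opt, cond)
        t = truth.times
        rate = cond.kcat * (100.0 / 1000.0) / cond.Km
        S_closed = 100.0 * np.exp(-rate * t)
        assert np.max(np.abs(truth.substrate - S_closed)) / 100.0 < 1e-3
        F_closed = opt.dark_offset + opt.gain * (100.0 - S_closed)
        assert np.max(np.abs(w.rfu - F_closed)) / F_closed.max() < 1e-3

    def test_substrate_conservation_and_monotone_product(
        self, noiseless_optics, default_kinetics
    ):
        cond = ConditionMeta(label="x")
        truth = simulate_free_thrombin(default_kinetics, cond)
        simulate_fluorescence(truth, noiseless_optics, cond)
        total = truth.substrate + truth.product
        assert np.max(np.abs(total - cond.substrate_total)) \
            < 1e-9 * cond.substrate_total
        assert np.all(np.diff(truth.product) >= -1e-12)

    def test_noiseless_fluorescence_nondecreasing(
        self, noiseless_optics, default_kinetics
    ):
        cond = ConditionMeta()
        truth = simulate_free_thrombin(default_kinetics, cond)
        w = simulate_fluorescence(truth, noiseless_optics, cond)
        assert np.all(np.diff(w.rfu) >= -1e-9)

    def test_baseline_increases_sublinearly_with_spike(
        self, noiseless_optics, default_kinetics
    ):
        # bench spike grid: baseline strictly increasing, increments
        # shrinking under a finite inner filter effect
        spikes = [0.0, 47.0, 70.0, 102.0, 200.0]
        f0 = []
        for s in spikes:
            cond = ConditionMeta(amc_spike=s)
            truth = simulate_free_thrombin(default_kinetics, cond)
            w = simulate_fluorescence(truth, noiseless_optics, cond)
            f0.append(w.rfu[0])
        f0 = np.array(f0)
        assert np.all(np.diff(f0) > 0)
        per_uM = np.diff(f0) / np.diff(spikes)
        assert np.all(np.diff(per_uM) < 0)

    def test_afc_substrate_raises_baseline_before_cleavage(
        self, noiseless_optics, default_kinetics
    ):
        cond0 = ConditionMeta(afc_substrate=0.0)
        cond1 = ConditionMeta(afc_substrate=400.0)
        t0 = simulate_free_thrombin(default_kinetics, cond0)
        t1 = simulate_free_thrombin(default_kinetics, cond1)
        w0 = simulate_fluorescence(t0, noiseless_optics, cond0)
        w1 = simulate_fluorescence(t1, noiseless_optics, cond1)
        expect = noiseless_optics.afc_bleed_coeff * 400.0
        assert w1.rfu[0] - w0.rfu[0] == pytest.approx(expect, rel=1e-9)

    def test_grid_mismatch_and_bad_km_raise(self, default_kinetics):
        cond = ConditionMeta()
        truth = simulate_free_thrombin(default_kinetics, cond)
        other = ConditionMeta(duration=30)
        with pytest.raises(ValueError):
            simulate_fluorescence(truth, OpticsParams(), other)
        with pytest.raises(ValueError):
            bad = ConditionMeta(Km=-5.0)
            bad.validate()

    def test_ground_truth_recoverable_by_inversion_oracle(
        self, default_kinetics
    ):
        # brute force: E = 1000 dP/dt (Km+S) / (kcat S), dP/dt numeric
        # on a fine grid
        cond = ConditionMeta(sampling_interval=3.0, duration=30)
        opt = OpticsParams(ife_K=None, noise_sd=0.0)
        truth = simulate_free_thrombin(default_kinetics, cond)
        simulate_fluorescence(truth, opt, cond)
        P, S, t = truth.product, truth.substrate, truth.times
        dP = np.gradient(P, t)
        mask = slice(5, -5)
        E_est = 1000.0 * dP[mask] * (cond.Km + S[mask]) / (
            cond.kcat * S[mask]
        )
        scale = truth.amidolytic.max()
        assert np.max(np.abs(E_est - truth.amidolytic[mask])) / scale < 1e-3

    def test_terminal_slope_positive_from_complex_activity(
        self, noiseless_optics
    ):
        # residual alpha2M-thrombin keeps cleaving: sloped tail
        kin = KineticParams(k_a2m=0.05, a2m_amidolytic_fraction=0.6)
        cond = ConditionMeta()
        truth = simulate_free_thrombin(kin, cond)
        w = simulate_fluorescence(truth, noiseless_optics, cond)
        assert truth.substrate[-1] > 0
        assert w.rfu[-1] - w.rfu[-2] > 0


class TestIfeTransform:
    @given(st.floats(0.001, 2000.0), st.floats(1.0, 5000.0))
    def test_concave_increasing_below_identity(self, x, K):
        y = float(ife_transform(x, K))
        assert 0 < y < x or x < 1e-8
        # concavity: midpoint value above chord
        y2 = float(ife_transform(2 * x, K))
        assert y > y2 / 2

    def test_identity_limit_and_unit_initial_slope(self):
        x = np.linspace(0, 100, 11)
        assert np.allclose(ife_transform(x, None), x)
        eps = 1e-6
        assert float(ife_transform(eps, 350.0)) / eps == pytest.approx(
            1.0, abs=1e-5
        )


class TestCalibratorWells:
    def test_linear_regime_calibrator_is_straight(self, linear_optics):
        cond = ConditionMeta(substrate_total=50000.0, duration=40)
        w, _ = make_calibrator_well(linear_optics, cond)
        coef = np.polyfit(w.times, w.rfu, 1)
        resid = w.rfu - np.polyval(coef, w.times)
        ss_tot = np.sum((w.rfu - w.rfu.mean()) ** 2)
        r2 = 1 - np.sum(resid**2) / ss_tot
        assert r2 > 0.999

    def test_finite_ife_calibrator_rate_strictly_decreasing(
        self, noiseless_optics
    ):
        w, _ = make_calibrator_well(noiseless_optics, ConditionMeta())
        rate = np.diff(w.rfu)
        assert np.all(np.diff(rate) < 0)

    def test_spiked_calibrator_higher_baseline_lower_initial_rate(
        self, noiseless_optics
    ):
        w0, _ = make_calibrator_well(noiseless_optics, ConditionMeta())
        ws, _ = make_calibrator_well(
            noiseless_optics, ConditionMeta(amc_spike=100.0)
        )
        assert ws.rfu[0] > w0.rfu[0]
        assert ws.rfu[1] - ws.rfu[0] < w0.rfu[1] - w0.rfu[0]

    def test_nonpositive_activity_rejected(self, noiseless_optics):
        with pytest.raises(ValueError):
            make_calibrator_well(
                noiseless_optics, ConditionMeta(calibrator_activity=0.0)
            )


class TestPlateGeneration:
    def test_ife_spike_layout(self, ife_spike_plate):
        # 5 spikes x 2 plasma states = 10 sample conditions, each with
        # a paired calibrator group
        labels = ife_spike_plate.condition_labels()
        assert len(labels) == 10
        for lab in labels:
            assert len(ife_spike_plate.calibrator_wells(lab)) >= 1

    def test_fixed_seed_is_bit_identical(self):
        cfg = {"scenario": "ife_spike",
               "params": {"amc_spikes": [0.0, 100.0],
                          "fviii_levels": [1.0]}}
        p1 = generate_plate(cfg, seed=7)
        p2 = generate_plate(cfg, seed=7)
        for w1, w2 in zip(p1.wells, p2.wells):
            assert w1.well_id == w2.well_id
            assert np.array_equal(w1.rfu, w2.rfu)

    def test_substrate_reduction_calibrators_match_s0(self):
        cfg = {"scenario": "substrate_reduction",
               "params": {"substrate_totals": [416.0, 20.8],
                          "fviii_levels": [1.0]}}
        plate = generate_plate(cfg, seed=2)
        for lab in plate.condition_labels():
            s0 = plate.sample_wells(lab)[0].condition.substrate_total
            for cw in plate.calibrator_wells(lab):
                assert cw.condition.substrate_total == s0

    def test_unknown_scenario_and_missing_calibrator_raise(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            generate_plate({"scenario": "nope"}, seed=0)
        with pytest.raises(ValueError, match="calibrator"):
            generate_plate(
                {"scenario": "ife_spike", "calibrator_replicates": 0},
                seed=0,
            )


def test_spike_preconsumption_percent_arithmetic():
    assert spike_preconsumption_percent(104.0, 416.0) == pytest.approx(25.0)
    with pytest.raises(ValueError):
        spike_preconsumption_percent(10.0, 0.0)
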