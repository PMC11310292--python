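import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import endoctrl as ec


class TestSteadyStateEstrogen:
    @pytest.mark.parametrize("F, r, mu, expected", [
        (0.0, 20.0, 5.94, 0.0),
        (50.0, 20.0, 5.94, 168.35016835),
        (360.0, 20.0, 5.94, 1212.12121212),
    ])
    def test_values(self, F, r, mu, expected):
        assert ec.steady_state_estrogen(F, r, mu) == pytest.approx(expected)

    def test_zero_washout_rejected(self):
        with pytest.raises(ValueError):
            ec.steady_state_estrogen(50.0, 20.0, 0.0)


class TestControlSchedule:
    def test_alternating_square_wave(self):
        s = ec.ControlSchedule.alternating(u_b=0.9, phase_on=1.0,
                                           phase_off=2.0, start=5.0)
        t = np.array([4.9, 5.0, 5.5, 6.1, 7.5, 8.0, 8.5])
        np.testing.assert_allclose(s.u_of(t), [0, 0.9, 0.9, 0, 0, 0.9, 0.9])
        switches = s.switch_times(5.0, 11.0)
        assert switches == [6.0, 8.0, 9.0]

    def test_tabulated_piecewise_linear(self):
        s = ec.ControlSchedule.tabulated([0.0, 1.0, 2.0], [0.0, 0.5, 0.0])
        assert s.u_of(0.5) == pytest.approx(0.25)
        assert s.u_of(5.0) == pytest.approx(0.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            ec.ControlSchedule(kind="alternating", u_b=1.0)
        with pytest.raises(ValueError):
            ec.ControlSchedule(kind="alternating", phase_on=0.0)
        with pytest.raises(ValueError):
            ec.ControlSchedule(kind="mystery")

    @settings(max_examples=50, derandomize=True)
    @given(t=st.floats(0.0, 50.0), u_b=st.floats(0.0, 0.99),
           on=st.floats(0.1, 5.0), off=st.floats(0.1, 5.0))
    def test_alternating_values_are_on_or_off(self, t, u_b, on, off):
        s = ec.ControlSchedule.alternating(u_b, on, off, start=3.0)
        assert s.u_of(t) in (0.0, u_b)


class TestIntegrate:
    def test_basic_cd_qualitative(self, table1):
        params, init = table1
        traj = ec.integrate("basic", params,
                            ec.BaseState(**{k[0]: v for k, v in init["CD"].items()}),
                            (0.0, 15.0))
        T, E, F = traj["T"], traj["E"], traj["F"]
        assert np.all(np.diff(F) <= 1e-12)              # fat only decreases
        assert T[-1] <= 1.0 / params.m1 * (1 + 1e-6)     # logistic bound
        assert np.all(E <= max(170.0, params.r * 50.0 / params.mu) * (1 + 1e-6))
        assert T[-1] > T[0]

    def test_tumor_free_fixed_point(self, table1):
        params, _ = table1
        traj = ec.integrate("basic", params, [0.0, 10.0, 80.0], (0.0, 30.0))
        assert np.allclose(traj["T"], 0.0, atol=1e-12)
        assert np.allclose(traj["F"], 80.0, rtol=1e-9)
        # estrogen relaxes to its fat-sustained steady state
        assert traj["E"][-1] == pytest.approx(
            ec.steady_state_estrogen(80.0, params.r, params.mu), rel=1e-6)

    def test_extended_reaches_carrying_capacity(self, ia):
        sc, params = ia
        traj = ec.integrate("extended", params, ec.initial_state("CD", sc),
                            (0.0, 60.0), grid_dt=0.1)
        assert traj.tumor_burden[-1] == pytest.approx(1.0 / params.m1, rel=0.02)

    def test_fat_conserved_without_growth_or_consumption(self, ia):
        _, params = ia
        params = params.replace(alpha=0.0, k2=0.0)
        traj = ec.integrate("extended", params, [1.0, 0.0, 170.0, 50.0],
                            (0.0, 10.0))
        assert np.allclose(traj["F"], 50.0, rtol=1e-9)

    def test_grid_refinement_convergence(self, ia):
        sc, params = ia
        init = ec.initial_state("CD", sc)
        sched = ec.ControlSchedule.alternating(0.99, 1.0, 1.0, start=14.0)
        a = ec.integrate("extended", params, init, (0.0, 25.0),
                         schedule=sched, grid_dt=0.05)
        b = ec.integrate("extended", params, init, (0.0, 25.0),
                         schedule=sched, grid_dt=0.025, rtol=1e-10, atol=1e-12)
        fa, fb = a.final_state(), b.final_state()
        scale = np.maximum(np.abs(fb), 1e-6)
        assert np.max(np.abs(fa - fb) / scale) < 1e-3

    def test_nesting_trajectories(self, table1):
        base, _ = table1
        ext = ec.load_default_extended().replace(c=0.0, k2=0.0)
        tb = ec.integrate("basic", base, [1.0, 170.0, 50.0], (0.0, 15.0))
        te = ec.integrate("extended", ext, [1.0, 0.0, 170.0, 50.0], (0.0, 15.0))
        np.testing.assert_allclose(te["S"], tb["T"], rtol=1e-6)
        np.testing.assert_allclose(te["E"], tb["E"], rtol=1e-6)
        np.testing.assert_allclose(te["F"], tb["F"], rtol=1e-6)

    def test_rejects_bad_inputs(self, table1):
        params, _ = table1
        with pytest.raises(ValueError):
            ec.integrate("basic", params, [1, 170, 50], (5.0, 5.0))
        with pytest.raises(ValueError):
            ec.integrate("basic", params, [-1, 170, 50], (0.0, 1.0))
        with pytest.raises(ValueError):
            ec.integrate("mystery", params, [1, 170, 50], (0.0, 1.0))


class TestDetectTreatmentStart:
    def test_already_detectable(self, ia):
        _, params = ia
        traj = ec.integrate("extended", params, [600.0, 0.0, 170.0, 50.0],
                            (0.0, 2.0))
        assert ec.detect_treatment_start(traj, params.eta, params.m1) == 0.0

    def test_interpolated_crossing_against_refined_grid(self, untreated_ia, ia):
        # the coarse-grid interpolated crossing must sit within one fine
        # grid step of the crossing found on a 10x finer grid
        sc, params = ia
        _, t_coarse = untreated_ia["CD"]
        fine = ec.integrate("extended", params, ec.initial_state("CD", sc),
                            (0.0, sc.t_f), grid_dt=0.005)
        t_fine = ec.detect_treatment_start(fine, params.eta, params.m1)
        assert abs(t_coarse - t_fine) < 0.05

    def test_never_detectable_returns_none(self, ia):
        _, params = ia
        traj = ec.integrate("extended", params, [1.0, 0.0, 170.0, 50.0],
                            (0.0, 1.0))
        assert ec.detect_treatment_start(traj, params.eta, params.m1) is None

    def test_literal_below_reading_available(self, ia):
        # the "first time below threshold" variant fires immediately for a
        # small growing tumor
        sc, params = ia
        traj = ec.integrate("extended", params, ec.initial_state("CD", sc),
                            (0.0, 5.0))
        t = ec.detect_treatment_start(traj, params.eta, params.m1,
                                      direction="down")
        assert t == 0.0

    def test_eta_weighting(self, ia):
        _, params = ia
        traj = ec.integrate("extended", params, [300.0, 300.0, 170.0, 50.0],
                            (0.0, 1.0))
        # with eta=1 composite starts at 600 >= 500 -> immediate
        assert ec.detect_treatment_start(traj, 1.0, params.m1) == 0.0


class TestTrajectoryIO:
    def test_csv_roundtrip(self, tmp_path, ia):
        sc, params = ia
        sched = ec.ControlSchedule.constant(0.5, start=1.0)
        traj = ec.integrate("extended", params, ec.initial_state("CD", sc),
                            (0.0, 3.0), schedule=sched, grid_dt=0.1)
        path = tmp_path / "traj.csv"
        traj.write_csv(path, arm="CD", scenario="Ia", schedule="constant")
        back = ec.Trajectory.read_csv(path)
        np.testing.assert_allclose(back.times, traj.times)
        np.testing.assert_allclose(back["S"], traj["S"])
        np.testing.assert_allclose(back.control, traj.control)

    def test_invariants(self):
        with pytest.raises(ValueError):
            ec.Trajectory(times=[0, 0], states=[[1], [1]], columns=("T",))
        with pytest.raises(ValueError):
            ec.Trajectory(times=[0, 1], states=[[1]], columns=("T",))
        with pytest.raises(ValueError):
            ec.Trajectory(times=[0, 1], states=[[1], [1]], columns=("T",),
                          control=[0.5, 1.0])
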