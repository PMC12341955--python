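import numpy as np
import pytest

import thermoclock as tc
from thermoclock.model import DEFAULT_INITIAL_STATE
from thermoclock.params import PARAM_NAMES


def state(**kw):
    y = DEFAULT_INITIAL_STATE.copy()
    for k, v in kw.items():
        y[tc.STATE_NAMES.index(k)] = v
    return y


class TestCascadeRhs:
    def test_ts1_fixed_point_derivative_zero(self, nominal):
        # 0.13*37 - 0.65*7.4 = 0
        dy = tc.cascade_rhs(state(TS1=7.4), T=37.0, Tavg=37.0, params=nominal)
        assert dy[0] == pytest.approx(0.0, abs=1e-12)

    def test_variation_term_vanishes_at_mean(self, nominal):
        other = nominal.replace(vact1_ts1=123.0)
        a = tc.cascade_rhs(state(), T=37.0, Tavg=37.0, params=nominal)
        b = tc.cascade_rhs(state(), T=37.0, Tavg=37.0, params=other)
        assert np.array_equal(a, b)

    def test_ts2_fixed_point_value(self, nominal):
        # algebraic balance of the Hill surge at TS1 = 7.4 nM
        ts2_star = (nominal.vb_ts2 / nominal.vd_ts2) * 7.4**3 / (20.0**3 + 7.4**3)
        dy = tc.cascade_rhs(state(TS1=7.4, TS2=ts2_star), 37.0, 37.0, nominal)
        assert ts2_star == pytest.approx(0.857, abs=5e-4)
        assert dy[1] == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_hsp_is_domain_error(self, nominal):
        with pytest.raises(tc.DomainError, match="indHSP"):
            tc.cascade_rhs(state(indHSP=0.0), 37.0, 37.0, nominal)


class TestClockRhs:
    def test_hill_at_michaelis_constant_is_half_maximal(self, nominal):
        y = state(nucPERCRY=nominal.k4b, Bmal1_mRNA=0.0)
        y[tc.STATE_NAMES.index("Bmal1_mRNA")] = 1e-300  # positivity guard
        dy = tc.clock_rhs(y, nominal)
        assert dy[3] == pytest.approx(nominal.v4b / 2, rel=1e-12)

    def test_khsf1_zero_decouples_from_cascade(self, nominal):
        dec = nominal.replace(khsf1=0.0)
        a = tc.clock_rhs(state(actHSF1=0.5, indHSP=1.0), dec)
        b = tc.clock_rhs(state(actHSF1=15.0, indHSP=9.0), dec)
        assert np.array_equal(a, b)

    def test_nonpositive_clockbmal1_is_domain_error(self, nominal):
        with pytest.raises(tc.DomainError, match="CLOCKBMAL1"):
            tc.clock_rhs(state(CLOCKBMAL1=0.0), nominal)


class TestCascadeFixedPoint:
    def test_closed_form_components(self, nominal):
        fp = tc.cascade_fixed_point(nominal, 37.0)
        assert fp["TS1"] == pytest.approx(0.13 * 37.0 / 0.65, rel=1e-12)
        assert fp["TS2"] == pytest.approx(0.857, abs=5e-4)
        assert 0 < fp["actHSF1"] < nominal.HSF1tot
        assert fp["indHSP"] > 0

    def test_no_production_gives_zero_sensors(self, nominal):
        fp = tc.cascade_fixed_point(nominal.replace(vact0_ts1=0.0), 37.0)
        assert fp["TS1"] == 0.0
        assert fp["TS2"] == 0.0

    def test_nonpositive_temperature_rejected(self, nominal):
        with pytest.raises(tc.DomainError):
            tc.cascade_fixed_point(nominal, -1.0)

    def test_long_integration_converges_to_fixed_point(self, nominal):
        # independent oracle for the ODE path: algebra vs integration
        fp = tc.cascade_fixed_point(nominal, 37.0)
        traj = tc.simulate(nominal, tc.Schedule.constant(37.0, 600.0))
        for name in ("TS1", "TS2", "actHSF1", "indHSP"):
            assert traj[name][-1] == pytest.approx(fp[name], abs=1e-6)


class TestSimulate:
    def test_trajectory_grid_and_finiteness(self, entrained_trajectory):
        t = entrained_trajectory.time
        assert t[0] == 0.0 and t[-1] == 1200.0
        assert np.all(np.diff(t) > 0)
        assert np.all(np.isfinite(entrained_trajectory.states))
        assert np.all(entrained_trajectory.states > 0)

    def test_acthsf1_bounded_by_total_pool(self, entrained_trajectory, nominal):
        assert np.all(entrained_trajectory["actHSF1"] <= nominal.HSF1tot)

    def test_entrained_phases_are_cycle_stable(self, entrained_trajectory):
        sched = entrained_trajectory.schedule
        for name in ("PerCry_mRNA", "Bmal1_mRNA", "BMAL1"):
            pk = tc.peaks(entrained_trajectory[name], entrained_trajectory.time)
            phases = pk % 24.0
            assert np.all(np.abs(np.diff(phases)) < 0.1)
            assert np.isfinite(tc.phase_of(entrained_trajectory[name],
                                           entrained_trajectory.time, sched))

    def test_invalid_inputs(self, nominal):
        sched = tc.Schedule.constant(37.0, 10.0)
        with pytest.raises(tc.SimulationError):
            tc.simulate(nominal, sched, t_span=(5.0, 5.0))
        with pytest.raises(tc.SimulationError):
            tc.simulate(nominal, sched, init=np.zeros(11))

    def test_csv_round_trip(self, tmp_path, nominal):
        import pandas as pd

        traj = tc.simulate(nominal, tc.Schedule.constant(37.0, 5.0))
        f = tmp_path / "traj.csv"
        traj.to_csv(f)
        df = pd.read_csv(f)
        assert list(df.columns) == ["time_h", *tc.STATE_NAMES]
        assert np.allclose(df["TS1"].to_numpy(), traj["TS1"])


class TestPopulationKernelProperties:
    def test_positivity_over_perturbed_parameter_sets(self):
        # 24 parameter sets jittered ±10% around nominal, 1200 h of square-
        # wave forcing: every component stays positive and finite, and
        # actHSF1 never exceeds the (per-cell) total pool
        spec = tc.PopulationSpec(n_cells=24, rel_width=0.10, seed=7)
        mat = tc.sample_population(spec)
        sched = tc.Schedule.rhythmic(tc.TemperaturePattern(), t_end=1200.0)
        ens = tc.simulate_population(mat, sched)
        assert np.all(np.isfinite(ens.states))
        assert np.all(ens.states > 0)
        tot = mat[:, PARAM_NAMES.index("HSF1tot")]
        assert np.all(ens.component("actHSF1") <= tot[:, None] * (1 + 1e-9))

    def test_decoupled_clock_is_bit_identical_under_cascade_changes(self):
        # with khsf1 = 0 the clock components must not depend on the cascade
        spec = tc.PopulationSpec(n_cells=2, rel_width=0.0, seed=0)
        mat = tc.sample_population(spec)
        mat[:, PARAM_NAMES.index("khsf1")] = 0.0
        other = mat.copy()
        other[:, PARAM_NAMES.index("vact0_ts1")] *= 3.0   # changes TS1/TS2/HSF1
        sched = tc.Schedule.rhythmic(tc.TemperaturePattern(), t_end=480.0)
        clock = ("PerCry_mRNA", "PERCRY", "nucPERCRY", "Bmal1_mRNA", "BMAL1",
                 "nucBMAL1", "CLOCKBMAL1")
        a = tc.simulate_population(mat, sched, components=clock)
        b = tc.simulate_population(other, sched, components=clock)
        assert np.array_equal(a.states, b.states)
        # ... while the cascade itself did change
        ca = tc.simulate_population(mat, sched, components=("TS1",))
        cb = tc.simulate_population(other, sched, components=("TS1",))
        assert not np.allclose(ca.states, cb.states)

    def test_kernel_matches_adaptive_reference(self, nominal, w12c12_1200h,
                                               entrained_trajectory):
        # fixed-step RK4 population path vs LSODA single-cell path
        mat = np.tile(nominal.as_array(), (2, 1))
        ens = tc.simulate_population(mat, w12c12_1200h,
                                     components=("PerCry_mRNA",))
        per_kernel = tc.period_of(ens.component("PerCry_mRNA")[0], ens.time)
        per_ref = tc.period_of(entrained_trajectory["PerCry_mRNA"],
                               entrained_trajectory.time)
        assert per_kernel == pytest.approx(per_ref, abs=5e-3)
        ref = np.interp(ens.time, entrained_trajectory.time,
                        entrained_trajectory["PerCry_mRNA"])
        mask = ens.time >= 480.0
        assert np.max(np.abs(ens.component("PerCry_mRNA")[0] - ref)[mask]) < 5e-3
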