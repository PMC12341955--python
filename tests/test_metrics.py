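import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import thermoclock as tc
from thermoclock.metrics import steady_peaks


@pytest.fixture()
def sine24():
    t = np.arange(0.0, 1200.0, 0.1)
    return t, np.sin(2 * np.pi * t / 24.0)


class TestPeaksAndPeriod:
    def test_sinusoid_peaks_on_quarter_cycle(self, sine24):
        t, x = sine24
        pk = tc.peaks(x, t, burn_in=0.0)
        expected = np.arange(6.0, 1200.0, 24.0)
        assert len(pk) == len(expected)
        assert np.max(np.abs(pk - expected)) < 0.01

    def test_constant_series_flagged_non_oscillatory(self):
        t = np.arange(0.0, 1000.0, 0.1)
        assert len(tc.peaks(np.full_like(t, 3.7), t)) == 0
        assert np.isnan(tc.period_of(np.full_like(t, 3.7), t))

    def test_sinusoid_period(self, sine24):
        t, x = sine24
        assert tc.period_of(x, t, burn_in=0.0) == pytest.approx(24.0, abs=1e-3)

    def test_steady_stage_drops_early_transient(self):
        # early peaks drift, late peaks are evenly spaced: only the stable
        # trailing run feeds the period estimate
        pk = np.array([0.0, 20.0, 41.0, 65.0, 89.0, 113.0, 137.0])
        steady = steady_peaks(pk)
        assert steady.tolist() == [41.0, 65.0, 89.0, 113.0, 137.0]


class TestPhase:
    def test_phase_vs_normal_and_reversed_reference(self):
        t = np.arange(0.0, 1200.0, 0.1)
        x = np.cos(2 * np.pi * (t - 5.0) / 24.0)   # peaks at ZT 5
        normal = tc.Schedule.rhythmic(tc.TemperaturePattern(), t_end=1200.0)
        rev = tc.Schedule.rhythmic(
            tc.TemperaturePattern(reversed_=True), t_end=1200.0)
        assert tc.phase_of(x, t, normal) == pytest.approx(5.0, abs=0.01)
        # reversed pattern: warm onset at ZT12, so the same series is 17 h late
        assert tc.phase_of(x, t, rev) == pytest.approx(17.0, abs=0.01)
        # cold-onset reference swaps the two readings
        assert tc.phase_of(x, t, normal, reference="cold") == \
            pytest.approx(17.0, abs=0.01)

    def test_drifting_series_flagged_unentrained(self):
        t = np.arange(0.0, 1200.0, 0.1)
        x = np.sin(2 * np.pi * t / 25.5)   # free-runs against a 24 h reference
        sched = tc.Schedule.rhythmic(tc.TemperaturePattern(), t_end=1200.0)
        assert np.isnan(tc.phase_of(x, t, sched))

    @pytest.mark.parametrize("after,before,expected", [
        (2.0, 14.0, -12.0),      # half-cycle inversion reports as an advance
        (14.0, 2.0, -12.0),
        (5.0, 4.0, 1.0),
        (0.5, 23.5, 1.0),        # wraps midnight
        (23.5, 0.5, -1.0),
    ])
    def test_phase_shift_convention(self, after, before, expected):
        assert tc.phase_shift(after, before) == pytest.approx(expected)


class TestRSyn:
    def test_identical_cells_give_exactly_one(self):
        t = np.arange(0.0, 240.0, 0.1)
        x = np.sin(2 * np.pi * t / 24.0) + 2.0
        assert tc.r_syn(np.tile(x, (5, 1))) == pytest.approx(1.0, abs=1e-12)

    def test_three_cell_toy_matches_direct_evaluation(self):
        # independent spreadsheet-style evaluation of the variance ratio
        rng = np.random.default_rng(1)
        mat = rng.normal(size=(3, 400)).cumsum(axis=1)
        ybar = mat.mean(axis=0)
        num = np.mean(ybar**2) - np.mean(ybar) ** 2
        den = np.mean([np.mean(r**2) - np.mean(r) ** 2 for r in mat])
        assert tc.r_syn(mat) == pytest.approx(num / den, abs=1e-12)

    def test_uniform_phases_desynchronized(self):
        t = np.arange(0.0, 1200.0, 0.25)
        phases = np.arange(1000) / 1000.0 * 24.0
        mat = np.sin(2 * np.pi * (t[None, :] - phases[:, None]) / 24.0)
        assert tc.r_syn(mat) < 0.01

    def test_flat_population_is_degenerate_not_zero(self):
        mat = np.full((4, 100), 2.5)
        assert np.isnan(tc.r_syn(mat))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_bounded_and_affine_invariant(self, seed):
        rng = np.random.default_rng(seed)
        mat = rng.normal(size=(4, 60))
        r = tc.r_syn(mat)
        assert 0.0 <= r <= 1.0 + 1e-12
        assert tc.r_syn(3.7 * mat - 11.0) == pytest.approx(r, rel=1e-9)

    def test_window_selection(self):
        t = np.arange(0.0, 100.0, 1.0)
        mat = np.vstack([np.sin(t), np.sin(t)])
        mat[:, t > 50] = 1.0   # same in both cells, still synchronized
        assert tc.r_syn(mat, time=t, window=(0.0, 50.0)) == \
            pytest.approx(1.0, abs=1e-12)
        with pytest.raises(ValueError):
            tc.r_syn(mat, time=t, window=(200.0, 300.0))


class TestWindowedRSyn:
    def test_centers_and_values(self):
        t = np.arange(0.0, 96.25, 0.25)
        mat = np.vstack([np.sin(2 * np.pi * t / 24),
                         np.sin(2 * np.pi * t / 24)])
        w = tc.windowed_r_syn(mat, time=t, window_h=24.0)
        assert w["t_center"].tolist() == [12.0, 36.0, 60.0, 84.0]
        assert np.allclose(w["r_syn"], 1.0)


def test_sync_report_round_trip():
    import json

    mat = tc.sample_population(tc.PopulationSpec(n_cells=8, seed=0))
    sched = tc.Schedule.rhythmic(tc.TemperaturePattern(), t_end=720.0)
    ens = tc.simulate_population(mat, sched, components=("PerCry_mRNA",))
    rep = tc.sync_report(ens, "PerCry_mRNA", window=(480.0, 720.0))
    d = json.loads(rep.to_json())
    assert d["component"] == "PerCry_mRNA"
    assert 0.0 <= d["r_syn"] <= 1.0
    assert len(d["phases_h"]) == 8
    assert rep.cell_frame().shape == (8, 2)
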