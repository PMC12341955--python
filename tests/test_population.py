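import numpy as np
import pytest

import thermoclock as tc
from thermoclock.params import PARAM_NAMES
from thermoclock.population import DEFAULT_VARIED_PARAMS, sample_individuals


class TestSamplePopulation:
    def test_zero_width_gives_identical_copies(self, nominal):
        mat = tc.sample_population(tc.PopulationSpec(n_cells=5, rel_width=0.0))
        assert mat.shape == (5, 41)
        assert np.array_equal(mat, np.tile(nominal.as_array(), (5, 1)))

    def test_fixed_seed_is_deterministic(self):
        spec = tc.PopulationSpec(n_cells=64, seed=42)
        assert np.array_equal(tc.sample_population(spec),
                              tc.sample_population(spec))
        other = tc.PopulationSpec(n_cells=64, seed=43)
        assert not np.array_equal(tc.sample_population(spec),
                                  tc.sample_population(other))

    def test_ranges_cover_and_center_on_nominal(self, nominal):
        # brute-force check over a large draw: every varied parameter stays
        # inside +-10% of nominal and its mean lands within 0.5% of nominal
        spec = tc.PopulationSpec(n_cells=8192, rel_width=0.10, seed=3)
        mat = tc.sample_population(spec)
        base = nominal.as_array()
        for name in DEFAULT_VARIED_PARAMS:
            j = PARAM_NAMES.index(name)
            col = mat[:, j]
            assert col.min() >= 0.9 * base[j] - 1e-12
            assert col.max() <= 1.1 * base[j] + 1e-12
            assert abs(col.mean() - base[j]) <= 0.005 * base[j]

    def test_hill_exponents_not_varied(self, nominal):
        mat = tc.sample_population(tc.PopulationSpec(n_cells=32, seed=0))
        for name in ("n", "p", "q", "r"):
            j = PARAM_NAMES.index(name)
            assert np.all(mat[:, j] == getattr(nominal, name))

    def test_invalid_specs(self):
        with pytest.raises(tc.ConfigError):
            tc.PopulationSpec(n_cells=1)
        with pytest.raises(tc.ConfigError):
            tc.PopulationSpec(rel_width=1.0)
        with pytest.raises(tc.ConfigError):
            tc.PopulationSpec(varied=("vact0_ts1", "nope"))


class TestSampleIndividuals:
    def test_triples_within_fold_range(self, nominal):
        spec = tc.IndividualSpec(n_subjects=256, fold_range=(0.5, 2.0), seed=1)
        df = sample_individuals(spec, nominal)
        assert list(df.columns) == ["vact0_ts1", "vact1_ts1", "kb_ts2"]
        for col in df.columns:
            ratio = df[col] / getattr(nominal, col)
            assert ratio.min() >= 0.5 - 1e-12
            assert ratio.max() <= 2.0 + 1e-12
        assert df.equals(sample_individuals(spec, nominal))


class TestSimulatePopulation:
    def test_identical_cells_identical_trajectories(self, nominal):
        mat = np.tile(nominal.as_array(), (3, 1))
        sched = tc.Schedule.rhythmic(tc.TemperaturePattern(), t_end=240.0)
        ens = tc.simulate_population(mat, sched, components=("PerCry_mRNA",))
        assert np.array_equal(ens.states[0], ens.states[1])
        assert np.array_equal(ens.states[0], ens.states[2])
        # the mean field of identical cells equals any single cell (up to
        # summation rounding)
        np.testing.assert_allclose(ens.average("PerCry_mRNA"),
                                   ens.states[0, :, 0], rtol=1e-15)

    def test_removing_a_cell_leaves_others_bit_identical(self):
        mat = tc.sample_population(tc.PopulationSpec(n_cells=5, seed=2))
        sched = tc.Schedule.rhythmic(tc.TemperaturePattern(), t_end=240.0)
        full = tc.simulate_population(mat, sched, components=("PerCry_mRNA",))
        reduced = tc.simulate_population(mat[[0, 1, 3, 4]], sched,
                                         components=("PerCry_mRNA",))
        assert np.array_equal(full.states[[0, 1, 3, 4]], reduced.states)

    def test_shared_grid_and_component_selection(self):
        mat = tc.sample_population(tc.PopulationSpec(n_cells=3, seed=0))
        sched = tc.Schedule.rhythmic(tc.TemperaturePattern(), t_end=120.0)
        ens = tc.simulate_population(mat, sched,
                                     components=("TS1", "PerCry_mRNA"))
        assert ens.states.shape == (3, len(ens.time), 2)
        assert ens.components == ("TS1", "PerCry_mRNA")
        with pytest.raises(KeyError):
            ens.component("BMAL1")

    def test_too_few_cells_rejected(self, nominal):
        sched = tc.Schedule.constant(37.0, 24.0)
        with pytest.raises(tc.SimulationError):
            tc.simulate_population(nominal.as_array()[None, :], sched)

    def test_integration_failure_names_the_cell(self, nominal):
        # a cell with zero HSP production drives indHSP to 0 -> flagged
        mat = np.tile(nominal.as_array(), (2, 1))
        mat[1, PARAM_NAMES.index("vb_hsp")] = 0.0
        sched = tc.Schedule.constant(37.0, 48.0)
        with pytest.raises(tc.SimulationError, match="cell 1"):
            tc.simulate_population(mat, sched)


class TestEnsembleAverage:
    def test_pointwise_mean(self):
        ens = tc.Ensemble(
            time=np.arange(4.0),
            states=np.array([[[1.0]] * 4, [[2.0]] * 4, [[3.0]] * 4]),
            components=("PerCry_mRNA",),
            param_matrix=np.zeros((3, 41)),
            schedule=tc.Schedule.constant(37.0, 4.0),
        )
        assert np.array_equal(tc.ensemble_average(ens, "PerCry_mRNA"),
                              np.full(4, 2.0))

    def test_antiphase_sinusoids_average_flat(self):
        t = np.arange(0.0, 48.0, 0.1)
        a = np.sin(2 * np.pi * t / 24)
        ens = tc.Ensemble(
            time=t, states=np.stack([a, -a])[:, :, None],
            components=("PerCry_mRNA",), param_matrix=np.zeros((2, 41)),
            schedule=tc.Schedule.constant(37.0, 48.0),
        )
        assert np.allclose(ens.average("PerCry_mRNA"), 0.0)
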