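"""Shared fixtures.

The heavier population runs (200 cells, shift schedules, the subject sweep)
are session-scoped so that several acceptance checks can share one
simulation.
"""

import numpy as np
import pytest

import thermoclock as tc
from thermoclock import experiments as ex


@pytest.fixture(scope="session")
def nominal():
    return tc.ModelParameters()


@pytest.fixture(scope="session")
def w12c12_1200h():
    return tc.Schedule.rhythmic(tc.TemperaturePattern(), t_end=1200.0)


@pytest.fixture(scope="session")
def entrained_trajectory(nominal, w12c12_1200h):
    """Nominal single cell under W12/C12 37±1.5 degC, adaptive reference
    integration."""
    return tc.simulate(nominal, w12c12_1200h)


@pytest.fixture(scope="session")
def pop200():
    return tc.PopulationSpec(n_cells=200, seed=0)


@pytest.fixture(scope="session")
def amplitude_sweep(pop200):
    """Amplitude sweep 0/1/3/5 degC plus the khsf1=0 control, 200 cells."""
    return ex.run_amplitude_sweep(pop200)


@pytest.fixture(scope="session")
def ass_752(pop200):
    """Shift-work protocol: 50 d normal, then 7-5:2 (R:N) for 100 d."""
    return ex.run_ass("7-5:2", pop200)


@pytest.fixture(scope="session")
def ass_752_low_amplitude(pop200):
    """Same protocol with the reversed-pattern amplitude lowered to 1 degC."""
    return ex.run_ass("7-5:2", pop200, dTr=1.0)


@pytest.fixture(scope="session")
def individual_sweep_table():
    """40 subjects x 50 cells under the nominal schedule and three ASSs."""
    return ex.run_individual_sweep(tc.IndividualSpec(n_subjects=40, seed=0),
                                   cells_per_subject=50)
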