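import numpy as np
import pytest

from gqsignal import synthetic
from gqsignal.trace_io import StimulusEvent, StimulusSchedule, TimeSeriesTrace

NOISELESS = synthetic.NoiseParams(0.0, 0.0, 0.0)


@pytest.fixture
def noiseless_config():
    """Single-stimulus, zero-noise, zero-variability configuration."""
    return synthetic.SimulationConfig(
        n_cells=1, cell_cv=0.0, noise=NOISELESS, seed=1
    )


@pytest.fixture(scope="session")
def default_population():
    """20-cell default-noise population shared by read-only tests."""
    cfg = synthetic.SimulationConfig(n_cells=20, seed=11)
    return synthetic.simulate_population(cfg)


@pytest.fixture
def opto_schedule():
    """Receptor + blue-light stimulation with light-off at 360 s."""
    return StimulusSchedule(events=[
        StimulusEvent(60.0, "ligand_add", "bombesin", "1 uM"),
        StimulusEvent(60.0, "light_on", "445nm"),
        StimulusEvent(360.0, "light_off", "445nm"),
    ])


def make_trace(time, intensity, cell="c0", channel="PH", compartment="cytosol"):
    return TimeSeriesTrace(cell_id=cell, channel=channel,
                           compartment=compartment,
                           time=np.asarray(time, dtype=float),
                           intensity=np.asarray(intensity, dtype=float))
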