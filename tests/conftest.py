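import numpy as np
import pytest

from fertdyn.synthetic_data import SimulationConfig, simulate_trials
from fertdyn.trial_model import ExperimentDesign


@pytest.fixture(scope="session")
def one_site_records():
    """12-pair single-site experiment, no treatment effect (null truth)."""
    design = ExperimentDesign(sites=(("SB", 12, ("8.03", "7.87", "7.76")),))
    records, truth = simulate_trials(SimulationConfig(design=design), seed=42)
    return records, truth


@pytest.fixture(scope="session")
def two_site_records():
    """Small two-site experiment for cross-site model structure tests."""
    design = ExperimentDesign(
        sites=(("FC", 4, ("8.03", "7.76", "7.61")),
               ("SB", 4, ("8.03", "7.87", "7.76")))
    )
    records, truth = simulate_trials(SimulationConfig(design=design), seed=7)
    return records, truth


@pytest.fixture(scope="session")
def decline_records():
    """Single-site experiment with a true 46% decline in beta at low pH."""
    design = ExperimentDesign(sites=(("SB", 12, ("8.03", "7.87", "7.76")),))
    truth = {("SB", "7.76"): {"beta": 3e-4 * 0.54}}
    records, tt = simulate_trials(
        SimulationConfig(design=design, truth=truth), seed=11
    )
    return records, tt


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
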