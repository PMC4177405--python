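import pytest
from hypothesis import HealthCheck, settings

from popcal.models import FAST_INDICATOR, SceneModel
from popcal.pipeline import analyze_session
from popcal.protocol import StimulusProtocol
from popcal.synthetic import make_population_tuning, simulate_population
from popcal.traces import CorrectionConfig

settings.register_profile(
    "deterministic", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def protocol():
    """Default grating protocol: 4 s blank / 4 s stim, 8 dirs, 15 Hz."""
    return StimulusProtocol()


@pytest.fixture(scope="session")
def short_protocol():
    """Small protocol for fast structural tests."""
    return StimulusProtocol(
        blank_duration=2.0, stim_duration=2.0, n_directions=4,
        n_trials_per_direction=2,
    )


@pytest.fixture(scope="session")
def tuned_session(protocol):
    """A simulated 60-cell all-tuned population and its analyzed session."""
    tuning = make_population_tuning(60, protocol, tuned_fraction=1.0, rng=42)
    scene = SceneModel(n_cells=60, seed=42)
    sim = simulate_population(protocol, scene, tuning, FAST_INDICATOR, seed=43)
    session = analyze_session(
        sim.measured, sim.measured_neuropil, protocol,
        CorrectionConfig(indicator="fast"),
    )
    return sim, session


@pytest.fixture(scope="session")
def noiseless_sim(protocol):
    """Zero-noise 10-cell simulation for exact-recovery checks."""
    tuning = make_population_tuning(10, protocol, tuned_fraction=1.0, rng=7)
    scene = SceneModel(n_cells=10, seed=7, gaussian_noise_fraction=0.0)
    return simulate_population(protocol, scene, tuning, FAST_INDICATOR, seed=8)
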