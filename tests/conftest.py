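"""Shared fixtures: default morphology, models and cached traces.

Session scope keeps the expensive simulations to one run each; everything
is deterministic, so caching cannot leak state between tests (models are
rebuilt where mutation matters).
"""
import numpy as np
import pytest

from tjunction import (
    build_geometry,
    discretize,
    build_membrane,
    SimulationConfig,
    StimulusProtocol,
    run_simulation,
)
from tjunction import protocols as proto


@pytest.fixture(scope="session")
def default_graph():
    return discretize(build_geometry())


@pytest.fixture(scope="session")
def passive_model(default_graph):
    return build_membrane(default_graph, passive_only=True)


@pytest.fixture(scope="session")
def passive_step_trace(passive_model):
    """Small hyperpolarizing somatic step on the passive model."""
    cfg = SimulationConfig(
        dt_ms=0.025,
        duration_ms=700.0,
        record_sites=(("soma", 0.0), ("junction", 0.0)),
        sample_ms=0.1,
    )
    stim = StimulusProtocol(
        site=("soma", 0.0), amplitude_nA=-0.01, width_ms=400.0, onset_ms=50.0
    )
    return run_simulation(passive_model, [stim], cfg), stim


@pytest.fixture(scope="session")
def active_model():
    return proto.make_model()


@pytest.fixture(scope="session")
def orthodromic_trace(active_model):
    """Single orthodromic spike with recordings at the standard sites."""
    sites = (
        ("soma", 0.0),
        ("junction", 0.0),
        ("peripheral", 3500.0),
        ("peripheral", 1500.0),
        ("central", 1500.0),
        ("central", 3500.0),
        ("central", 5000.0),
    )
    cfg = SimulationConfig(
        dt_ms=0.01, duration_ms=60.0, record_sites=sites, sample_ms=0.025
    )
    stim = StimulusProtocol(site=("peripheral", 4600.0))
    return run_simulation(proto.make_model(), [stim], cfg)
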