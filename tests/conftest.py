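"""Shared fixtures: small synthetic cohorts reused across test modules."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from classrsa.synth import SynthConfig, simulate_cohort

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_cohort(rho=0.5, seed=0, n_students=6, n_events=10, n_channels=3,
                duration_range=(6, 30), with_teacher=False, **kw):
    cfg = SynthConfig(n_students=n_students, n_channels=n_channels,
                      n_events=n_events, duration_range=duration_range,
                      embed_strength=rho, embed_channel=1,
                      boundary_amp=kw.pop("boundary_amp", 0.0),
                      global_amp=kw.pop("global_amp", 0.0),
                      seed=seed, **kw)
    return (cfg, *simulate_cohort(cfg, with_teacher=with_teacher))


@pytest.fixture(scope="session")
def small_cohort():
    """Six students, ten events, moderate embedded structure."""
    cfg, ev, students, truth = make_cohort(rho=0.8, seed=11)
    return cfg, ev, students, truth


@pytest.fixture(scope="session")
def noiseless_pair():
    """Two students with a pure embedded signal (rho=1, no noise sources)."""
    cfg, ev, students, truth = make_cohort(rho=1.0, seed=7, n_students=2)
    return cfg, ev, students, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
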