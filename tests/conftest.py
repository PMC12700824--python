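"""Shared fixtures: session-scoped simulated traces reused across modules."""

import numpy as np
import pytest
from hypothesis import settings

from ffstools.simulate import (
    DEFAULT_VOLUME,
    SimulationConfig,
    SpeciesSpec,
    simulate_trace,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def volume():
    return DEFAULT_VOLUME


@pytest.fixture(scope="session")
def trace_occ1():
    """25 s monomer trace: eps_g = 1e4 cts/s, N = 1, D = 25 µm²/s."""
    cfg = SimulationConfig(
        species=(SpeciesSpec(eps_g=1.0e4, mean_occupancy=1.0, D=25.0),),
        duration=25.0,
        seed=101,
    )
    return cfg, simulate_trace(cfg)


@pytest.fixture(scope="session")
def trace_n5():
    """5 s trace at occupancy 5 (amplitude and diffusion-time checks)."""
    cfg = SimulationConfig(
        species=(SpeciesSpec(eps_g=1.0e4, mean_occupancy=5.0, D=25.0),),
        duration=5.0,
        seed=102,
    )
    return cfg, simulate_trace(cfg)


@pytest.fixture(scope="session")
def trace_fcs():
    """10 s (1e5-bin) trace at occupancy 0.5 for correlator checks."""
    cfg = SimulationConfig(
        species=(SpeciesSpec(eps_g=1.0e4, mean_occupancy=0.5, D=25.0),),
        duration=10.0,
        seed=103,
    )
    return cfg, simulate_trace(cfg)


def poisson_trace(lam_g, n_bins, bin_width=1e-4, lam_r=None, seed=0):
    """Uncorrelated Poisson trace (detector-noise-only stand-in)."""
    from ffstools.simulate import PhotonTrace

    rng = np.random.default_rng(seed)
    g = rng.poisson(lam_g, n_bins) if np.isscalar(lam_g) else rng.poisson(lam_g)
    if lam_r is None:
        lam_r = 0.0
    r = rng.poisson(lam_r, n_bins) if np.isscalar(lam_r) else rng.poisson(lam_r)
    return PhotonTrace(bin_width, g, r)
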