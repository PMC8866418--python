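import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dcswave as dw

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


STUDY_MU_A = 0.01
STUDY_DB = 1e-6


@pytest.fixture(scope="session")
def layers2():
    """Two-layer head model: 15 mm superficial slab over a semi-infinite
    deep layer, identical optics, identical baseline dynamics."""
    return (dw.TissueLayer(15.0, 1.0, mu_a=STUDY_MU_A, db=STUDY_DB),
            dw.TissueLayer(math.inf, 1.0, mu_a=STUDY_MU_A, db=STUDY_DB))


@pytest.fixture(scope="session")
def geometry20():
    return dw.DetectionGeometry(rho=20.0, detector_size=2.0,
                                size_convention="radius")


@pytest.fixture(scope="session")
def records_small(layers2, geometry20):
    """10^6 launches at rho = 20 mm (a few hundred detected photons)."""
    return dw.simulate_photons(layers2, geometry20, 1_000_000, seed=101)


@pytest.fixture(scope="session")
def records_big(layers2, geometry20):
    """7.6x10^7 launches at rho = 20 mm (~3x10^4 detected photons); the
    workhorse record set for pathlength-distribution and gated studies."""
    return dw.simulate_photons(layers2, geometry20, 76_000_000, seed=42)


@pytest.fixture(scope="session")
def spectrum_single():
    """Single 800 nm line, in-medium wavevector (n = 1.33)."""
    return dw.discretize_spectrum(800.0, medium_index=1.33)


@pytest.fixture(scope="session")
def dynamics_base(layers2):
    return dw.DynamicsSpec.from_layers(layers2)


@pytest.fixture(scope="session")
def params_mc(spectrum_single):
    """Semi-infinite parameters matched to the transport physics:
    index-matched absorbing boundary => Reff = 0."""
    return dw.SemiInfiniteParams(rho=20.0, mu_s_prime=1.0, mu_a=STUDY_MU_A,
                                 k0=spectrum_single.k0, db=STUDY_DB, reff=0.0)


def synth_reps(records, spectrum, dynamics, n_reps, seed, tb_s=1e-6,
               n_bins=10_000, max_lag=300):
    """Replicate g2 curves from fresh speckle substreams (shared helper)."""
    curves = []
    for rep in range(n_reps):
        s = dw.synthesize_speckle(
            records, spectrum, dynamics, tb_s, n_bins,
            rng_directions=dw.substream(seed, "directions", rep),
            rng_phases=dw.substream(seed, "phases", rep),
            rng_brownian=dw.substream(seed, "brownian", rep))
        curves.append(dw.g2_estimate(s, max_lag))
    return curves
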