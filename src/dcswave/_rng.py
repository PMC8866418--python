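"""Named random substreams derived from one master seed.

Every stochastic stage of the pipeline (photon transport, IRF sampling, initial
phases, scattering-direction draws, Brownian increments, Poisson counting) pulls
an independent generator from a fixed registry, so a single master seed pins the
whole simulation while stages stay statistically independent and individually
reproducible.
"""

from __future__ import annotations

import numpy as np

# Fixed registry: changing these indices silently changes every seeded result.
STREAMS = {
    "transport": 0,
    "irf": 1,
    "phases": 2,
    "directions": 3,
    "brownian": 4,
    "poisson": 5,
    "replicates": 6,
    "subset": 7,
}


def substream(master_seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Generator for the named stage, optionally sub-indexed (e.g. per replicate)."""
    if name not in STREAMS:
        raise KeyError(f"unknown stream {name!r}; known: {sorted(STREAMS)}")
    ss = np.random.SeedSequence(entropy=int(master_seed),
                                spawn_key=(STREAMS[name], int(index)))
    return np.random.default_rng(ss)


def small_seed(master_seed: int, name: str, index: int = 0) -> int:
    """A 31-bit integer seed for code that cannot take a Generator (numba kernels)."""
    ss = np.random.SeedSequence(entropy=int(master_seed),
                                spawn_key=(STREAMS[name], int(index)))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)
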