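"""Seed-substream derivation.

All randomness in the package flows from a single integer seed.  Each stage
draws from its own child generator derived via ``SeedSequence(seed,
spawn_key=(stream_id, index))`` so any stage is reproducible in isolation:
re-running e.g. outcome generation with the same seed gives the same draws
regardless of how many other stages ran before it.
"""

from __future__ import annotations

import numpy as np

# Fixed stream ids; never renumber (would silently change all generated data).
STREAMS = {
    "genotypes": 0,
    "months": 1,
    "heterogeneity": 2,
    "noise": 3,
    "covariates": 4,
    "outcomes": 5,
    "selection": 6,
    "tiebreak": 7,
    "bootstrap": 8,
}


def substream(seed: int, stream: str, index: int = 0) -> np.random.Generator:
    """Return the dedicated child generator for ``stream`` under ``seed``.

    ``index`` distinguishes repeated uses within a stream (one per outcome,
    one per bootstrap replicate, ...).
    """
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(STREAMS[stream], int(index)))
    return np.random.default_rng(ss)
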