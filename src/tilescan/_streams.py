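"""Named random substreams.

All randomness in a run flows from one integer seed; each pipeline stage
draws from its own child stream so that, e.g., changing the number of
permutations cannot perturb the simulated counts.
"""

from __future__ import annotations

import numpy as np

_STAGES = {"design": 0, "sim": 1, "score": 2, "scan": 3, "fixture": 4}


def substream(seed: int, stage: str) -> np.random.Generator:
    """Return the generator for ``stage`` derived from the run ``seed``."""
    if stage not in _STAGES:
        raise KeyError(f"unknown random stream {stage!r}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGES[stage],))
    return np.random.default_rng(ss)
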