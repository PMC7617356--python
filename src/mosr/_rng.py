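"""Named, reproducible random substreams.

Every stochastic stage of the pipeline draws from its own substream of a
single master seed, so stages are individually reproducible and insensitive
to how much randomness other stages consume.
"""

from __future__ import annotations

import numpy as np

# fixed registry: adding names is fine, reordering is a breaking change
_STREAMS = {
    "cohort": 0,
    "outcome": 1,
    "missing": 2,
    "split": 3,
    "gp_init": 4,
    "gp_selection": 5,
    "gp_crossover": 6,
    "gp_mutation": 7,
    "cv": 8,
    "test_eval": 9,
    "shap": 10,
    "fixture": 11,
    "calibrate": 12,
    "background": 13,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Return the generator for the named substream of ``seed``."""
    if name not in _STREAMS:
        raise KeyError(f"unknown substream {name!r}")
    ss = np.random.SeedSequence(int(seed), spawn_key=(_STREAMS[name],))
    return np.random.default_rng(ss)


def substream_seed(seed: int, name: str) -> int:
    """A plain integer seed (< 2**31) derived from the named substream."""
    return int(substream(seed, name).integers(0, 2**31 - 1))
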