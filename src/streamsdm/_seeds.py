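"""Deterministic sub-seed derivation.

All stochastic stages draw their RNG seed from a single master seed via
a fixed splitting rule, so the order in which stages run (or whether a
stage runs at all) never changes the randomness any other stage sees.
"""

from __future__ import annotations

import numpy as np

# stage identifiers; fixed integers so the split is stable across versions
STAGES = {
    "dem": 1,
    "covariates": 2,
    "reflectance": 3,
    "occurrences": 4,
    "surveys": 5,
    "pseudoabsence": 6,
    "forest": 7,
    "permutation": 8,
    "vegetation": 9,
    "conserved": 10,
}


def derive_seed(master: int, *keys: int | str) -> int:
    """Derive a deterministic sub-seed (< 2**31) from a master seed.

    ``keys`` identify the stage and replicate, e.g.
    ``derive_seed(master, "forest", 3)``.
    """
    ints = [int(master) & 0x7FFFFFFF]
    for k in keys:
        ints.append(STAGES[k] if isinstance(k, str) else int(k))
    ss = np.random.SeedSequence(ints)
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def rng_for(master: int, *keys: int | str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master, *keys))
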