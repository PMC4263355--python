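"""Named, independent random streams derived from one master seed.

Every stochastic ingredient of a simulation (topology, delays, background
spike trains, oscillatory drive, initial conditions) draws from its own
``numpy.random.Generator`` so that, e.g., regenerating the background noise
does not perturb the network realization.
"""

from __future__ import annotations

import numpy as np

#: canonical stream names used throughout the package
STREAMS = ("topology", "delays", "background", "oscillation", "init", "trial")


def stream(master_seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Return an independent generator for the named stream.

    Parameters
    ----------
    master_seed:
        The experiment-level seed.
    name:
        Any string label; conventionally one of :data:`STREAMS`.
    index:
        Optional sub-index (e.g. trial number) spawning a further
        independent stream.
    """
    ss = np.random.SeedSequence(master_seed, spawn_key=(_key(name), index))
    return np.random.default_rng(ss)


def _key(name: str) -> int:
    # stable, platform-independent hash of the stream name
    h = 0
    for c in name.encode():
        h = (h * 131 + c) % (2**31 - 1)
    return h
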