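"""Seed fan-out: one user-facing seed, named substreams everywhere else."""

import numpy as np

# fixed stream ids; order is part of the on-disk reproducibility contract
STREAMS = {
    "generator": 1,
    "sampling": 2,
    "forest": 3,
    "geo": 4,
}


def substream(seed: int, name: str, *extra: int) -> np.random.Generator:
    """Return a Generator for the named substream of a global seed."""
    if name not in STREAMS:
        raise KeyError(f"unknown rng substream {name!r}")
    return np.random.default_rng(
        np.random.SeedSequence((int(seed), STREAMS[name], *map(int, extra)))
    )


def child_seed(seed: int, name: str, *extra: int) -> int:
    """A 31-bit integer seed derived from a named substream (for numba kernels)."""
    return int(substream(seed, name, *extra).integers(0, 2**31 - 1))
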