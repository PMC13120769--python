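"""Named, independent random substreams derived from one root seed.

Every stochastic component (adjacency draw, yields, drive realization, ...)
pulls its generator from :func:`substream` with a distinct name, so adding
one more drive realization never perturbs the network draw, and vice versa.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seeds"]


def substream(seed: int, *names: object) -> np.random.Generator:
    """Return a Generator for the substream identified by ``names``.

    Streams with different names (or different root seeds) are
    statistically independent; the same (seed, names) pair always yields
    the same stream.
    """
    key = tuple(zlib.crc32(str(n).encode("utf-8")) for n in names)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=key))


def child_seeds(seed: int, n: int, *names: object) -> np.ndarray:
    """Derive ``n`` integer seeds (< 2**31) for independent child components."""
    state = substream(seed, "child-seeds", *names).integers(0, 2**31 - 1, size=n)
    return np.asarray(state, dtype=np.int64)
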