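"""Named random substreams.

All randomness in the package flows from a single root seed.  Substreams are
derived from the root seed plus a tuple of string names (participant id,
condition, stage ...) hashed with CRC-32, so the stream a given entity sees
does not depend on how many other entities exist or in which order they are
generated.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(root_seed: int, *names: str | int) -> np.random.Generator:
    """Return a Generator for the substream identified by ``names``."""
    key = tuple(
        n if isinstance(n, int) else zlib.crc32(n.encode("utf-8")) for n in names
    )
    ss = np.random.SeedSequence(entropy=int(root_seed), spawn_key=key)
    return np.random.default_rng(ss)


def child_seeds(root_seed: int, n: int, *names: str | int) -> list[int]:
    """Derive ``n`` integer seeds (< 2**31) from a named substream."""
    rng = substream(root_seed, *names)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]
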