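"""Named child random streams derived from one master seed.

Every stochastic component asks for a stream by a stable string name, so
regenerating one artifact (say, the expression matrix) never perturbs the
draws of another (say, the genome sequence).
"""

from __future__ import annotations

import zlib

import numpy as np


def child_rng(master_seed: int, name: str) -> np.random.Generator:
    """Return a Generator seeded from ``master_seed`` and a stable name hash.

    crc32 is stable across platforms and Python versions, unlike ``hash``.
    """
    tag = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, tag]))
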