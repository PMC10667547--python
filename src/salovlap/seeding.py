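"""Deterministic sub-seeding: one master seed reproduces a whole run.

Every randomized stage draws its own integer seed as a pure function of the
master seed and a stage name, so stages can be re-run in isolation and adding a
stage never perturbs the others.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed"]


def derive_seed(master: int, name: str) -> int:
    """Stage seed below 2**31, stable across platforms and runs."""
    tag = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence([int(master), tag])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
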