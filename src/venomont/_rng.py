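"""Deterministic seed fan-out.

A single user-facing seed is split into independent per-component streams
by hashing a stable component label into a ``SeedSequence`` spawn key.
Adding a new generator (new label) therefore never perturbs the streams of
existing components.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, label: str) -> np.random.Generator:
    """Independent RNG for component ``label`` under global ``seed``."""
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))
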