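"""Seeded random-number substreams.

A single master seed is expanded into independent, *named* substreams so
that adding or re-running one stage (say, financial-toxicity labelling)
never perturbs the draws of another (say, survival times).
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def _label_key(label: str) -> int:
    # CRC32 is stable across platforms and Python versions, unlike hash().
    return zlib.crc32(label.encode("utf-8"))


def substream_seed(master_seed: int, label: str) -> int:
    """Derive a deterministic 31-bit child seed from a master seed and a label."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(_label_key(label),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def substream(master_seed: int, label: str) -> np.random.Generator:
    """Return an independent Generator for the named stage."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(_label_key(label),))
    return np.random.default_rng(ss)
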