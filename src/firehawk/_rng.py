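"""Seed fan-out: one user-facing seed, independent child streams per stage."""

from __future__ import annotations

import zlib

import numpy as np


def child_rng(seed: int, label: str) -> np.random.Generator:
    """Return a Generator for ``label`` derived deterministically from ``seed``.

    Stages seeded through distinct labels get statistically independent
    streams, so each pipeline step is reproducible on its own.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(label.encode())]))
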