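"""Stage-keyed seed substreams.

A single run seed governs every stochastic stage; each stage derives an
independent 31-bit seed keyed by its name, so stages can be rerun in
isolation with identical results.
"""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(seed: int, label: str) -> int:
    """Deterministic 31-bit sub-seed for a named stage."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode("utf8"))])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)
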