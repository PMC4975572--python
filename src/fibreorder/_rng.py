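"""Deterministic seed derivation.

All stochastic stages receive sub-seeds derived from one master seed, the fibre's
stable identifier and a component tag, so per-fibre results do not depend on batch
order or on which other fibres are processed alongside.
"""

from __future__ import annotations

import hashlib

_SEED_MOD = 2**31


def derive_seed(master_seed: int, *tags: object) -> int:
    """Hash (master_seed, *tags) into a seed in [0, 2^31).

    SHA-256 based, hence stable across platforms and Python versions.
    """
    h = hashlib.sha256()
    h.update(str(int(master_seed)).encode())
    for tag in tags:
        h.update(b"\x1f")
        h.update(str(tag).encode())
    return int.from_bytes(h.digest()[:8], "big") % _SEED_MOD
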