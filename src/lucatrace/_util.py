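"""Small shared helpers."""

from __future__ import annotations

import hashlib


def subseed(master_seed: int, label: str) -> int:
    """Derive a stream seed < 2**31 from a master seed and a stage label.

    Every stochastic stage of a run draws its own generator from the master
    seed through this rule, so stages stay independent and reproducible.
    """
    digest = hashlib.sha256(f"{int(master_seed)}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)
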