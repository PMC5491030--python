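"""Stable seed derivation shared across modules.

Per-stage seeds are derived from a master seed plus string tokens with CRC32,
so each pipeline stage is reproducible in isolation and seeds never depend on
python hash randomization.  Derived seeds stay below 2**31.
"""

from __future__ import annotations

import zlib


def derive_seed(master: int, *tokens: object) -> int:
    text = repr((int(master),) + tuple(str(t) for t in tokens))
    return zlib.crc32(text.encode("utf-8")) & 0x7FFFFFFF
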