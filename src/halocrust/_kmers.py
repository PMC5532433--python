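"""Shared 2-bit nucleotide encoding and rolling k-mer codes (internal)."""

from __future__ import annotations

import numpy as np

_CODE = np.zeros(256, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _CODE[_c] = _i

_COMP = {65: 84, 84: 65, 67: 71, 71: 67}  # A<->T, C<->G byte values


def encode(seq: str) -> np.ndarray:
    """2-bit codes (A=0 C=1 G=2 T=3; other characters fold to A)."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Packed integer code of every k-window of a 2-bit encoded array."""
    if len(arr) < k:
        return np.empty(0, dtype=np.uint64)
    windows = np.lib.stride_tricks.sliding_window_view(arr, k).astype(np.uint64)
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.uint64)
    return (windows * powers).sum(axis=1)
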