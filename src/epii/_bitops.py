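"""Internal helpers for packing boolean vectors into 64-bit words.

Bit ``i`` of a vector lands in word ``i // 64`` at bit position ``i % 64``
(little-endian bit order).  Padding bits beyond the vector length are always
zero; consumers that complement words must AND with :func:`pad_mask`.
"""

from __future__ import annotations

import numpy as np

WORD = 64

popcount = np.bitwise_count


def n_words(n_bits: int) -> int:
    """Number of 64-bit words needed to hold ``n_bits`` bits."""
    return (n_bits + WORD - 1) // WORD


def pack_bits(bits: np.ndarray) -> np.ndarray:
    """Pack a boolean array along its last axis into uint64 words.

    Parameters
    ----------
    bits
        Array of 0/1 values, shape ``(..., n)``.

    Returns
    -------
    numpy.ndarray
        uint64 array of shape ``(..., n_words(n))`` with zero padding bits.
    """
    bits = np.asarray(bits)
    if bits.dtype != np.uint8:
        bits = bits.astype(np.uint8)
    n = bits.shape[-1]
    w = n_words(n)
    pad = w * WORD - n
    if pad:
        bits = np.concatenate(
            [bits, np.zeros(bits.shape[:-1] + (pad,), np.uint8)], axis=-1
        )
    packed = np.packbits(bits, axis=-1, bitorder="little")
    return np.ascontiguousarray(packed).view(np.uint64)


def unpack_bits(words: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`pack_bits`; returns a uint8 0/1 array of length ``n``."""
    words = np.ascontiguousarray(words)
    bits = np.unpackbits(words.view(np.uint8), axis=-1, bitorder="little")
    return bits[..., :n]


def pad_mask(n_bits: int) -> np.ndarray:
    """uint64 word vector with ones in the first ``n_bits`` bit positions."""
    bits = np.zeros(n_words(n_bits) * WORD, np.uint8)
    bits[:n_bits] = 1
    return pack_bits(bits)
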