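"""Reversible integer transforms: zigzag, delta coding, Stream VByte.

Stream VByte stores each unsigned 32-bit integer in 1-4 little-endian bytes
and keeps the per-integer byte lengths in a *separate* block of control
bytes — 2 bits per integer (byte length minus one), four integers per control
byte, the first integer of each group in the two least-significant bits.
Separating the control stream is what lets vectorised decoders run fast; here
it simply defines the portable byte layout.

Sorted variant-code columns are delta-encoded first (store differences,
invert with a cumulative sum), which turns dense sorted codes into small
integers that Stream VByte packs into one or two bytes each.  Signed field
columns are zigzag-mapped (0,-1,1,-2,... -> 0,1,2,3,...) so that the -1
missing sentinel and small negative scores also encode compactly.

Serialized block layout (consumed by :mod:`varzip.archive_io`)::

    [u32 count, little-endian][control bytes][data bytes]
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

from .errors import CorruptArchiveError, IntegerOverflowError, NotSortedError

_U32_MAX = 1 << 32


@dataclass(frozen=True)
class SvbBlock:
    """A Stream VByte block: count, control bytes, data bytes."""

    count: int
    control: bytes
    data: bytes


def zigzag(n):
    """Map signed to unsigned: 0->0, -1->1, 1->2, -2->3, ...

    Accepts a Python int or an integer ndarray (signed 32-bit domain);
    returns the same shape.
    """
    v = np.asarray(n, dtype=np.int64)
    if v.size and (v.min() < -(1 << 31) or v.max() >= 1 << 31):
        raise IntegerOverflowError("zigzag input outside signed 32-bit range")
    out = ((v << 1) ^ (v >> 63)).astype(np.uint32)
    if out.ndim == 0:
        return int(out)
    return out


def unzigzag(u):
    """Inverse of :func:`zigzag`."""
    v = np.asarray(u, dtype=np.uint64).astype(np.int64)
    out = (v >> 1) ^ -(v & 1)
    if out.ndim == 0:
        return int(out)
    return out.astype(np.int64)


def delta_encode(values) -> np.ndarray:
    """Differences of a non-decreasing u32 sequence; first element kept as is."""
    v = np.asarray(values, dtype=np.uint64)
    if v.size == 0:
        return np.zeros(0, dtype=np.uint32)
    if v.max() >= _U32_MAX:
        raise IntegerOverflowError("delta_encode input exceeds 32 bits")
    d = np.diff(v.astype(np.int64))
    if d.size and d.min() < 0:
        raise NotSortedError("delta_encode requires a non-decreasing sequence")
    return np.concatenate([v[:1], d.astype(np.uint64)]).astype(np.uint32)


def prefix_sum(deltas) -> np.ndarray:
    """Cumulative sum; exact inverse of :func:`delta_encode`."""
    d = np.asarray(deltas, dtype=np.uint64)
    if d.size == 0:
        return np.zeros(0, dtype=np.uint32)
    c = np.cumsum(d)
    if c[-1] >= _U32_MAX:
        raise IntegerOverflowError("prefix_sum overflows 32 bits")
    return c.astype(np.uint32)


def _byte_length_codes(v32: np.ndarray) -> np.ndarray:
    """2-bit code per value: bytes needed minus one (brute thresholds)."""
    return (
        (v32 >= 1 << 8).astype(np.uint8)
        + (v32 >= 1 << 16).astype(np.uint8)
        + (v32 >= 1 << 24).astype(np.uint8)
    )


def svb_encode(values) -> SvbBlock:
    """Encode a u32 sequence as a Stream VByte block."""
    v = np.asarray(values, dtype=np.uint64)
    n = int(v.size)
    if n == 0:
        return SvbBlock(0, b"", b"")
    if v.max() >= _U32_MAX:
        raise IntegerOverflowError("svb_encode input exceeds 32 bits")
    v32 = np.ascontiguousarray(v.astype("<u4"))
    codes = _byte_length_codes(v32)
    pad = (-n) % 4
    grouped = np.concatenate([codes, np.zeros(pad, dtype=np.uint8)]).reshape(-1, 4)
    control = (
        grouped[:, 0]
        | (grouped[:, 1] << 2)
        | (grouped[:, 2] << 4)
        | (grouped[:, 3] << 6)
    ).astype(np.uint8)
    raw = v32.view(np.uint8).reshape(n, 4)
    mask = np.arange(4, dtype=np.uint8) <= codes[:, None]
    return SvbBlock(n, control.tobytes(), raw[mask].tobytes())


def svb_decode(block: SvbBlock) -> np.ndarray:
    """Decode a Stream VByte block back to a u32 array."""
    n = block.count
    if n == 0:
        if block.control or block.data:
            raise CorruptArchiveError("empty block carries trailing bytes")
        return np.zeros(0, dtype=np.uint32)
    n_control = (n + 3) // 4
    if len(block.control) != n_control:
        raise CorruptArchiveError(
            f"control block holds {len(block.control)} bytes, expected {n_control}"
        )
    cb = np.frombuffer(block.control, dtype=np.uint8)
    codes = np.column_stack([(cb >> s) & 0x3 for s in (0, 2, 4, 6)]).ravel()[:n]
    lengths = codes.astype(np.int64) + 1
    total = int(lengths.sum())
    if len(block.data) != total:
        raise CorruptArchiveError(
            f"data block holds {len(block.data)} bytes, expected {total}"
        )
    out = np.zeros((n, 4), dtype=np.uint8)
    mask = np.arange(4) < lengths[:, None]
    out[mask] = np.frombuffer(block.data, dtype=np.uint8)
    return out.view("<u4").ravel().astype(np.uint32)


def pack_block(block: SvbBlock) -> bytes:
    """Serialize: [u32 count LE][control][data]."""
    return struct.pack("<I", block.count) + block.control + block.data


def unpack_block(buf: bytes) -> SvbBlock:
    """Parse a serialized block, verifying byte counts exactly."""
    if len(buf) < 4:
        raise CorruptArchiveError("block shorter than its count header")
    (n,) = struct.unpack_from("<I", buf)
    n_control = (n + 3) // 4 if n else 0
    control = buf[4 : 4 + n_control]
    if len(control) != n_control:
        raise CorruptArchiveError("truncated control block")
    data = buf[4 + n_control :]
    block = SvbBlock(n, control, data)
    svb_decode(block)  # validates data length against the control stream
    return block


def encode_u32_block(values) -> bytes:
    """svb_encode + serialize in one step."""
    return pack_block(svb_encode(values))


def decode_u32_block(buf: bytes) -> np.ndarray:
    """Parse + svb_decode in one step."""
    return svb_decode(unpack_block(buf))
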