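"""Occurrence-map encodings: value list, delta list (hex stream), bitmap.

An occurrence map is the m-bit presence/absence vector of one k-mer across m
experiments (1-based experiment positions; position 1 is the most significant
bit of the first payload byte).  Three codecs compete and the shortest code
wins:

* value list  — the t 1-positions as fixed-width ceil(log2 m)-bit indices;
  only applicable while t*ceil(log2 m) <= 64;
* delta list  — alternating 0-run/1-run lengths <x1, y1, ..., x_{w+1}>,
  each run length emitted as a prefix-coded hexadecimal token (see
  ``hex_encode_integer``), so the stream is a sequence of hex digits;
* bitmap      — the raw m bits.

Ties are broken value list > delta list > bitmap.  All payloads are padded to
byte boundaries; ``bit_length`` records the unpadded length, which is the
quantity bucket assignment ranges over.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np


class CodecError(ValueError):
    """Corrupt payload or inconsistent (kind, m) on decode."""


class EncodingNotApplicable(ValueError):
    """The codec's applicability condition is violated for this map."""


class EncodingKind(enum.IntEnum):
    VALUE_LIST = 0
    DELTA_LIST = 1
    BITMAP = 2


# tie-break priority: lower wins at equal bit_length
_PRIORITY = {EncodingKind.VALUE_LIST: 0, EncodingKind.DELTA_LIST: 1, EncodingKind.BITMAP: 2}


@dataclass(frozen=True)
class OccurrenceMap:
    """Presence/absence of one k-mer across m experiments (1-based)."""

    bits: np.ndarray  # bool, shape (m,)

    def __post_init__(self):
        object.__setattr__(self, "bits", np.asarray(self.bits, dtype=bool))

    @property
    def m(self) -> int:
        return self.bits.size

    @property
    def t(self) -> int:
        return int(self.bits.sum())

    @classmethod
    def from_string(cls, s: str) -> "OccurrenceMap":
        return cls(np.frombuffer(s.encode(), dtype=np.uint8) == ord("1"))

    @classmethod
    def from_positions(cls, m: int, positions) -> "OccurrenceMap":
        bits = np.zeros(m, dtype=bool)
        for p in positions:
            if not 1 <= p <= m:
                raise ValueError(f"position {p} outside 1..{m}")
            bits[p - 1] = True
        return cls(bits)

    def positions(self) -> np.ndarray:
        """1-based indices of the set bits, ascending."""
        return np.flatnonzero(self.bits) + 1

    def to_string(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)

    def __eq__(self, other) -> bool:
        return isinstance(other, OccurrenceMap) and np.array_equal(self.bits, other.bits)


@dataclass(frozen=True)
class EncodedOccurrence:
    kind: EncodingKind
    payload: bytes
    bit_length: int


class _BitWriter:
    """MSB-first bit accumulator."""

    def __init__(self):
        self.acc = 0
        self.nbits = 0

    def write(self, value: int, nbits: int) -> None:
        if value < 0 or value >> nbits:
            raise ValueError(f"{value} does not fit in {nbits} bits")
        self.acc = (self.acc << nbits) | value
        self.nbits += nbits

    def getvalue(self) -> bytes:
        pad = (-self.nbits) % 8
        return ((self.acc << pad) | 0).to_bytes((self.nbits + pad) // 8, "big") if self.nbits else b""


class _BitReader:
    def __init__(self, payload: bytes, bit_length: int):
        self.data = payload
        self.bit_length = bit_length
        self.pos = 0

    def read(self, nbits: int) -> int:
        if self.pos + nbits > self.bit_length:
            raise CodecError("bit stream exhausted")
        out = 0
        for _ in range(nbits):
            byte = self.data[self.pos >> 3]
            out = (out << 1) | ((byte >> (7 - (self.pos & 7))) & 1)
            self.pos += 1
        return out

    @property
    def remaining(self) -> int:
        return self.bit_length - self.pos


def _index_width(m: int) -> int:
    return max(1, math.ceil(math.log2(m)))


# -- value list --------------------------------------------------------------

def encode_value_list(omap: OccurrenceMap) -> EncodedOccurrence:
    m, t = omap.m, omap.t
    if t == 0:
        raise ValueError("all-absent map is never stored")
    if m < 2:
        raise EncodingNotApplicable("value list needs m >= 2")
    width = _index_width(m)
    if t * width > 64:
        raise EncodingNotApplicable(f"t*ceil(log2 m) = {t * width} > 64")
    wr = _BitWriter()
    for p in omap.positions():
        wr.write(int(p) - 1, width)
    return EncodedOccurrence(EncodingKind.VALUE_LIST, wr.getvalue(), t * width)


def _decode_value_list(payload: bytes, bit_length: int, m: int) -> OccurrenceMap:
    width = _index_width(m)
    if bit_length % width:
        raise CodecError("value-list bit length not a multiple of index width")
    rd = _BitReader(payload, bit_length)
    bits = np.zeros(m, dtype=bool)
    prev = -1
    for _ in range(bit_length // width):
        idx = rd.read(width)
        if idx >= m or idx <= prev:
            raise CodecError("value-list indices not ascending within 1..m")
        bits[idx] = True
        prev = idx
    return OccurrenceMap(bits)


# -- delta list ---------------------------------------------------------------

def encode_delta_list(omap: OccurrenceMap) -> list[int]:
    """Alternating run lengths <x1, y1, ..., x_{w+1}> starting and ending with
    a (possibly empty) 0-run; the all-zero map degenerates to <m>."""
    bits = omap.bits.view(np.uint8)
    m = omap.m
    change = np.flatnonzero(bits[1:] != bits[:-1]) + 1
    bounds = np.concatenate([[0], change, [m]])
    runs = np.diff(bounds).tolist()
    if bits[0] == 1:
        runs = [0] + runs
    if bits[-1] == 1:
        runs = runs + [0]
    return runs


def expand_delta_list(runs: list[int], m: int) -> OccurrenceMap:
    if len(runs) % 2 == 0:
        raise CodecError("delta list must have odd length")
    if sum(runs) != m:
        raise CodecError(f"delta-list runs sum to {sum(runs)}, expected {m}")
    vals = np.arange(len(runs)) % 2  # 0-run, 1-run, 0-run, ...
    for i, r in enumerate(runs):
        if r < 0 or (i % 2 == 1 and r < 1) or (0 < i < len(runs) - 1 and i % 2 == 0 and r < 1):
            raise CodecError(f"invalid run length {r} at position {i}")
    return OccurrenceMap(np.repeat(vals, runs).astype(bool))


_HEX_CLASSES = (
    # (upper bound on z, prefix value, prefix bits, value bits)
    (8, 0b1, 1, 3),
    (64, 0b01, 2, 6),
    (512, 0b001, 3, 9),
    (4096, 0b0001, 4, 12),
    (1 << 28, 0b0000, 4, 28),
)


def hex_encode_integer(z: int) -> tuple[int, int]:
    """Prefix-coded token for a run length: (token value, token bit length).

    Token lengths are multiples of 4, so a concatenated stream reads as a
    hexadecimal digit sequence (e.g. z=0 -> 0x8, z=14 -> 0x4E)."""
    if z < 0:
        raise ValueError("run lengths are non-negative")
    for bound, prefix, pbits, vbits in _HEX_CLASSES:
        if z < bound:
            return (prefix << vbits) | z, pbits + vbits
    raise ValueError(f"integer {z} >= 2^28 overflows the 32-bit token class")


def hex_decode_integer(rd: _BitReader) -> int:
    """Read one token; the leading-zero count identifies its class."""
    zeros = 0
    while zeros < 4:
        if rd.read(1) == 1:
            break
        zeros += 1
    vbits = {0: 3, 1: 6, 2: 9, 3: 12, 4: 28}[zeros]
    return rd.read(vbits)


def hex_encode_delta_list(runs: list[int]) -> EncodedOccurrence:
    wr = _BitWriter()
    for z in runs:
        tok, nbits = hex_encode_integer(z)
        wr.write(tok, nbits)
    return EncodedOccurrence(EncodingKind.DELTA_LIST, wr.getvalue(), wr.nbits)


def delta_list_bit_length(runs: list[int]) -> int:
    return sum(hex_encode_integer(z)[1] for z in runs)


def hex_decode_stream(payload: bytes, bit_length: int, m: int) -> list[int]:
    """Parse tokens until the runs sum to m on an x-run (odd token count)."""
    rd = _BitReader(payload, bit_length)
    runs: list[int] = []
    total = 0
    while True:
        runs.append(hex_decode_integer(rd))
        total += runs[-1]
        if total > m:
            raise CodecError(f"delta-list runs exceed m={m}")
        if total == m and len(runs) % 2 == 1:
            break
    if rd.remaining >= 4:
        raise CodecError("trailing tokens after the delta list")
    return runs


# -- bitmap -------------------------------------------------------------------

def encode_bitmap(omap: OccurrenceMap) -> EncodedOccurrence:
    payload = np.packbits(omap.bits.view(np.uint8), bitorder="big").tobytes()
    return EncodedOccurrence(EncodingKind.BITMAP, payload, omap.m)


def _decode_bitmap(payload: bytes, m: int) -> OccurrenceMap:
    if len(payload) < (m + 7) // 8:
        raise CodecError("bitmap payload shorter than m bits")
    bits = np.unpackbits(np.frombuffer(payload, dtype=np.uint8), count=m, bitorder="big")
    return OccurrenceMap(bits.astype(bool))


# -- dispatch -----------------------------------------------------------------

def choose_encoding(omap: OccurrenceMap) -> EncodedOccurrence:
    """Encode with whichever applicable codec yields the shortest code."""
    if omap.t == 0:
        raise ValueError("all-absent map is never stored")
    candidates: list[EncodedOccurrence] = []
    try:
        candidates.append(encode_value_list(omap))
    except EncodingNotApplicable:
        pass
    candidates.append(hex_encode_delta_list(encode_delta_list(omap)))
    candidates.append(encode_bitmap(omap))
    return min(candidates, key=lambda e: (e.bit_length, _PRIORITY[e.kind]))


def decode_occurrence(enc: EncodedOccurrence, m: int) -> OccurrenceMap:
    if enc.kind == EncodingKind.VALUE_LIST:
        return _decode_value_list(enc.payload, enc.bit_length, m)
    if enc.kind == EncodingKind.DELTA_LIST:
        return expand_delta_list(hex_decode_stream(enc.payload, enc.bit_length, m), m)
    if enc.kind == EncodingKind.BITMAP:
        if enc.bit_length != m:
            raise CodecError("bitmap bit length must equal m")
        return _decode_bitmap(enc.payload, m)
    raise CodecError(f"unknown encoding kind {enc.kind}")
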