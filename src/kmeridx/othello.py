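"""The Othello minimal-perfect-hashing classifier.

An Othello stores a many-to-one mapping T from a fixed key set S (here,
2-bit packed k-mers) to categories V = {1..v}.  It keeps two arrays A and B
of l-bit integers, l = ceil(log2(v+1)), indexed by a pair of seeded hash
functions, such that for every constructed key s

    A[h_a(s)] XOR B[h_b(s)] == T(s).

Querying any key — constructed or alien — costs two array reads and one XOR.
Array lengths are the powers of two m_a = 2^ceil(log2 n) and
m_b = 2^ceil(log2(4n/3)), so m_a + m_b stays below 4n and total storage is
at most 4n*l bits.

Construction models keys as edges of the bipartite graph on the array index
sets; when the graph is acyclic, values are assigned by traversal from
arbitrary roots, leaving every unvisited entry at 0.  A cyclic graph triggers
a reseed of the hash pair.  Keeping untouched entries at zero matters: it is
what pushes the alien-query mass onto value 0 and makes the asymptotic
rejection bound p_0 > e^-1.5 ≈ 0.223 hold.
"""

from __future__ import annotations

import logging
import struct
import zlib
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

_MAGIC = b"KOTH"
_VERSION = 1

_C1 = np.uint64(0x9E3779B97F4A7C15)
_C2 = np.uint64(0xBF58476D1CE4E5B9)
_C3 = np.uint64(0x94D049BB133111EB)


class OthelloBuildError(RuntimeError):
    """Raised when construction cannot find an acyclic hash pair."""


class OthelloFormatError(ValueError):
    """Raised on corrupt or incompatible serialized structures."""


def mix64(x: np.ndarray | int, seed: int) -> np.ndarray:
    """Seeded 64-bit finalizer-style mixer (splitmix64 family)."""
    z = np.asarray(x, dtype=np.uint64) ^ np.uint64(seed)
    z = z + _C1
    z = (z ^ (z >> np.uint64(30))) * _C2
    z = (z ^ (z >> np.uint64(27))) * _C3
    return z ^ (z >> np.uint64(31))


def _derive_seed_pair(seed: int, attempt: int) -> tuple[int, int]:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(attempt,))
    a, b = ss.generate_state(2, dtype=np.uint64)
    return int(a), int(b)


def _array_sizes(n: int) -> tuple[int, int]:
    m_a = 1 << int(np.ceil(np.log2(n))) if n > 1 else 1
    m_b = 1 << int(np.ceil(np.log2(4 * n / 3)))
    return m_a, m_b


def _try_assign(ia, ib, vals, m_a, m_b):
    """Assign array values along the acyclic bipartite key graph.

    Returns the node value list (A nodes then B nodes) or None if any cycle
    (including a repeated index pair) is found.
    """
    n = len(ia)
    n_nodes = m_a + m_b
    deg = [0] * n_nodes
    for u in ia:
        deg[u] += 1
    for w in ib:
        deg[w + m_a] += 1
    indptr = [0] * (n_nodes + 1)
    for i in range(n_nodes):
        indptr[i + 1] = indptr[i] + deg[i]
    pos = indptr[:-1].copy()
    eidx = [0] * (2 * n)
    for e in range(n):
        u = ia[e]
        eidx[pos[u]] = e
        pos[u] += 1
        w = ib[e] + m_a
        eidx[pos[w]] = e
        pos[w] += 1

    node_val = [0] * n_nodes
    visited = bytearray(n_nodes)
    edge_done = bytearray(n)
    for root in range(n_nodes):
        if visited[root] or deg[root] == 0:
            continue
        visited[root] = 1
        stack = [root]
        while stack:
            u = stack.pop()
            for p in range(indptr[u], indptr[u + 1]):
                e = eidx[p]
                if edge_done[e]:
                    continue
                edge_done[e] = 1
                a_node = ia[e]
                b_node = ib[e] + m_a
                w = b_node if u == a_node else a_node
                if visited[w]:
                    return None  # cycle
                node_val[w] = node_val[u] ^ vals[e]
                visited[w] = 1
                stack.append(w)
    return node_val


@dataclass
class Othello:
    """A constructed Othello map.  See the module docstring for semantics."""

    A: np.ndarray
    B: np.ndarray
    n: int
    v: int
    l: int
    m_a: int
    m_b: int
    hash_seed_pair: tuple[int, int]

    @classmethod
    def build(
        cls,
        keys: np.ndarray,
        values: np.ndarray,
        v: int | None = None,
        seed: int = 0,
        max_attempts: int = 100,
    ) -> "Othello":
        keys = np.ascontiguousarray(keys, dtype=np.uint64)
        values = np.asarray(values, dtype=np.int64)
        n = keys.size
        if n < 1:
            raise ValueError("need at least one key")
        if values.size != n:
            raise ValueError("keys and values differ in length")
        if v is None:
            v = int(values.max())
        if v < 1:
            raise ValueError("v must be >= 1")
        if values.min() < 1 or values.max() > v:
            bad = values[(values < 1) | (values > v)][0]
            raise ValueError(f"value {bad} outside 1..{v}")
        uniq, counts = np.unique(keys, return_counts=True)
        if uniq.size != n:
            dup = uniq[counts > 1][0]
            raise ValueError(f"duplicate key {int(dup):#x}")

        l = int(np.ceil(np.log2(v + 1)))
        m_a, m_b = _array_sizes(n)
        vals_list = values.astype(np.uint32).tolist()
        for attempt in range(max_attempts):
            sa, sb = _derive_seed_pair(seed, attempt)
            ia = (mix64(keys, sa) & np.uint64(m_a - 1)).tolist()
            ib = (mix64(keys, sb) & np.uint64(m_b - 1)).tolist()
            node_val = _try_assign(ia, ib, vals_list, m_a, m_b)
            if node_val is not None:
                if attempt:
                    log.info("othello: acyclic after %d reseed(s)", attempt)
                arr = np.asarray(node_val, dtype=np.uint32)
                return cls(arr[:m_a].copy(), arr[m_a:].copy(), n, v, l, m_a, m_b, (sa, sb))
        raise OthelloBuildError(
            f"no acyclic hash pair found for n={n} after {max_attempts} attempts"
        )

    # -- query ------------------------------------------------------------
    def query(self, keys: np.ndarray | int) -> np.ndarray | int:
        """tau(key) = A[h_a(key)] XOR B[h_b(key)], for any key, vectorized."""
        scalar = np.isscalar(keys)
        arr = np.atleast_1d(np.asarray(keys, dtype=np.uint64))
        sa, sb = self.hash_seed_pair
        ia = mix64(arr, sa) & np.uint64(self.m_a - 1)
        ib = mix64(arr, sb) & np.uint64(self.m_b - 1)
        out = self.A[ia] ^ self.B[ib]
        return int(out[0]) if scalar else out

    def hash_indices(self, keys: np.ndarray | int) -> tuple[np.ndarray, np.ndarray]:
        arr = np.atleast_1d(np.asarray(keys, dtype=np.uint64))
        sa, sb = self.hash_seed_pair
        return (
            mix64(arr, sa) & np.uint64(self.m_a - 1),
            mix64(arr, sb) & np.uint64(self.m_b - 1),
        )

    # -- alien-value analytics ---------------------------------------------
    def value_fractions(self) -> tuple[np.ndarray, np.ndarray]:
        """a_x, b_x: fraction of entries of A resp. B equal to each x in C."""
        size = 1 << self.l
        a = np.bincount(self.A, minlength=size) / self.m_a
        b = np.bincount(self.B, minlength=size) / self.m_b
        return a, b

    @property
    def storage_bits(self) -> int:
        """l-bit-packed accounting of A plus B."""
        return (self.m_a + self.m_b) * self.l

    # -- serialization -----------------------------------------------------
    def to_bytes(self) -> bytes:
        header = _MAGIC + struct.pack(
            "<HQQQQQQQ",
            _VERSION,
            self.n,
            self.v,
            self.l,
            self.m_a,
            self.m_b,
            self.hash_seed_pair[0],
            self.hash_seed_pair[1],
        )
        payload = _pack_lbit(self.A, self.l) + _pack_lbit(self.B, self.l)
        body = header + payload
        return body + struct.pack("<I", zlib.crc32(body))

    @classmethod
    def from_bytes(cls, data: bytes) -> "Othello":
        hdr_len = 4 + struct.calcsize("<HQQQQQQQ")
        if len(data) < hdr_len + 4:
            raise OthelloFormatError("truncated Othello stream")
        if data[:4] != _MAGIC:
            raise OthelloFormatError("bad magic bytes")
        (version, n, v, l, m_a, m_b, sa, sb) = struct.unpack(
            "<HQQQQQQQ", data[4:hdr_len]
        )
        if version != _VERSION:
            raise OthelloFormatError(f"unsupported version {version}")
        bytes_a = (m_a * l + 7) // 8
        bytes_b = (m_b * l + 7) // 8
        end = hdr_len + bytes_a + bytes_b
        if len(data) < end + 4:
            raise OthelloFormatError("truncated Othello stream")
        (crc,) = struct.unpack("<I", data[end : end + 4])
        if crc != zlib.crc32(data[:end]):
            raise OthelloFormatError("checksum mismatch")
        A = _unpack_lbit(data[hdr_len : hdr_len + bytes_a], m_a, l)
        B = _unpack_lbit(data[hdr_len + bytes_a : end], m_b, l)
        return cls(A, B, n, v, l, m_a, m_b, (sa, sb))


def _pack_lbit(arr: np.ndarray, l: int) -> bytes:
    bits = (arr[:, None] >> np.arange(l, dtype=np.uint32)) & 1
    return np.packbits(bits.astype(np.uint8).ravel(), bitorder="little").tobytes()


def _unpack_lbit(data: bytes, count: int, l: int) -> np.ndarray:
    bits = np.unpackbits(
        np.frombuffer(data, dtype=np.uint8), count=count * l, bitorder="little"
    ).reshape(count, l)
    return (bits.astype(np.uint32) << np.arange(l, dtype=np.uint32)).sum(
        axis=1, dtype=np.uint32
    )


@dataclass
class AlienProfile:
    """Distribution of tau over alien keys.

    ``p[x]`` is the probability that a uniformly random alien key returns x;
    it is the XOR convolution of the value fractions of A and B.  ``exact``
    is False when the flat large-l approximation replaced the convolution.
    """

    p: np.ndarray
    exact: bool

    @property
    def p0(self) -> float:
        return float(self.p[0])


EXACT_CONVOLUTION_MAX_L = 12  # full XOR convolution below this, flat approx at/above


def alien_value_distribution(o: Othello, force_exact: bool = False) -> AlienProfile:
    """Alien-query value distribution p_x = sum_t a_t * b_{x XOR t}.

    The exact convolution costs O(4^l) and is used for l < 12.  For larger l
    only p_0 = sum_t a_t b_t is computed exactly (O(2^l)); the remaining mass
    is spread evenly over the nonzero values, matching the flat approximation
    used by the index-level false-positive model.
    """
    a, b = o.value_fractions()
    size = 1 << o.l
    if force_exact or o.l < EXACT_CONVOLUTION_MAX_L:
        xs = np.arange(size)
        p = b[xs[:, None] ^ xs[None, :]] @ a
        return AlienProfile(p, exact=True)
    p0 = float(a @ b)
    p = np.full(size, (1.0 - p0) / (size - 1))
    p[0] = p0
    return AlienProfile(p, exact=False)


def alien_rejection_probability(o: Othello, profile: AlienProfile | None = None) -> float:
    """P_Alien = p_0 + sum_{x=v+1}^{2^l-1} p_x (probability an alien key maps
    outside the valid category set and is recognized as alien)."""
    if profile is None:
        profile = alien_value_distribution(o)
    p = profile.p
    return float(p[0] + p[o.v + 1 :].sum())


# Functional aliases matching the operation names used throughout the docs.
def build_othello(pairs_or_keys, values=None, **kwargs) -> Othello:
    """Build from an iterable of (key, value) pairs or parallel arrays."""
    if values is None:
        pairs = list(pairs_or_keys)
        keys = np.array([p[0] for p in pairs], dtype=np.uint64)
        values = np.array([p[1] for p in pairs], dtype=np.int64)
    else:
        keys = np.asarray(pairs_or_keys, dtype=np.uint64)
        values = np.asarray(values, dtype=np.int64)
    return Othello.build(keys, values, **kwargs)


def query_othello(o: Othello, key) -> int | np.ndarray:
    return o.query(key)


def serialize_othello(o: Othello) -> bytes:
    return o.to_bytes()


def deserialize_othello(data: bytes) -> Othello:
    return Othello.from_bytes(data)
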