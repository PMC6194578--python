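"""2-bit packed k-mer primitives.

A k-mer over ACGT is packed into a single ``uint64`` with the first base in
the most significant occupied 2-bit slot (A=0, C=1, G=2, T=3).  All indexing
and hashing operates on *canonical* k-mers: the lexicographic minimum of a
k-mer and its reverse complement, which collapses strand the same way
Jellyfish's canonical dumps do.  Odd k in 15..31 is supported; odd k rules
out self-reverse-complement palindromes.
"""

from __future__ import annotations

import gzip
import logging

import numpy as np

log = logging.getLogger(__name__)

MIN_K = 15
MAX_K = 31

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _BASE_CODE[_b] = _i

_CODE_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)

_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)


def check_k(k: int) -> int:
    if not (MIN_K <= k <= MAX_K) or k % 2 == 0:
        raise ValueError(f"k must be odd and in [{MIN_K}, {MAX_K}], got {k}")
    return k


def pack_kmers(codes: np.ndarray) -> np.ndarray:
    """Pack an (n, k) matrix of 2-bit base codes into uint64 keys."""
    k = codes.shape[1]
    out = np.zeros(codes.shape[0], dtype=np.uint64)
    for j in range(k):
        out = (out << np.uint64(2)) | codes[:, j].astype(np.uint64)
    return out


def unpack_kmers(keys: np.ndarray, k: int) -> np.ndarray:
    """Inverse of :func:`pack_kmers`: (n, k) matrix of base codes."""
    keys = np.asarray(keys, dtype=np.uint64)
    out = np.empty((keys.size, k), dtype=np.uint8)
    for j in range(k):
        shift = np.uint64(2 * (k - 1 - j))
        out[:, j] = ((keys >> shift) & np.uint64(3)).astype(np.uint8)
    return out


def revcomp_packed(keys: np.ndarray, k: int) -> np.ndarray:
    """Reverse complement of packed k-mers, fully vectorized.

    Complementing is a bitwise NOT on each 2-bit slot; reversal swaps 2-bit
    groups within bytes and then byte-swaps the word, after which the k
    occupied slots sit in the high bits and are shifted back down.
    """
    x = np.array(keys, dtype=np.uint64, copy=True)
    x = ~x
    x = ((x >> np.uint64(2)) & _M2) | ((x & _M2) << np.uint64(2))
    x = ((x >> np.uint64(4)) & _M4) | ((x & _M4) << np.uint64(4))
    x = x.byteswap()
    x >>= np.uint64(64 - 2 * k)
    return x


def canonicalize(keys: np.ndarray, k: int) -> np.ndarray:
    rc = revcomp_packed(keys, k)
    return np.minimum(np.asarray(keys, dtype=np.uint64), rc)


def encode_sequences(lines: np.ndarray, k: int) -> tuple[np.ndarray, int]:
    """Pack an (n, k) uint8 byte matrix of sequences; rows with non-ACGT
    characters are dropped.  Returns (packed keys, number skipped)."""
    codes = _BASE_CODE[lines]
    valid = ~(codes == 255).any(axis=1)
    n_skipped = int((~valid).sum())
    return pack_kmers(codes[valid]), n_skipped


def kmer_to_string(key: int, k: int) -> str:
    return bytes(_CODE_BASE[unpack_kmers(np.array([key], dtype=np.uint64), k)[0]]).decode()


def string_to_kmer(s: str, k: int | None = None) -> int:
    if k is None:
        k = len(s)
    if len(s) != k:
        raise ValueError(f"expected a {k}-mer, got length {len(s)}")
    codes = _BASE_CODE[np.frombuffer(s.upper().encode(), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError(f"non-ACGT character in k-mer {s!r}")
    return int(pack_kmers(codes[None, :])[0])


def kmers_to_bytes(keys: np.ndarray, k: int, jellyfish: bool = True) -> bytes:
    """Render packed k-mers as file content: Jellyfish-dump FASTA dialect
    (``>count`` then sequence) or plain one-per-line text."""
    codes = unpack_kmers(keys, k)
    chars = _CODE_BASE[codes]
    n = chars.shape[0]
    if jellyfish:
        out = np.empty((n, k + 4), dtype=np.uint8)
        out[:, 0] = ord(">")
        out[:, 1] = ord("1")
        out[:, 2] = ord("\n")
        out[:, 3:-1] = chars
        out[:, -1] = ord("\n")
    else:
        out = np.empty((n, k + 1), dtype=np.uint8)
        out[:, :-1] = chars
        out[:, -1] = ord("\n")
    return out.tobytes()


def _read_bytes(path) -> bytes:
    with open(path, "rb") as fh:
        head = fh.read(2)
        fh.seek(0)
        if head == b"\x1f\x8b":
            with gzip.open(fh) as gz:
                return gz.read()
        return fh.read()


def read_kmer_file(path, k: int) -> np.ndarray:
    """Read a k-mer file into sorted unique canonical packed k-mers.

    Auto-detects the Jellyfish FASTA dump dialect (">count" headers) versus
    plain one-k-mer-per-line text; gzip-compressed files are transparent.
    Counts are ignored (presence only).  Records of the wrong length or
    containing non-ACGT characters are skipped with a logged count.
    """
    check_k(k)
    raw = _read_bytes(path)
    lines = raw.split(b"\n")
    seqs = [ln.strip() for ln in lines if ln.strip() and not ln.startswith(b">")]
    n_total = len(seqs)
    good = [s for s in seqs if len(s) == k]
    n_skipped = n_total - len(good)
    if good:
        mat = np.frombuffer(b"".join(good), dtype=np.uint8).reshape(len(good), k)
        keys, bad = encode_sequences(mat, k)
        n_skipped += bad
    else:
        keys = np.empty(0, dtype=np.uint64)
    if n_skipped:
        log.warning("%s: skipped %d invalid record(s)", path, n_skipped)
    if keys.size == 0:
        raise ValueError(f"{path}: zero valid k-mers")
    return np.unique(canonicalize(keys, k))


def random_kmers(n: int, k: int, rng: np.random.Generator, canonical: bool = True) -> np.ndarray:
    """n distinct random packed k-mers (canonicalized unless disabled)."""
    out = np.empty(0, dtype=np.uint64)
    hi = 1 << (2 * k)
    while out.size < n:
        draw = rng.integers(0, hi, size=int(1.2 * (n - out.size)) + 16, dtype=np.uint64)
        if canonical:
            draw = canonicalize(draw, k)
        out = np.unique(np.concatenate([out, draw]))
    rng.shuffle(out)
    return np.sort(out[:n])
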