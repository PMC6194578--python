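"""Two-level k-mer occurrence index.

Construction follows a merge-sort strategy: per-experiment k-mer files are
combined into *groups* of about 50 experiments whose group-local occurrence
maps are kept (and persisted) delta-list encoded; groups are then merged into
full occurrence maps over all |E| experiments.  k-mers present in exactly one
experiment are encoded directly in the root Othello (value = experiment ID in
1..|E|); all others are compressed with the shortest-code codec and placed in
buckets by encoded bit length (value = |E| + bucket ID).  Each bucket holds
its own Othello mapping its k-mers to stored-map slots 1..v_b; identical
encoded maps share one slot.

Bucket length ranges are estimated from a seeded sample of encoded lengths:
starting at length 1, ranges are extended greedily while the estimated
payload sum_i i*L_i stays within the bucket capacity (128 MB by default,
interpreted as bytes of encoded payload).
"""

from __future__ import annotations

import gzip
import logging
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np

from . import codecs
from .codecs import EncodedOccurrence, EncodingKind, OccurrenceMap
from .kmers import check_k, read_kmer_file
from .othello import Othello

log = logging.getLogger(__name__)

DEFAULT_GROUP_SIZE = 50
DEFAULT_BUCKET_CAP = 128 << 20  # bytes of encoded payload per bucket
SAMPLE_MAX = 10_000_000
SAMPLE_MIN = 10_000
SAMPLE_FRACTION = 0.001

_GRP_MAGIC = b"KGRP"
_MAP_MAGIC = b"KMAP"
_VERSION = 1


class IndexFormatError(ValueError):
    pass


@dataclass
class ExperimentManifest:
    """Ordered experiment list; order defines experiment IDs 1..|E|."""

    entries: list[tuple[str, str]]  # (name, k-mer file path)
    k: int

    def __post_init__(self):
        check_k(self.k)
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("experiment names must be unique")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]

    @classmethod
    def from_tsv(cls, path, k: int) -> "ExperimentManifest":
        entries = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"manifest line needs name<TAB>path: {line!r}")
            entries.append((parts[0], parts[1]))
        return cls(entries, k)


# ---------------------------------------------------------------------------
# group files (construction step 1)
# ---------------------------------------------------------------------------

@dataclass
class GroupFile:
    """Sorted k-mers of <= group-size experiments with group-local maps."""

    member_names: list[str]
    k: int
    kmers: np.ndarray  # uint64, sorted unique
    occ: np.ndarray  # bool, shape (n_kmers, n_members)

    @property
    def n_members(self) -> int:
        return len(self.member_names)

    def save(self, path) -> None:
        """Persist with delta-list encoded rows (the on-disk group format)."""
        payloads = []
        bitlens = np.empty(self.kmers.size, dtype=np.uint16)
        for i in range(self.kmers.size):
            enc = codecs.hex_encode_delta_list(
                codecs.encode_delta_list(OccurrenceMap(self.occ[i]))
            )
            payloads.append(enc.payload)
            bitlens[i] = enc.bit_length
        names_blob = "\t".join(self.member_names).encode()
        blob = b"".join(payloads)
        body = (
            _GRP_MAGIC
            + struct.pack(
                "<HHHQQQ",
                _VERSION,
                self.k,
                self.n_members,
                self.kmers.size,
                len(names_blob),
                len(blob),
            )
            + names_blob
            + self.kmers.astype("<u8").tobytes()
            + bitlens.astype("<u2").tobytes()
            + blob
        )
        Path(path).write_bytes(body + struct.pack("<I", zlib.crc32(body)))

    @classmethod
    def load(cls, path) -> "GroupFile":
        data = Path(path).read_bytes()
        hdr = struct.calcsize("<HHHQQQ")
        if data[:4] != _GRP_MAGIC:
            raise IndexFormatError(f"{path}: bad group-file magic")
        version, k, n_members, n_kmers, names_len, blob_len = struct.unpack(
            "<HHHQQQ", data[4 : 4 + hdr]
        )
        if version != _VERSION:
            raise IndexFormatError(f"{path}: unsupported version {version}")
        if zlib.crc32(data[:-4]) != struct.unpack("<I", data[-4:])[0]:
            raise IndexFormatError(f"{path}: checksum mismatch")
        pos = 4 + hdr
        names = data[pos : pos + names_len].decode().split("\t") if names_len else []
        pos += names_len
        kmers = np.frombuffer(data[pos : pos + 8 * n_kmers], dtype="<u8").astype(np.uint64)
        pos += 8 * n_kmers
        bitlens = np.frombuffer(data[pos : pos + 2 * n_kmers], dtype="<u2")
        pos += 2 * n_kmers
        occ = np.zeros((n_kmers, n_members), dtype=bool)
        for i in range(n_kmers):
            nbytes = (int(bitlens[i]) + 7) // 8
            runs = codecs.hex_decode_stream(
                data[pos : pos + nbytes], int(bitlens[i]), n_members
            )
            occ[i] = codecs.expand_delta_list(runs, n_members).bits
            pos += nbytes
        return cls(names, k, kmers, occ)


def build_group_file(entries: list[tuple[str, str]], k: int) -> GroupFile:
    """Merge <= group-size sorted member k-mer lists into one group."""
    if not entries:
        raise ValueError("group needs at least one experiment")
    member_kmers = [read_kmer_file(path, k) for _, path in entries]
    union = np.unique(np.concatenate(member_kmers))
    occ = np.zeros((union.size, len(entries)), dtype=bool)
    for j, kk in enumerate(member_kmers):
        occ[np.searchsorted(union, kk), j] = True
    return GroupFile([n for n, _ in entries], k, union, occ)


def merge_group_files(groups: list[GroupFile]) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Merge groups into (experiment names, union k-mers, full occ matrix)."""
    if not groups:
        raise ValueError("no groups to merge")
    names: list[str] = []
    for g in groups:
        for n in g.member_names:
            if n in names:
                raise ValueError(f"experiment {n!r} appears in more than one group")
            names.append(n)
        if g.k != groups[0].k:
            raise ValueError("groups disagree on k")
    union = np.unique(np.concatenate([g.kmers for g in groups]))
    occ = np.zeros((union.size, len(names)), dtype=bool)
    col = 0
    for g in groups:
        rows = np.searchsorted(union, g.kmers)
        occ[rows, col : col + g.n_members] = g.occ
        col += g.n_members
    return names, union, occ


# ---------------------------------------------------------------------------
# bucket range estimation (construction step 2)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BucketSpec:
    bucket_id: int  # 1-based
    lo: int  # closed lower bound on encoded bit length
    hi: int | None  # open upper bound; None = unbounded


def sample_size(total: int) -> int:
    return min(total, min(SAMPLE_MAX, max(int(SAMPLE_FRACTION * total), SAMPLE_MIN)))


def estimate_bucket_ranges(
    sampled_lengths: np.ndarray,
    total: int,
    cap_bytes: int = DEFAULT_BUCKET_CAP,
) -> list[BucketSpec]:
    """Greedy maximal contiguous length ranges under the payload cap.

    L_i is the sampled count of maps with encoded bit length i scaled by the
    inverse sampling fraction; each bucket [n_t, n_{t+1}) is extended while
    sum_i i*L_i stays within the capacity (converted to bits).
    """
    sampled_lengths = np.asarray(sampled_lengths)
    if sampled_lengths.size == 0:
        raise ValueError("empty length sample")
    scale = total / sampled_lengths.size
    L = np.bincount(sampled_lengths) * scale
    cap_bits = cap_bytes * 8
    specs: list[BucketSpec] = []
    start, running = 1, 0.0
    for i in range(1, L.size):
        class_bits = i * L[i]
        # close the range only when a non-empty class would overflow it; a
        # single class larger than the cap gets a range of its own
        if class_bits > 0 and running + class_bits > cap_bits and i > start:
            specs.append(BucketSpec(len(specs) + 1, start, i))
            start, running = i, class_bits
        else:
            running += class_bits
    specs.append(BucketSpec(len(specs) + 1, start, None))
    return specs


def assign_to_buckets(
    kmers: np.ndarray,
    occ: np.ndarray,
    specs: list[BucketSpec] | None = None,
    cap_bytes: int = DEFAULT_BUCKET_CAP,
    seed: int = 0,
):
    """Split k-mers into the root-direct list (t = 1) and per-bucket lists.

    Returns (root_direct_kmers, root_direct_exp_ids, specs, buckets) where
    buckets is a list of (kmer array, list of EncodedOccurrence) per spec.
    """
    t = occ.sum(axis=1)
    if (t == 0).any():
        raise ValueError("all-absent k-mers cannot be indexed")
    single = t == 1
    root_kmers = kmers[single]
    root_exps = occ[single].argmax(axis=1) + 1

    multi_idx = np.flatnonzero(~single)
    encodings: list[EncodedOccurrence] = [
        codecs.choose_encoding(OccurrenceMap(occ[i])) for i in multi_idx
    ]
    lengths = np.array([e.bit_length for e in encodings], dtype=np.int64)

    if specs is None:
        if multi_idx.size:
            rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
            size = sample_size(multi_idx.size)
            pick = rng.choice(multi_idx.size, size=size, replace=False) if size < multi_idx.size else np.arange(multi_idx.size)
            specs = estimate_bucket_ranges(lengths[pick], multi_idx.size, cap_bytes)
        else:
            specs = []

    buckets: list[tuple[np.ndarray, list[EncodedOccurrence]]] = []
    if specs:
        bounds = np.array([s.lo for s in specs[1:]], dtype=np.int64)
        which = np.searchsorted(bounds, lengths, side="right")
        for b in range(len(specs)):
            sel = np.flatnonzero(which == b)
            buckets.append((kmers[multi_idx[sel]], [encodings[i] for i in sel]))
        for spec, (bk, bencs) in zip(specs, buckets):
            actual = sum(e.bit_length for e in bencs)
            if actual > cap_bytes * 8:
                log.warning(
                    "bucket %d payload %d bits exceeds the %d-byte cap estimate",
                    spec.bucket_id, actual, cap_bytes,
                )
    return root_kmers, root_exps, specs, buckets


# ---------------------------------------------------------------------------
# the index (construction step 3, persistence, query routing)
# ---------------------------------------------------------------------------

@dataclass
class Bucket:
    """One second-level bucket: an Othello over its k-mers plus stored maps."""

    bucket_id: int
    m: int  # number of experiments
    othello: Othello
    kinds: np.ndarray  # uint8 per slot
    bitlens: np.ndarray  # uint32 per slot
    offsets: np.ndarray  # uint64 byte offset per slot into blob
    blob: bytes
    _matrix: np.ndarray | None = field(default=None, repr=False)

    @property
    def v_b(self) -> int:
        return len(self.kinds)

    def decode_slot(self, slot: int) -> OccurrenceMap:
        """slot is 1-based, matching the bucket Othello's category set."""
        i = slot - 1
        start = int(self.offsets[i])
        end = start + (int(self.bitlens[i]) + 7) // 8
        enc = EncodedOccurrence(
            EncodingKind(int(self.kinds[i])), self.blob[start:end], int(self.bitlens[i])
        )
        return codecs.decode_occurrence(enc, self.m)

    def slot_matrix(self) -> np.ndarray:
        """(v_b, m) bool matrix of all stored maps (cached)."""
        if self._matrix is None:
            mat = np.zeros((self.v_b, self.m), dtype=bool)
            for i in range(self.v_b):
                mat[i] = self.decode_slot(i + 1).bits
            self._matrix = mat
        return self._matrix

    def maps_to_bytes(self) -> bytes:
        body = (
            _MAP_MAGIC
            + struct.pack("<HQQQ", _VERSION, self.v_b, self.m, len(self.blob))
            + self.kinds.astype(np.uint8).tobytes()
            + self.bitlens.astype("<u4").tobytes()
            + self.offsets.astype("<u8").tobytes()
            + self.blob
        )
        return body + struct.pack("<I", zlib.crc32(body))

    @staticmethod
    def maps_from_bytes(data: bytes, bucket_id: int, othello: Othello) -> "Bucket":
        if data[:4] != _MAP_MAGIC:
            raise IndexFormatError("bad bucket map magic")
        hdr = struct.calcsize("<HQQQ")
        version, v_b, m, blob_len = struct.unpack("<HQQQ", data[4 : 4 + hdr])
        if version != _VERSION:
            raise IndexFormatError(f"unsupported bucket map version {version}")
        if zlib.crc32(data[:-4]) != struct.unpack("<I", data[-4:])[0]:
            raise IndexFormatError("bucket map checksum mismatch")
        pos = 4 + hdr
        kinds = np.frombuffer(data[pos : pos + v_b], dtype=np.uint8).copy()
        pos += v_b
        bitlens = np.frombuffer(data[pos : pos + 4 * v_b], dtype="<u4").astype(np.uint32)
        pos += 4 * v_b
        offsets = np.frombuffer(data[pos : pos + 8 * v_b], dtype="<u8").astype(np.uint64)
        pos += 8 * v_b
        blob = data[pos : pos + blob_len]
        return Bucket(bucket_id, m, othello, kinds, bitlens, offsets, blob)


def _build_bucket(
    bucket_id: int,
    kmers: np.ndarray,
    encodings: list[EncodedOccurrence],
    m: int,
    seed: int,
) -> Bucket:
    """Deduplicate identical encoded maps into slots and build the Othello."""
    slot_of: dict[tuple, int] = {}
    kinds: list[int] = []
    bitlens: list[int] = []
    payloads: list[bytes] = []
    values = np.empty(kmers.size, dtype=np.int64)
    for i, enc in enumerate(encodings):
        key = (int(enc.kind), enc.bit_length, enc.payload)
        slot = slot_of.get(key)
        if slot is None:
            slot = len(kinds) + 1
            slot_of[key] = slot
            kinds.append(int(enc.kind))
            bitlens.append(enc.bit_length)
            payloads.append(enc.payload)
        values[i] = slot
    offsets = np.zeros(len(payloads), dtype=np.uint64)
    acc = 0
    for i, p in enumerate(payloads):
        offsets[i] = acc
        acc += len(p)
    oth = Othello.build(kmers, values, v=len(kinds), seed=seed)
    return Bucket(
        bucket_id,
        m,
        oth,
        np.array(kinds, dtype=np.uint8),
        np.array(bitlens, dtype=np.uint32),
        offsets,
        b"".join(payloads),
    )


def _derive_component_seed(seed: int, tag: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(100 + tag,))
    return int(ss.generate_state(1, dtype=np.uint64)[0])


@dataclass
class OccurrenceIndex:
    """Root Othello plus per-bucket Othellos and stored encoded maps."""

    experiment_names: list[str]
    k: int
    root: Othello
    buckets: list[Bucket]
    specs: list[BucketSpec]
    seed: int
    n_kmers: int
    groups: list[GroupFile] | None = None
    _lazy_dir: Path | None = field(default=None, repr=False)

    @property
    def n_experiments(self) -> int:
        return len(self.experiment_names)

    @property
    def n_buckets(self) -> int:
        return len(self.specs)

    def _bucket(self, b: int) -> Bucket:
        """1-based bucket accessor; loads lazily when opened without preload."""
        bk = self.buckets[b - 1]
        if bk is None:
            oth = Othello.from_bytes((self._lazy_dir / f"bucket_{b}.oth").read_bytes())
            data = gzip.decompress((self._lazy_dir / f"bucket_{b}.maps.gz").read_bytes())
            bk = Bucket.maps_from_bytes(data, b, oth)
            self.buckets[b - 1] = bk
        return bk

    # -- query routing ------------------------------------------------------
    def route(self, kmers: np.ndarray) -> np.ndarray:
        """Root Othello values for packed canonical k-mers."""
        return self.root.query(np.asarray(kmers, dtype=np.uint64))

    def query_kmers_dense(self, kmers: np.ndarray) -> np.ndarray:
        """(n, |E|) presence matrix for packed canonical k-mers.

        Root values in 1..|E| set a single experiment; values |E|+b route to
        bucket b whose Othello picks a stored map slot; anything else (0,
        beyond |E|+|B|, or an invalid slot) means absent everywhere.
        """
        kmers = np.atleast_1d(np.asarray(kmers, dtype=np.uint64))
        E = self.n_experiments
        out = np.zeros((kmers.size, E), dtype=bool)
        tau = np.asarray(self.route(kmers), dtype=np.int64)
        direct = (tau >= 1) & (tau <= E)
        out[np.flatnonzero(direct), tau[direct] - 1] = True
        for b in range(1, self.n_buckets + 1):
            sel = np.flatnonzero(tau == E + b)
            if sel.size == 0:
                continue
            bk = self._bucket(b)
            slots = np.asarray(bk.othello.query(kmers[sel]), dtype=np.int64)
            ok = (slots >= 1) & (slots <= bk.v_b)
            out[sel[ok]] = bk.slot_matrix()[slots[ok] - 1]
        return out

    def query_kmer(self, kmer: int):
        """Three-way outcome for one k-mer; see :mod:`kmeridx.query`."""
        from .query import KmerQueryResult  # local import to avoid a cycle

        tau = int(self.root.query(kmer))
        E = self.n_experiments
        if 1 <= tau <= E:
            bits = np.zeros(E, dtype=bool)
            bits[tau - 1] = True
            return KmerQueryResult("root", tau, OccurrenceMap(bits))
        if E < tau <= E + self.n_buckets:
            bk = self._bucket(tau - E)
            slot = int(bk.othello.query(kmer))
            if 1 <= slot <= bk.v_b:
                return KmerQueryResult("bucket", None, bk.decode_slot(slot))
        return KmerQueryResult("absent", None, None)

    # -- persistence ---------------------------------------------------------
    def save(self, directory, keep_groups: bool = False) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "root.oth").write_bytes(self.root.to_bytes())
        for b in range(1, self.n_buckets + 1):
            bk = self._bucket(b)
            (directory / f"bucket_{b}.oth").write_bytes(bk.othello.to_bytes())
            (directory / f"bucket_{b}.maps.gz").write_bytes(
                gzip.compress(bk.maps_to_bytes(), mtime=0)
            )
        root_el = ET.Element("kmeridx", version=str(_VERSION))
        ET.SubElement(
            root_el,
            "params",
            k=str(self.k),
            seed=str(self.seed),
            n_kmers=str(self.n_kmers),
            n_experiments=str(self.n_experiments),
            n_buckets=str(self.n_buckets),
        )
        exps = ET.SubElement(root_el, "experiments")
        for i, name in enumerate(self.experiment_names, start=1):
            ET.SubElement(exps, "experiment", id=str(i), name=name)
        specs_el = ET.SubElement(root_el, "buckets")
        for spec, bk in zip(self.specs, self.buckets):
            ET.SubElement(
                specs_el,
                "bucket",
                id=str(spec.bucket_id),
                lo=str(spec.lo),
                hi="" if spec.hi is None else str(spec.hi),
                v_b=str(self._bucket(spec.bucket_id).v_b),
            )
        ET.indent(root_el)
        ET.ElementTree(root_el).write(directory / "meta.xml", encoding="utf-8")
        if keep_groups:
            if self.groups is None:
                raise ValueError("no group files retained on this index")
            gdir = directory / "groups"
            gdir.mkdir(exist_ok=True)
            for i, g in enumerate(self.groups, start=1):
                g.save(gdir / f"group_{i}.grp")

    @classmethod
    def load(cls, directory, preload: bool = True) -> "OccurrenceIndex":
        directory = Path(directory)
        meta_path = directory / "meta.xml"
        if not meta_path.exists():
            raise IndexFormatError(f"{directory}: missing meta.xml")
        tree = ET.parse(meta_path)
        root_el = tree.getroot()
        if root_el.get("version") != str(_VERSION):
            raise IndexFormatError("unsupported index version")
        params = root_el.find("params")
        k = int(params.get("k"))
        seed = int(params.get("seed"))
        n_kmers = int(params.get("n_kmers"))
        names = [e.get("name") for e in root_el.find("experiments")]
        specs = [
            BucketSpec(int(e.get("id")), int(e.get("lo")), int(e.get("hi")) if e.get("hi") else None)
            for e in root_el.find("buckets")
        ]
        root = Othello.from_bytes((directory / "root.oth").read_bytes())
        idx = cls(names, k, root, [None] * len(specs), specs, seed, n_kmers,
                  _lazy_dir=directory)
        if preload:
            for b in range(1, len(specs) + 1):
                idx._bucket(b)
        gdir = directory / "groups"
        if gdir.is_dir():
            idx.groups = [GroupFile.load(p) for p in sorted(gdir.glob("group_*.grp"),
                                                            key=lambda p: int(p.stem.split("_")[1]))]
        return idx

    def info(self) -> dict:
        return {
            "k": self.k,
            "n_experiments": self.n_experiments,
            "n_buckets": self.n_buckets,
            "n_kmers": self.n_kmers,
            "experiments": list(self.experiment_names),
            "bucket_slots": [self._bucket(b).v_b for b in range(1, self.n_buckets + 1)],
        }


def build_index_from_groups(
    groups: list[GroupFile],
    *,
    cap_bytes: int = DEFAULT_BUCKET_CAP,
    seed: int = 0,
    keep_groups: bool = False,
) -> OccurrenceIndex:
    names, union, occ = merge_group_files(groups)
    k = groups[0].k
    E = len(names)
    root_kmers, root_exps, specs, bucket_inputs = assign_to_buckets(
        union, occ, cap_bytes=cap_bytes, seed=seed
    )
    # drop trailing empty buckets only if *no* k-mer was bucketed at all
    buckets = [
        _build_bucket(i + 1, bk, bencs, E, _derive_component_seed(seed, i + 1))
        for i, (bk, bencs) in enumerate(bucket_inputs)
        if bk.size
    ]
    if len(buckets) != len(bucket_inputs):
        # re-number contiguously; empty length ranges can arise from sampling
        specs = [
            BucketSpec(j + 1, specs[b.bucket_id - 1].lo, specs[b.bucket_id - 1].hi)
            for j, b in enumerate(buckets)
        ]
        for j, b in enumerate(buckets):
            b.bucket_id = j + 1
    all_keys = np.concatenate([root_kmers] + [b_kmers for b_kmers, _ in bucket_inputs if b_kmers.size])
    all_vals = np.concatenate(
        [root_exps]
        + [
            np.full(bk.othello.n, E + bk.bucket_id, dtype=np.int64)
            for bk in buckets
        ]
    )
    root = Othello.build(
        all_keys, all_vals, v=E + len(buckets), seed=_derive_component_seed(seed, 0)
    )
    log.info(
        "index built: |E|=%d, |B|=%d, %d k-mers (%d root-direct)",
        E, len(buckets), union.size, root_kmers.size,
    )
    return OccurrenceIndex(
        names, k, root, buckets, specs, seed, union.size,
        groups=groups if keep_groups else None,
    )


def build_index(
    manifest: ExperimentManifest,
    *,
    group_size: int = DEFAULT_GROUP_SIZE,
    cap_bytes: int = DEFAULT_BUCKET_CAP,
    seed: int = 0,
    keep_groups: bool = False,
) -> OccurrenceIndex:
    """Full pipeline: group merge, bucket assignment, Othello construction."""
    if group_size < 1:
        raise ValueError("group size must be >= 1")
    groups = [
        build_group_file(manifest.entries[i : i + group_size], manifest.k)
        for i in range(0, len(manifest.entries), group_size)
    ]
    return build_index_from_groups(
        groups, cap_bytes=cap_bytes, seed=seed, keep_groups=keep_groups
    )


def insert_experiments(
    groups: list[GroupFile],
    new_entries: list[tuple[str, str]],
    *,
    group_size: int = DEFAULT_GROUP_SIZE,
    cap_bytes: int = DEFAULT_BUCKET_CAP,
    seed: int = 0,
    keep_groups: bool = True,
) -> OccurrenceIndex:
    """Append new experiments as fresh groups and rebuild levels 2 and 3.

    New experiments receive IDs |E|+1.. in entry order; the result answers
    every query identically to a from-scratch build on the union.
    """
    k = groups[0].k
    existing = {n for g in groups for n in g.member_names}
    for name, _ in new_entries:
        if name in existing:
            raise ValueError(f"experiment {name!r} already indexed")
    new_groups = [
        build_group_file(new_entries[i : i + group_size], k)
        for i in range(0, len(new_entries), group_size)
    ]
    return build_index_from_groups(
        groups + new_groups, cap_bytes=cap_bytes, seed=seed, keep_groups=keep_groups
    )


def save_index(index: OccurrenceIndex, directory, keep_groups: bool = False) -> None:
    index.save(directory, keep_groups=keep_groups)


def load_index(directory, preload: bool = True) -> OccurrenceIndex:
    return OccurrenceIndex.load(directory, preload=preload)
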