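"""Sequence queries: decomposition into canonical k-mers and hit reporting.

A query sequence of length L yields L-k+1 windows.  Windows containing
non-ACGT characters are marked invalid, excluded from the k-mer total w, and
reported as gaps in hit maps.  Per experiment, the hit count is the number of
valid query k-mers present, and the hit ratio is hits/w.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from concurrent.futures import ThreadPoolExecutor

import numpy as np
from Bio import SeqIO

from .codecs import OccurrenceMap
from .index import OccurrenceIndex
from .kmers import canonicalize, _BASE_CODE

log = logging.getLogger(__name__)

TSV_COLUMNS = ("query", "experiment", "hits", "total_kmers", "ratio")


@dataclass
class KmerQueryResult:
    """Outcome of one k-mer lookup: routed via the root ('root'), via a
    bucket ('bucket'), or recognized as absent ('absent')."""

    route: str
    experiment: int | None  # 1-based, for root-direct hits
    occurrence: OccurrenceMap | None

    @property
    def present(self) -> bool:
        return self.route != "absent"


@dataclass
class SequenceQueryResult:
    name: str
    w: int  # count of valid k-mer windows
    hits: np.ndarray  # int, per experiment
    ratios: np.ndarray | None  # hits/w; None when w == 0
    hit_maps: np.ndarray | None = None  # bool (w_total, E) incl. invalid rows
    valid: np.ndarray | None = None  # bool per window position

    @property
    def available(self) -> bool:
        return self.w > 0


def decompose_sequence(seq: str, k: int) -> list[tuple[int, int | None]]:
    """(1-based window start, canonical packed k-mer or None) per window.

    Windows overlapping any non-ACGT character are marked None (invalid).
    """
    codes = _BASE_CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
    n = codes.size - k + 1
    if n < 1:
        log.warning("query shorter than k=%d: %d bases", k, codes.size)
        return []
    bad = codes == 255
    # window i (0-based) is invalid if any of codes[i:i+k] is bad
    invalid = np.convolve(bad.astype(np.int32), np.ones(k, dtype=np.int32))[k - 1 : k - 1 + n] > 0
    fwd = np.zeros(n, dtype=np.uint64)
    codes64 = np.where(bad, 0, codes).astype(np.uint64)
    acc = np.uint64(0)
    mask = np.uint64((1 << (2 * k)) - 1)
    out_fwd = np.empty(n + k - 1, dtype=np.uint64)
    for i in range(codes.size):
        acc = ((acc << np.uint64(2)) | codes64[i]) & mask
        out_fwd[i] = acc
    fwd = out_fwd[k - 1 :]
    canon = canonicalize(fwd, k)
    return [
        (i + 1, None if invalid[i] else int(canon[i]))
        for i in range(n)
    ]


def _valid_kmers(windows) -> tuple[np.ndarray, np.ndarray]:
    valid = np.array([km is not None for _, km in windows], dtype=bool)
    kmers = np.array([km for _, km in windows if km is not None], dtype=np.uint64)
    return valid, kmers


def query_kmer(index: OccurrenceIndex, kmer: int) -> KmerQueryResult:
    return index.query_kmer(kmer)


def query_sequence(
    index: OccurrenceIndex,
    seq: str,
    name: str = "query",
    emit_hit_maps: bool = False,
) -> SequenceQueryResult:
    windows = decompose_sequence(seq, index.k)
    valid, kmers = _valid_kmers(windows)
    w = int(valid.sum())
    E = index.n_experiments
    if w == 0:
        return SequenceQueryResult(name, 0, np.zeros(E, dtype=np.int64), None,
                                   valid=valid)
    dense = index.query_kmers_dense(kmers)  # (w, E)
    hits = dense.sum(axis=0).astype(np.int64)
    ratios = hits / w
    hit_maps = None
    if emit_hit_maps:
        hit_maps = np.zeros((valid.size, E), dtype=bool)
        hit_maps[valid] = dense
    return SequenceQueryResult(name, w, hits, ratios, hit_maps, valid)


def hit_map_strings(result: SequenceQueryResult) -> list[str]:
    """Per-experiment hit maps as 0/1/· strings in query coordinates."""
    if result.hit_maps is None:
        raise ValueError("query was run without emit_hit_maps")
    rows = []
    for e in range(result.hit_maps.shape[1]):
        rows.append(
            "".join(
                "·" if not result.valid[i] else ("1" if result.hit_maps[i, e] else "0")
                for i in range(result.valid.size)
            )
        )
    return rows


def batch_query(
    index: OccurrenceIndex,
    fasta_path,
    emit_hit_maps: bool = False,
    workers: int = 1,
):
    """Query every FASTA record, preserving record order.

    Yields SequenceQueryResult objects; multi-worker execution produces
    output identical to serial execution.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        log.warning("%s: empty FASTA", fasta_path)
        return

    def run(rec):
        return query_sequence(index, str(rec.seq), rec.id, emit_hit_maps)

    if workers <= 1:
        for rec in records:
            yield run(rec)
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            yield from pool.map(run, records)


def write_tsv(results, index: OccurrenceIndex, out_fh) -> int:
    """TSV rows (query, experiment, hits, total_kmers, ratio); returns count."""
    out_fh.write("\t".join(TSV_COLUMNS) + "\n")
    n = 0
    for res in results:
        for e, name in enumerate(index.experiment_names):
            ratio = f"{res.ratios[e]:.6g}" if res.available else "NA"
            out_fh.write(
                f"{res.name}\t{name}\t{int(res.hits[e])}\t{res.w}\t{ratio}\n"
            )
            n += 1
    return n
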