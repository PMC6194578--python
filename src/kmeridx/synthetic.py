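"""Synthetic cohorts with known ground truth.

Real RNA-seq collections show U- or L-shaped k-mer occurrence-frequency
histograms: a large mass of experiment-private k-mers (frequency 1), a spike
of housekeeping-like k-mers present in essentially every experiment, and a
spread of tissue-specific k-mers in between.  The generator emulates exactly
that structure — and nothing else about real data (no sequencing errors, no
abundance structure, no shared isoforms) — from three ingredients:

* core transcripts included in every experiment (frequency |E| k-mers);
* variable transcripts, each included per experiment with its own Bernoulli
  probability drawn from a fixed range (mid-frequency k-mers);
* per-experiment private random k-mers (frequency 1).

The fusion cohort generator spikes junction k-mers into a small (<2%) set of
samples and optionally injects a subset of junction k-mers into ~99% of
samples to mimic repetitive-sequence background, emitting the truth call set.
Everything is deterministic under the seed, and the emitted truth matrix is
exact by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fusion import FusionQuery
from .index import ExperimentManifest
from .kmers import canonicalize, check_k, kmers_to_bytes, pack_kmers, random_kmers

log = logging.getLogger(__name__)


@dataclass
class CohortSpec:
    """Defaults target ~5e5 distinct k-mers over 100 experiments with >=30%
    of k-mers at frequency 1 and >=10% at frequency |E|."""

    n_experiments: int = 100
    k: int = 21
    n_core_transcripts: int = 120
    n_variable_transcripts: int = 260
    transcript_length: tuple[int, int] = (100, 1000)
    variable_inclusion: tuple[float, float] = (0.02, 0.5)
    private_kmers_per_experiment: int = 3000
    seed: int = 0

    def __post_init__(self):
        check_k(self.k)
        if self.n_experiments < 1:
            raise ValueError("need at least one experiment")
        if self.n_core_transcripts + self.n_variable_transcripts < 1 and not self.private_kmers_per_experiment:
            raise ValueError("empty sequence pool and no private k-mers")


@dataclass
class SyntheticCohort:
    manifest: ExperimentManifest
    kmers: np.ndarray  # sorted unique canonical k-mers with t >= 1
    truth: np.ndarray  # bool (n_kmers, n_experiments)

    def occurrence_histogram(self) -> np.ndarray:
        """counts[t] = number of k-mers present in exactly t experiments."""
        return np.bincount(self.truth.sum(axis=1), minlength=self.truth.shape[1] + 1)


def _random_transcript_kmers(rng: np.random.Generator, length: int, k: int) -> np.ndarray:
    codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    n = length - k + 1
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)[:n]
    return np.unique(canonicalize(pack_kmers(windows), k))


def simulate_experiments(spec: CohortSpec, out_dir) -> SyntheticCohort:
    """Write one Jellyfish-dialect k-mer file per experiment plus a manifest
    TSV; returns the exact truth occurrence matrix."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(0,)))
    E, k = spec.n_experiments, spec.k
    lo, hi = spec.transcript_length
    if lo < k:
        raise ValueError(f"transcripts must be at least k={k} bases")

    sources: list[tuple[np.ndarray, np.ndarray]] = []  # (kmers, membership)
    all_members = np.ones(E, dtype=bool)
    for _ in range(spec.n_core_transcripts):
        km = _random_transcript_kmers(rng, int(rng.integers(lo, hi + 1)), k)
        sources.append((km, all_members))
    qlo, qhi = spec.variable_inclusion
    for _ in range(spec.n_variable_transcripts):
        km = _random_transcript_kmers(rng, int(rng.integers(lo, hi + 1)), k)
        q = rng.uniform(qlo, qhi)
        sources.append((km, rng.random(E) < q))

    transcript_union = (
        np.unique(np.concatenate([km for km, _ in sources]))
        if sources
        else np.empty(0, dtype=np.uint64)
    )
    n_private = spec.private_kmers_per_experiment * E
    private = np.empty(0, dtype=np.uint64)
    if n_private:
        private = random_kmers(int(1.05 * n_private) + 16, k, rng)
        pos = np.searchsorted(transcript_union, private)
        pos = np.minimum(pos, max(transcript_union.size - 1, 0))
        if transcript_union.size:
            private = private[transcript_union[pos] != private]
        if private.size < n_private:
            raise ValueError("private k-mer pool exhausted; lower the private rate")
        rng.shuffle(private)
        private = private[:n_private]

    union = np.unique(np.concatenate([transcript_union, private]))
    truth = np.zeros((union.size, E), dtype=bool)
    for km, members in sources:
        truth[np.searchsorted(union, km)] |= members
    for e in range(E):
        chunk = private[e * spec.private_kmers_per_experiment : (e + 1) * spec.private_kmers_per_experiment]
        truth[np.searchsorted(union, chunk), e] = True

    present = truth.any(axis=1)
    union, truth = union[present], truth[present]

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for e in range(E):
        name = f"exp{e + 1:04d}"
        path = out_dir / f"{name}.kmers.fa"
        path.write_bytes(kmers_to_bytes(union[truth[:, e]], k))
        entries.append((name, str(path)))
    manifest = ExperimentManifest(entries, k)
    (out_dir / "manifest.tsv").write_text(
        "".join(f"{n}\t{p}\n" for n, p in entries)
    )
    log.info(
        "cohort: %d experiments, %d distinct k-mers (%.0f%% frequency-1, %.0f%% frequency-|E|)",
        E, union.size,
        100 * (truth.sum(axis=1) == 1).mean(),
        100 * (truth.sum(axis=1) == E).mean(),
    )
    return SyntheticCohort(manifest, union, truth)


# ---------------------------------------------------------------------------
# fusion cohorts
# ---------------------------------------------------------------------------

@dataclass
class FusionCohortSpec:
    """Cohort of samples with spiked fusion junctions over a repetitive
    background.  ``background_kmers`` gives, per junction, how many of its
    k-1 junction-spanning k-mers are injected into ``background_fraction`` of
    all samples (0 = clean junction, Fig-4a-like; larger values emulate the
    repetitive high-background case)."""

    n_samples: int = 2000
    n_spiked: int = 10
    k: int = 21
    background_kmers: tuple[int, ...] = (0, 6, 11)
    background_fraction: float = 0.99
    filler_kmers_per_sample: int = 100
    mu: int = 7
    seed: int = 0

    def __post_init__(self):
        check_k(self.k)
        if self.n_spiked / self.n_samples >= 0.02:
            raise ValueError("spiked fraction must stay below 2% of samples")
        w = self.k - 1  # junction k-mers per query
        for bg in self.background_kmers:
            if not 0 <= bg <= w:
                raise ValueError(f"background k-mer count {bg} outside 0..{w}")
            if w - (bg + self.mu) < 1:
                raise ValueError(
                    f"spike margin {w - bg - self.mu} < 1: spiked samples could "
                    f"not exceed delta + mu"
                )


@dataclass
class FusionCohort:
    manifest: ExperimentManifest
    junctions: list[FusionQuery]
    junction_kmers: dict[str, np.ndarray]
    truth: dict[str, np.ndarray] = field(default_factory=dict)  # spiked sample indices
    background: dict[str, np.ndarray] = field(default_factory=dict)  # bg sample indices

    def junction_table(self, path) -> None:
        Path(path).write_text(
            "".join(f"{j.fusion_id}\t{j.donor_side}\t{j.acceptor_side}\n" for j in self.junctions)
        )


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=n)]).decode()


def spike_fusion_cohort(spec: FusionCohortSpec, out_dir) -> FusionCohort:
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(1,)))
    k = spec.k
    side = k - 1
    n = spec.n_samples

    junctions: list[FusionQuery] = []
    jkmers: dict[str, np.ndarray] = {}
    for j, bg in enumerate(spec.background_kmers):
        while True:
            fq = FusionQuery(f"fusion{j + 1:02d}", _random_bases(rng, side), _random_bases(rng, side), k)
            seq = np.frombuffer(fq.junction.encode(), dtype=np.uint8)
            codes = np.zeros(seq.size, dtype=np.uint8)
            for code, base in enumerate(b"ACGT"):
                codes[seq == base] = code
            windows = np.lib.stride_tricks.sliding_window_view(codes, k)
            km = canonicalize(pack_kmers(windows), k)
            if np.unique(km).size == km.size:  # keep per-junction k-mers distinct
                break
        junctions.append(fq)
        jkmers[fq.fusion_id] = km

    all_junction = np.unique(np.concatenate(list(jkmers.values())))
    filler_pool = random_kmers(spec.filler_kmers_per_sample * n + 64, k, rng)
    pos = np.minimum(np.searchsorted(all_junction, filler_pool), all_junction.size - 1)
    filler_pool = filler_pool[all_junction[pos] != filler_pool][: spec.filler_kmers_per_sample * n]
    rng.shuffle(filler_pool)

    truth: dict[str, np.ndarray] = {}
    bg_sets: dict[str, np.ndarray] = {}
    extra: list[list[np.ndarray]] = [[] for _ in range(n)]
    for fq, bg_count in zip(junctions, spec.background_kmers):
        spiked = np.sort(rng.choice(n, size=spec.n_spiked, replace=False))
        truth[fq.fusion_id] = spiked
        bg_samples = np.sort(
            rng.choice(n, size=int(spec.background_fraction * n), replace=False)
        )
        bg_sets[fq.fusion_id] = bg_samples
        km = jkmers[fq.fusion_id]
        for s in bg_samples:
            if bg_count:
                extra[s].append(km[:bg_count])
        for s in spiked:
            extra[s].append(km)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    fps = spec.filler_kmers_per_sample
    for s in range(n):
        name = f"sample{s + 1:05d}"
        km = np.unique(
            np.concatenate([filler_pool[s * fps : (s + 1) * fps]] + extra[s])
        )
        path = out_dir / f"{name}.kmers.fa"
        path.write_bytes(kmers_to_bytes(km, k))
        entries.append((name, str(path)))
    manifest = ExperimentManifest(entries, k)
    (out_dir / "manifest.tsv").write_text("".join(f"{nm}\t{p}\n" for nm, p in entries))
    cohort = FusionCohort(manifest, junctions, jkmers, truth, bg_sets)
    cohort.junction_table(out_dir / "junctions.tsv")
    return cohort
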