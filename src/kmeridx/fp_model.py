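"""Analytic false-positive model for alien k-mer queries.

For a fixed built structure, a uniformly random alien k-mer hashes uniformly
into both arrays of each Othello, so the distribution of returned values is
the XOR convolution of the array value fractions (the AlienProfile).  Routing
an alien key through the two-level index therefore has computable outcome
probabilities:

* recognized as alien at the root: root_P_Alien;
* falsely reported in experiment e directly: root_p_e;
* routed into bucket b (probability root_p_{|E|+b}) where it is either
  recognized (bucket P_Alien) or lands on stored map slot x, falsely claiming
  presence in every experiment that map marks.

Per experiment, bucket false positives accumulate as
    bP(e) = sum_{x in V_b} bp_x * W_{x,e},
computed by the exact convolution when the bucket's l < 12 and otherwise with
the flat approximation  bP(e) ~= (1 - bp_0)/(2^l - 1) * sum_x W_{x,e}.

The whole-index quantities are
    P(e)    = root_p_e + sum_b root_p_{|E|+b} * bP(e)
    P_Alien = root_P_Alien + sum_b root_p_{|E|+b} * bucket_P_Alien.

Over w alien k-mers the false-hit count for experiment e is
Binomial(w, P(e)); ``sequence_error_tail`` evaluates its upper tail exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .index import Bucket, OccurrenceIndex
from .kmers import canonicalize
from .othello import (
    EXACT_CONVOLUTION_MAX_L,
    AlienProfile,
    alien_rejection_probability,
    alien_value_distribution,
)


@dataclass
class FalsePositiveReport:
    per_experiment: np.ndarray  # P(e), length |E|
    alien_recognition: float  # P_Alien for the whole index
    root_profile: AlienProfile
    root_alien: float  # root P_Alien
    bucket_alien: np.ndarray  # bucket P_Alien per bucket
    bucket_per_experiment: np.ndarray  # bP(e), shape (|B|, |E|)
    bucket_marginals: np.ndarray  # sum_x W_{x,e}, shape (|B|, |E|)


def bucket_marginals(bucket: Bucket) -> np.ndarray:
    """Number of stored maps in the bucket marking each experiment present."""
    return bucket.slot_matrix().sum(axis=0).astype(np.int64)


def bucket_false_positive(
    bucket: Bucket, e: int | None = None, force_exact: bool = False
) -> np.ndarray | float:
    """bP(e) for one experiment (1-based) or the whole vector.

    Exact XOR-convolution below l = 12; the flat average
    (1-p0)/(2^l-1) above, where the O(4^l) convolution is impractical.
    """
    l = bucket.othello.l
    if force_exact or l < EXACT_CONVOLUTION_MAX_L:
        profile = alien_value_distribution(bucket.othello, force_exact=True)
        p_slots = profile.p[1 : bucket.v_b + 1]
        vec = p_slots @ bucket.slot_matrix()
    else:
        profile = alien_value_distribution(bucket.othello)
        p_bar = (1.0 - profile.p0) / ((1 << l) - 1)
        vec = p_bar * bucket_marginals(bucket)
    return vec if e is None else float(vec[e - 1])


def false_positive_report(index: OccurrenceIndex, force_exact: bool = False) -> FalsePositiveReport:
    E = index.n_experiments
    nB = index.n_buckets
    root_profile = alien_value_distribution(index.root, force_exact=force_exact)
    root_alien = alien_rejection_probability(index.root, root_profile)
    per_exp = root_profile.p[1 : E + 1].copy()
    b_alien = np.zeros(nB)
    b_per_exp = np.zeros((nB, E))
    b_marg = np.zeros((nB, E), dtype=np.int64)
    alien = root_alien
    for b in range(1, nB + 1):
        bk = index._bucket(b)
        p_route = float(root_profile.p[E + b])
        b_per_exp[b - 1] = bucket_false_positive(bk, force_exact=force_exact)
        b_marg[b - 1] = bucket_marginals(bk)
        bprof = alien_value_distribution(bk.othello, force_exact=force_exact)
        b_alien[b - 1] = alien_rejection_probability(bk.othello, bprof)
        per_exp += p_route * b_per_exp[b - 1]
        alien += p_route * b_alien[b - 1]
    return FalsePositiveReport(
        per_exp, float(alien), root_profile, root_alien, b_alien, b_per_exp, b_marg
    )


def index_false_positive(index: OccurrenceIndex, e: int | None = None):
    """Whole-index P(e): probability an alien k-mer is falsely reported
    present in experiment e (vector over all e when e is None)."""
    rep = false_positive_report(index)
    return rep.per_experiment if e is None else float(rep.per_experiment[e - 1])


def index_alien_recognition(index: OccurrenceIndex) -> float:
    return false_positive_report(index).alien_recognition


def sequence_error_tail(w: int, p: float, c: int) -> float:
    """P[X > c] for X ~ Binomial(w, p), by direct log-space summation."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be a probability")
    if w < 1 or c < 0:
        raise ValueError("need w >= 1 and c >= 0")
    if c >= w:
        return 0.0
    if p == 0.0:
        return 0.0
    if p == 1.0:
        return 1.0
    log_p = math.log(p)
    log_q = math.log1p(-p)
    lgw = math.lgamma(w + 1)
    terms = [
        math.exp(
            lgw - math.lgamma(x + 1) - math.lgamma(w - x + 1) + x * log_p + (w - x) * log_q
        )
        for x in range(c + 1, w + 1)
    ]
    return min(1.0, math.fsum(terms))


# ---------------------------------------------------------------------------
# empirical measurement (the Monte-Carlo counterpart of the model)
# ---------------------------------------------------------------------------

def sample_alien_kmers(
    index_kmers: np.ndarray, k: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n random canonical k-mers not present in the (sorted) indexed set."""
    out = []
    have = 0
    hi = 1 << (2 * k)
    while have < n:
        draw = canonicalize(
            rng.integers(0, hi, size=int(1.1 * (n - have)) + 16, dtype=np.uint64), k
        )
        pos = np.searchsorted(index_kmers, draw)
        pos = np.minimum(pos, index_kmers.size - 1)
        alien = draw[index_kmers[pos] != draw]
        out.append(alien[: n - have])
        have += out[-1].size
    return np.concatenate(out)


def empirical_alien_rates(
    index: OccurrenceIndex, probes: np.ndarray
) -> tuple[np.ndarray, float]:
    """(per-experiment false-positive fraction, alien-recognition fraction)
    over the given alien probes."""
    n = probes.size
    E = index.n_experiments
    tau = np.asarray(index.route(probes), dtype=np.int64)
    counts = np.bincount(tau[(tau >= 1) & (tau <= E)], minlength=E + 1)[1:].astype(np.float64)
    recognized = int(((tau < 1) | (tau > E + index.n_buckets)).sum())
    for b in range(1, index.n_buckets + 1):
        sel = tau == E + b
        if not sel.any():
            continue
        bk = index._bucket(b)
        slots = np.asarray(bk.othello.query(probes[sel]), dtype=np.int64)
        ok = (slots >= 1) & (slots <= bk.v_b)
        recognized += int((~ok).sum())
        slot_counts = np.bincount(slots[ok], minlength=bk.v_b + 1)[1:]
        counts += slot_counts @ bk.slot_matrix()
    return counts / n, recognized / n
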