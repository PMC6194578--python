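# Methods

## The Othello classifier

Both levels of the index rest on the same primitive: a minimal-perfect-hashing
*classifier* that stores a many-to-one map T from n fixed keys to categories
{1..v} in two arrays A, B of l-bit integers, l = ⌈log₂(v+1)⌉, with

    τ(s) = A[h_a(s)] ⊕ B[h_b(s)].

Keys are 2-bit-packed canonical k-mers (the lexicographic minimum of a k-mer
and its reverse complement, matching Jellyfish's canonical dumps), hashed by
a seeded splitmix64-style 64-bit mixer; the two indices come from two
independently seeded mixes masked to the power-of-two array lengths
m_a = 2^⌈log₂n⌉ and m_b = 2^⌈log₂(4n/3)⌉. These sizes keep
2.67n ≤ m_a + m_b < 4n (equality ~8n/3 when 4n/3 is itself a power of two),
hence total storage ≤ 4n·l bits.

Construction treats each key as an edge between node h_a(s) on the A side and
h_b(s) on the B side. If the bipartite graph is acyclic, values are assigned
by depth-first traversal: each component root keeps value 0 and each edge
fixes its far endpoint so the XOR equals T(s). A cycle — including a repeated
index pair — triggers a reseed of the hash pair; at these array sizes the
acyclicity probability per attempt is a constant well above 1/3, so the
expected number of reseeds is small (the count is logged; construction fails
loudly after 100 attempts). Two invariants matter downstream:

* unassigned entries stay 0 (never randomized), which concentrates the alien
  query mass on value 0;
* a fixed seed yields a byte-identical structure, which is what makes whole
  index builds reproducible.

Serialization is a fixed header (n, v, l, m_a, m_b, seeds, version), the two
arrays bit-packed at l bits per entry little-endian, and a CRC32; truncation,
version mismatch and corruption are explicit errors.

### Alien-query distribution

For a uniformly random key outside the constructed set, the two hash indices
are uniform and independent, so the returned value x has probability

    p_x = Σ_t a_t · b_{x⊕t},

where a_t, b_t are the fractions of entries of A, B equal to t. The package
computes this exact XOR convolution whenever l < 12 (O(4^l)); the probability
of *recognizing* an alien key is P_Alien = p₀ + Σ_{x>v} p_x, and since
untouched entries hold 0, p₀ ≥ a₀b₀ → e^{-n(1/m_a + 1/m_b)} > e^{-1.5} ≈
0.223 as n grows.

For l ≥ 12 the convolution is replaced by the flat estimate
p̄_{x≠0} = (1−p₀)/(2^l−1) with p₀ = Σ_t a_t b_t still computed exactly
(O(2^l)). **Accuracy caveat:** array values are XOR sums of stored category
values along construction-tree paths, which concentrates p_x on small
integers. The flat estimate is therefore near-exact (≲5% relative) when the
category set nearly fills the l-bit range (v close to 2^l − 1), but biased
low by up to ~30% when v sits just above a power of two (e.g. v ≈ 2500,
l = 12). The exact path remains available (`force_exact=True`) for any l.

## Occurrence-map codecs

An occurrence map is an m-bit presence vector over the indexed experiments,
1-based, experiment 1 at the most significant bit of the first payload byte.
Three codecs compete and the shortest (ties: value list > delta list >
bitmap) wins:

* **value list** — t indices of ⌈log₂m⌉ bits (stored 0-based, read as 1-based
  ascending positions); applicable while t·⌈log₂m⌉ ≤ 64;
* **delta list** — alternating run lengths ⟨x₁, y₁, …, x_{w+1}⟩ with
  x₁, x_{w+1} ≥ 0, interior runs ≥ 1, Σ = m; each run length becomes a
  prefix-coded token of 4/8/12/16/32 bits (leading-zero count selects the
  class: values <8, <64, <512, <4096, <2²⁸), so the stream is a hexadecimal
  digit sequence and decodes unambiguously;
* **bitmap** — the m raw bits.

Payloads are padded to byte boundaries; `bit_length` records the unpadded
length, the quantity bucket assignment ranges over. All-absent maps are never
stored at index level (an unobserved k-mer simply is not indexed); the
degenerate ⟨m⟩ delta list appears only transiently in group files.

## Index construction

1. **Group merge.** Per-experiment k-mer files (Jellyfish FASTA dump or plain
   text, gzip-transparent; counts ignored, non-ACGT or wrong-length records
   skipped with a logged count) are merged into groups of ≤50 experiments.
   On disk a group file stores its sorted k-mers with delta-list-encoded
   group-local maps (and is much smaller than the member files whenever the
   k-mer sets overlap); in memory during a build the group matrices stay as
   boolean arrays and are encoded only when persisted. Retained group files
   make later insertion cheap: new experiments are appended as new groups and
   steps 2–3 rerun, giving an index that answers identically to a
   from-scratch build on the union.
2. **Bucket ranges.** k-mers present in exactly one experiment bypass the
   buckets entirely (the root stores their experiment ID). For the rest, the
   chosen-encoding bit lengths are sampled — min(10⁷, max(0.1% of the total,
   10⁴)) maps, seeded — and the per-length counts L_i scaled by the inverse
   sampling fraction. Ranges [n_t, n_{t+1}) grow greedily from length 1 while
   Σ i·L_i stays within the bucket capacity (128 MB of encoded payload by
   default, interpreted as bytes and converted to bits for the inequality; a
   single length class larger than the cap gets a range of its own, and the
   final range is open-ended). Because the estimate is sampled, a bucket's
   realized payload may exceed the cap; that is logged, not fatal.
3. **Othello construction.** Within each bucket, identical encoded maps are
   deduplicated into slots 1..v_b (so v_b, and hence l_b, reflects distinct
   maps — the false-positive marginals W_{x,e} are computed over these
   deduplicated slots); the bucket Othello maps k-mers to slots, and the root
   Othello maps every indexed k-mer to its experiment ID (t = 1) or |E| + b.

The saved index is a directory: `meta.xml` (experiments in ID order, k,
seeds, bucket table), `root.oth`, `bucket_<b>.oth`, gzip-compressed
`bucket_<b>.maps.gz`, and optionally `groups/`. Loading with `preload=True`
decompresses everything up front (online mode); lazy loading defers each
bucket to first use — both answer identically. Builds are deterministic under
the seed down to file bytes (gzip mtime pinned to zero).

## Query semantics

A sequence of length L yields L−k+1 windows; windows containing non-ACGT
characters are invalid — excluded from the denominator w and shown as gaps
(`·`) in hit maps. (Counting invalid windows as misses instead is a
constructor flag away; the reported totals treat w as *valid* k-mers.) Each
valid k-mer resolves three ways at the root: value in 1..|E| → present in
exactly that experiment; |E| < value ≤ |E|+|B| → bucket lookup, where a slot
value in 1..v_b decodes to the exact stored map and anything else means
absent; any other root value means absent everywhere. Indexed k-mers always
return their exact maps; only alien k-mers can false-positive. Hit counts,
ratios (= hits/w exactly) and optional per-window hit maps are reported per
experiment; batch FASTA queries preserve record order even with multiple
worker threads.

## False-positive model

With the alien-value profiles of the root and bucket Othellos, the
whole-index quantities are

    P(e)    = root_p_e + Σ_b root_p_{|E|+b} · Σ_{x∈V_b} bp_x · W_{x,e}
    P_Alien = root_P_Alien + Σ_b root_p_{|E|+b} · bucket_P_Alien,

using the exact convolution per Othello when its l < 12 and the flat
estimate above otherwise. Because alien keys hash uniformly given the built
structure, the number of false hits among w alien query k-mers for
experiment e is exactly Binomial(w, P(e)); `sequence_error_tail` evaluates
its upper tail P[X > c] by direct log-space summation (lgamma-based terms,
fsum), agreeing with exact rational arithmetic to ~13 significant digits —
no normal approximation is involved.

## Fusion calling

A junction query is the concatenation of the last k−1 donor-exon bases and
the first k−1 acceptor-exon bases, so all k−1 constituent k-mers span the
breakpoint; with k = 21 that is the 20+20 junction and 20 k-mers. Repetitive
junction k-mers present in a large fraction of samples inflate everyone's hit
count; assuming a true fusion occurs in under 2% of samples, the background
level δ is read off the per-sample hit distribution as the 98th-percentile
*nearest-rank* value (an achievable integer hit count; the percentile is a
parameter to match other signal-to-noise regimes). A sample is called when
hits ≥ δ + μ (strict > available by flag; the default μ is 7). The
θ-containment rule hits/w ≥ θ is provided for comparison: on junctions with
≥ θ·w repetitive k-mers it calls essentially every background sample, which
the noise-aware rule excludes by construction.

## Synthetic data

The cohort generator reproduces the one property of real collections the
index's behaviour hinges on: the U/L-shaped k-mer occurrence-frequency
histogram. Defaults (100 experiments; 120 core transcripts included
everywhere; 260 variable transcripts with per-transcript inclusion
probabilities uniform in 0.02–0.5; transcript lengths uniform in 100–1000;
3000 private random k-mers per experiment; k = 21) yield ~5×10⁵ distinct
k-mers with ≥30% at frequency 1 and ≥10% at frequency |E|. Transcripts are
random ACGT strings: structural correctness of the index does not depend on
biological sequence composition, so none is simulated — nor are sequencing
errors, abundances, or isoform sharing. Passing tests therefore demonstrate
exact storage/retrieval and calibrated false-positive behaviour, not
robustness to read-level noise.

The fusion generator spikes all junction k-mers into <2% of samples and
injects a configurable subset (defaults 0, 6 and 11 of the 20) into 99% of
samples as repetitive background, plus 100 private filler k-mers per sample;
it validates that the spike margin (k−1) − (background + μ) stays ≥ 1.
Everything is deterministic under the seed and every dataset ships its truth
labels; all oracle tests consume those labels.

## Scales and numerical choices

* Test and acceptance fixtures run at the stated study conditions: full
  cohort 100 × ~5×10⁵ k-mers, 10⁶ alien probes, 2000-sample fusion cohort;
  unit tests use smaller cohorts with a reduced bucket capacity so the
  multi-bucket code paths are exercised.
* Exact/approximate convolution switch at l = 12; both paths cross-validated.
* Monte-Carlo agreement is asserted at 3 binomial standard deviations per
  experiment. One hundred simultaneous 3σ checks carry a ~25% chance of a
  spurious exceedance per fresh random seed; the suite's seeds are fixed, so
  the checks are deterministic.
* Nearest-rank percentile (rank ⌈q/100·N⌉ of the ascending sort) keeps δ an
  integer hit count; ties in codec lengths break toward the cheaper decoder.
* k is odd (default 21, range 15–31) so no k-mer equals its own reverse
  complement under canonicalization.

## Known limitations

* No bit-level compatibility with other implementations' index files is
  attempted; the hash family and serialization are this package's own.
* The flat l ≥ 12 approximation can understate bucket false-positive rates
  by tens of percent when v_b sits just above a power of two (see above);
  predictions for such buckets should use `force_exact` when 2^l makes that
  feasible.
* Construction holds each group's boolean matrix and the merged occurrence
  matrix in memory; collections orders of magnitude beyond the tested scales
  would need out-of-core merging.
* Dynamic insertion of single k-mers into a built Othello is out of scope;
  updates go through retained group files.
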