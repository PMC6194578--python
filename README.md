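# kmeridx

`kmeridx` indexes the k-mer content of many sequencing experiments (bulk or
single-cell RNA-seq, or anything else reducible to per-experiment k-mer sets)
and answers arbitrary sequence queries with per-experiment k-mer hit counts
and hit ratios. It is aimed at large-scale *containment search*: "which of my
thousands of experiments contain this transcript / junction / novel
sequence?" — without realigning any reads.

## The data structure

The atom is the **occurrence map** of a canonical k-mer *s*: the m-bit vector
recording its presence across the m indexed experiments. Maps are compressed
with whichever of three codecs yields the shortest code — a **value list**
(the *t* 1-positions in ⌈log₂m⌉ bits each, used while *t*⌈log₂m⌉ ≤ 64), a
**delta list** (alternating 0-run/1-run lengths ⟨x₁, y₁, …, x_{w+1}⟩ emitted
as prefix-coded hexadecimal tokens), or a raw **bitmap**.

Retrieval is served by a hierarchy of **Othello** classifiers. An Othello
O(S, V) stores a many-to-one map T : S → V = {1..v} in two arrays of
l-bit integers (l = ⌈log₂(v+1)⌉) indexed by a hash pair ⟨h_a, h_b⟩ so that

    τ(s) = A[h_a(s)] XOR B[h_b(s)] = T(s)   for every s ∈ S,

with m_a = 2^⌈log₂n⌉, m_b = 2^⌈log₂(4n/3)⌉, hence at most 4n·l bits in
total and two memory reads per query. k-mers present in a single experiment
are encoded directly in the root Othello (value = experiment ID); all others
route to a bucket (value = |E| + b) chosen by encoded map length, where a
per-bucket Othello maps the k-mer to its stored map slot.

A key queried outside S (an *alien* k-mer) still returns a deterministic
value; the distribution of that value is the XOR convolution of the array
value fractions, p_x = Σ_t a_t·b_{x⊕t}, which makes false-positive rates
computable: per experiment,

    P(e) = root_p_e + Σ_b root_p_{|E|+b} · Σ_{x∈V_b} bp_x · W_{x,e},

and the probability an alien key is recognized as alien satisfies
P_Alien ≥ p₀ > e^-1.5 ≈ 0.223 asymptotically. Over w query k-mers the
false-hit count per experiment is Binomial(w, P(e)).

On top of the query layer sits a **noise-aware fusion caller**: a junction
query concatenates the last 20 donor-exon bases with the first 20
acceptor-exon bases so every 21-mer spans the breakpoint; the per-sample
hit-count distribution yields a background estimate δ (98th-percentile
nearest rank), and a sample is called when its hits reach δ + μ.

## Worked example

```bash
# a labeled synthetic cohort: 8 experiments with a U-shaped k-mer
# occurrence-frequency histogram
kmeridx simulate cohort --out cohort --seed 4 --experiments 8 \
    --core-transcripts 4 --variable-transcripts 8 --private-kmers 150
kmeridx build --manifest cohort/manifest.tsv --out idx --seed 5 --keep-groups
kmeridx info --index idx
```

```
k	21
n_experiments	8
n_buckets	1
n_kmers	5103
experiments	exp0001,exp0002,exp0003,exp0004,exp0005,exp0006,exp0007,exp0008
```

5103 distinct 21-mers were indexed; those present in exactly one experiment
live in the root Othello, the rest in one bucket (the default 128 MB bucket
capacity is far from exhausted here). Querying the first 21-mer of
experiment 1's file:

```bash
head -2 cohort/exp0001.kmers.fa | tail -1 > probe.seq
printf ">probe\n%s\n" "$(cat probe.seq)" > probe.fa
kmeridx query --index idx --fasta probe.fa --out hits.tsv
head -3 hits.tsv
```

```
query	experiment	hits	total_kmers	ratio
probe	exp0001	1	1	1
probe	exp0002	1	1	1
```

This particular k-mer comes from a core transcript the generator put in every
experiment, so its exact 8-experiment occurrence map comes back through the
bucket route and the hit ratio (hits/w with w = 1 valid query k-mer) is 1 in
all eight rows — indexed k-mers always return their exact occurrence maps. `kmeridx fpreport` prints the analytic
per-experiment false-positive probabilities for alien k-mers alongside
(optionally) their Monte-Carlo measurements, and `kmeridx fusion` runs the
noise-aware caller over a junction table.

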