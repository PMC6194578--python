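import gzip
from pathlib import Path

import numpy as np
import pytest

from kmeridx import codecs
from kmeridx.index import (
    Bucket,
    BucketSpec,
    ExperimentManifest,
    GroupFile,
    IndexFormatError,
    _build_bucket,
    assign_to_buckets,
    build_group_file,
    build_index,
    estimate_bucket_ranges,
    insert_experiments,
    load_index,
    merge_group_files,
    save_index,
)
from kmeridx.kmers import kmers_to_bytes, random_kmers


def write_kmer_file(path, keys, k=21):
    Path(path).write_bytes(kmers_to_bytes(np.sort(np.asarray(keys, dtype=np.uint64)), k))
    return str(path)


@pytest.fixture()
def tiny_experiments(tmp_path, rng):
    """10 experiments over a shared pool so k-mer sets overlap."""
    pool = random_kmers(600, 21, rng)
    entries, membership = [], []
    for e in range(10):
        mask = rng.random(600) < 0.4
        mask[rng.integers(0, 600)] = True
        entries.append((f"e{e}", write_kmer_file(tmp_path / f"e{e}.txt", pool[mask])))
        membership.append(mask)
    return pool, np.array(membership).T, entries  # truth: (n_kmers, 10)


# -- groups --------------------------------------------------------------------

def test_single_member_group(tmp_path, rng):
    keys = random_kmers(50, 21, rng)
    path = write_kmer_file(tmp_path / "one.txt", keys)
    g = build_group_file([("solo", path)], 21)
    assert g.occ.shape == (50, 1) and g.occ.all()


def test_group_membership_matches_sets(tiny_experiments):
    pool, truth, entries = tiny_experiments
    g = build_group_file(entries[:4], 21)
    present = truth[:, :4].any(axis=1)
    assert np.array_equal(g.kmers, pool[present])
    assert np.array_equal(g.occ, truth[present][:, :4])


def test_group_file_roundtrip_and_compression(tmp_path, tiny_experiments):
    pool, truth, entries = tiny_experiments
    g = build_group_file(entries, 21)
    path = tmp_path / "g.grp"
    g.save(path)
    g2 = GroupFile.load(path)
    assert g2.member_names == g.member_names
    assert np.array_equal(g2.kmers, g.kmers)
    assert np.array_equal(g2.occ, g.occ)
    member_bytes = sum(Path(p).stat().st_size for _, p in entries)
    assert path.stat().st_size < member_bytes  # overlapping sets compress


def test_merge_group_files_matches_dense_oracle(tiny_experiments):
    pool, truth, entries = tiny_experiments
    groups = [build_group_file(entries[i : i + 4], 21) for i in (0, 4, 8)]
    names, union, occ = merge_group_files(groups)
    present = truth.any(axis=1)
    assert names == [n for n, _ in entries]
    assert np.array_equal(union, pool[present])
    assert np.array_equal(occ, truth[present])


def test_merge_rejects_duplicate_experiments(tiny_experiments):
    _, _, entries = tiny_experiments
    g = build_group_file(entries[:2], 21)
    with pytest.raises(ValueError, match="more than one group"):
        merge_group_files([g, g])


# -- bucket range estimation ----------------------------------------------------

def test_single_bucket_when_under_cap():
    lengths = np.full(100, 24)
    specs = estimate_bucket_ranges(lengths, total=100, cap_bytes=1 << 20)
    assert specs == [BucketSpec(1, 1, None)]


def test_greedy_ranges_are_maximal():
    # 10 maps at each length 4, 8, 12, 16; cap = 7 bytes = 56 bits.
    # By hand: 4*10 = 40 fits; adding 8*10 = 80 exceeds -> [1, 8).
    # 8*10 = 80 exceeds the cap on its own, so it gets a bucket [8, 12)
    # (a single length class is never split); likewise [12, 16), [16, inf).
    lengths = np.repeat([4, 8, 12, 16], 10)
    specs = estimate_bucket_ranges(lengths, total=40, cap_bytes=7)
    assert specs == [
        BucketSpec(1, 1, 8),
        BucketSpec(2, 8, 12),
        BucketSpec(3, 12, 16),
        BucketSpec(4, 16, None),
    ]
    # maximality: extending any closed bucket by the next occupied class
    # would push it over the cap
    counts = np.bincount(lengths, minlength=20)
    for spec, nxt in zip(specs, specs[1:]):
        in_range = sum(j * counts[j] for j in range(spec.lo, nxt.lo))
        assert in_range + nxt.lo * counts[nxt.lo] > 56


def test_empty_sample_is_an_error():
    with pytest.raises(ValueError, match="empty"):
        estimate_bucket_ranges(np.array([], dtype=int), total=0, cap_bytes=1)


def test_assignment_respects_ranges_and_root_direct(rng):
    kmers = random_kmers(500, 21, rng)
    occ = rng.random((500, 100)) < 0.05
    occ[:, 0] |= ~occ.any(axis=1)
    root_k, root_e, specs, buckets = assign_to_buckets(kmers, occ, cap_bytes=64, seed=3)
    t = occ.sum(axis=1)
    assert np.array_equal(root_k, kmers[t == 1])
    assert np.array_equal(root_e, occ[t == 1].argmax(axis=1) + 1)
    for spec, (bk, bencs) in zip(specs, buckets):
        for enc in bencs:
            assert spec.lo <= enc.bit_length
            assert spec.hi is None or enc.bit_length < spec.hi
    # a k-mer in exactly 2 of 100 experiments -> 14-bit value list
    two = np.flatnonzero(t == 2)
    if two.size:
        for spec, (bk, bencs) in zip(specs, buckets):
            if np.isin(kmers[two[0]], bk):
                assert spec.lo <= 14 and (spec.hi is None or 14 < spec.hi)


# -- index build / query --------------------------------------------------------

def test_build_single_experiment_has_no_buckets(tmp_path, rng):
    keys = random_kmers(100, 21, rng)
    m = ExperimentManifest([("only", write_kmer_file(tmp_path / "o.txt", keys))], 21)
    idx = build_index(m, seed=1)
    assert idx.n_buckets == 0
    assert (np.asarray(idx.route(keys)) == 1).all()


def test_small_build_exact_retrieval(small_cohort, small_index):
    dense = small_index.query_kmers_dense(small_cohort.kmers)
    assert np.array_equal(dense, small_cohort.truth)
    t = small_cohort.truth.sum(axis=1)
    tau = np.asarray(small_index.route(small_cohort.kmers))
    E = small_index.n_experiments
    assert ((tau <= E) == (t == 1)).all()  # single-occurrence root optimization


def test_query_kmer_three_way_routing(small_cohort, small_index):
    t = small_cohort.truth.sum(axis=1)
    i1 = np.flatnonzero(t == 1)[0]
    res = small_index.query_kmer(int(small_cohort.kmers[i1]))
    assert res.route == "root"
    assert res.experiment == int(small_cohort.truth[i1].argmax()) + 1
    i2 = np.flatnonzero(t >= 2)[0]
    res2 = small_index.query_kmer(int(small_cohort.kmers[i2]))
    assert res2.route == "bucket"
    assert np.array_equal(res2.occurrence.bits, small_cohort.truth[i2])


def test_bucket_integrity(small_index):
    for b in range(1, small_index.n_buckets + 1):
        bk = small_index._bucket(b)
        spec = small_index.specs[b - 1]
        assert bk.v_b == len(set(zip(bk.kinds.tolist(), bk.bitlens.tolist(), bk.offsets.tolist())))
        for slot in range(1, bk.v_b + 1):
            omap = bk.decode_slot(slot)
            assert omap.m == small_index.n_experiments
            assert spec.lo <= bk.bitlens[slot - 1]
            assert spec.hi is None or bk.bitlens[slot - 1] < spec.hi
        ends = bk.offsets + (bk.bitlens + 7) // 8
        assert (bk.offsets[1:] >= ends[:-1]).all()  # non-overlapping slots


def test_rebuild_determinism(small_cohort):
    a = build_index(small_cohort.manifest, group_size=7, cap_bytes=2 << 10, seed=7)
    b = build_index(small_cohort.manifest, group_size=7, cap_bytes=2 << 10, seed=7)
    assert a.root.to_bytes() == b.root.to_bytes()
    for x, y in zip(a.buckets, b.buckets):
        assert x.othello.to_bytes() == y.othello.to_bytes()
        assert x.maps_to_bytes() == y.maps_to_bytes()


def test_save_load_roundtrip(tmp_path, small_cohort, small_index, rng):
    d = tmp_path / "idx"
    save_index(small_index, d)
    probes = random_kmers(5000, 21, rng)
    expected = small_index.query_kmers_dense(probes)
    for preload in (True, False):
        idx2 = load_index(d, preload=preload)
        assert idx2.experiment_names == small_index.experiment_names
        assert np.array_equal(idx2.query_kmers_dense(probes), expected)
        assert np.array_equal(
            idx2.query_kmers_dense(small_cohort.kmers), small_cohort.truth
        )
    # gzip makes the on-disk maps smaller than the raw payload
    raw = sum(len(small_index._bucket(b).maps_to_bytes()) for b in range(1, small_index.n_buckets + 1))
    on_disk = sum((d / f"bucket_{b}.maps.gz").stat().st_size for b in range(1, small_index.n_buckets + 1))
    assert on_disk < raw
    # metadata lists experiments in ID order
    meta = (d / "meta.xml").read_text()
    assert all(name in meta for name in small_index.experiment_names)


def test_load_missing_meta_is_an_error(tmp_path):
    with pytest.raises(IndexFormatError, match="meta.xml"):
        load_index(tmp_path / "nope")


def test_saved_indexes_are_byte_identical(tmp_path, small_cohort):
    dirs = []
    for tag in ("a", "b"):
        idx = build_index(small_cohort.manifest, group_size=7, cap_bytes=2 << 10, seed=7)
        d = tmp_path / tag
        save_index(idx, d)
        dirs.append(d)
    for f in sorted(p.name for p in dirs[0].iterdir()):
        assert (dirs[0] / f).read_bytes() == (dirs[1] / f).read_bytes()


# -- insertion -------------------------------------------------------------------

def test_insert_zero_experiments_is_identity(small_cohort, rng):
    base = build_index(small_cohort.manifest, group_size=7, cap_bytes=2 << 10, seed=7,
                       keep_groups=True)
    same = insert_experiments(base.groups, [], group_size=7, cap_bytes=2 << 10, seed=7)
    probes = random_kmers(2000, 21, rng)
    assert np.array_equal(base.query_kmers_dense(probes), same.query_kmers_dense(probes))


def test_inserted_experiments_get_appended_ids(small_cohort):
    entries = small_cohort.manifest.entries
    base = build_index(
        ExperimentManifest(entries[:15], 21), group_size=7, cap_bytes=2 << 10, seed=7,
        keep_groups=True,
    )
    grown = insert_experiments(base.groups, entries[15:], group_size=7,
                               cap_bytes=2 << 10, seed=7)
    assert grown.experiment_names == [n for n, _ in entries]
    with pytest.raises(ValueError, match="already indexed"):
        insert_experiments(base.groups, entries[:1])


def test_bucket_marginal_free_experiment():
    maps = [codecs.OccurrenceMap.from_positions(4, [1, 2]),
            codecs.OccurrenceMap.from_positions(4, [2, 3])]
    encs = [codecs.choose_encoding(m) for m in maps]
    kmers = np.array([11, 22], dtype=np.uint64)
    bk = _build_bucket(1, kmers, encs, m=4, seed=0)
    assert bk.slot_matrix()[:, 3].sum() == 0  # experiment 4 marked nowhere
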