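import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kmeridx import codecs
from kmeridx.codecs import (
    CodecError,
    EncodingKind,
    EncodingNotApplicable,
    OccurrenceMap,
    _BitReader,
    choose_encoding,
    decode_occurrence,
    encode_bitmap,
    encode_delta_list,
    encode_value_list,
    expand_delta_list,
    hex_decode_integer,
    hex_decode_stream,
    hex_encode_delta_list,
    hex_encode_integer,
)

# deterministic hypothesis runs
settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def occurrence_maps(max_m=4096, min_t=0):
    @st.composite
    def _maps(draw):
        m = draw(st.integers(min_value=max(1, min_t), max_value=max_m))
        density = draw(st.floats(min_value=0.0, max_value=1.0))
        seed = draw(st.integers(min_value=0, max_value=2**31 - 1))
        bits = np.random.default_rng(seed).random(m) < density
        if min_t and bits.sum() < min_t:
            bits[draw(st.integers(min_value=0, max_value=m - 1))] = True
        return OccurrenceMap(bits)

    return _maps()


# -- worked example ------------------------------------------------------------

def test_delta_list_worked_example():
    omap = OccurrenceMap.from_string("11100111111111111110")
    runs = encode_delta_list(omap)
    assert runs == [0, 3, 2, 14, 1]
    enc = hex_encode_delta_list(runs)
    assert enc.payload.hex() == "8ba4e9"
    assert enc.bit_length == 24
    assert decode_occurrence(enc, 20) == omap


# -- hexadecimal token table ---------------------------------------------------

@pytest.mark.parametrize(
    "z, token, nbits",
    [
        (0, 0x8, 4),
        (7, 0xF, 4),
        (8, 0x48, 8),
        (14, 0x4E, 8),
        (63, 0x7F, 8),
        (64, 0x240, 12),
        (511, 0x3FF, 12),
        (512, 0x1200, 16),
        (4095, 0x1FFF, 16),
        (4096, 0x00001000, 32),
        (2**28 - 1, 2**28 - 1, 32),
    ],
)
def test_hex_token_classes(z, token, nbits):
    assert hex_encode_integer(z) == (token, nbits)


def test_hex_token_overflow():
    with pytest.raises(ValueError, match="overflows"):
        hex_encode_integer(2**28)


@pytest.mark.parametrize("z", list(range(0, 600)) + [4095, 4096, 10_000, 2**28 - 1])
def test_hex_token_roundtrip(z):
    token, nbits = hex_encode_integer(z)
    payload = (token << ((-nbits) % 8)).to_bytes((nbits + 7) // 8, "big")
    assert hex_decode_integer(_BitReader(payload, nbits)) == z


@given(st.lists(st.integers(min_value=0, max_value=2**28 - 1), min_size=1, max_size=30))
def test_hex_stream_is_prefix_free(zs):
    """Any token concatenation decodes back to the same integers."""
    enc = hex_encode_delta_list(zs)
    rd = _BitReader(enc.payload, enc.bit_length)
    decoded = [hex_decode_integer(rd) for _ in zs]
    assert decoded == zs


# -- delta list ----------------------------------------------------------------

def test_delta_list_all_ones():
    omap = OccurrenceMap.from_string("11111")
    runs = encode_delta_list(omap)
    assert runs == [0, 5, 0]
    enc = hex_encode_delta_list(runs)
    assert enc.payload.hex().rstrip("0") == "8d8"
    assert enc.bit_length == 12


def test_delta_list_all_zero_degenerates():
    omap = OccurrenceMap(np.zeros(13, dtype=bool))
    assert encode_delta_list(omap) == [13]
    assert expand_delta_list([13], 13) == omap


@given(occurrence_maps(max_m=2000))
def test_delta_runs_sum_to_m(omap):
    runs = encode_delta_list(omap)
    assert sum(runs) == omap.m
    assert len(runs) % 2 == 1
    assert expand_delta_list(runs, omap.m) == omap


def test_delta_decode_detects_corruption():
    enc = hex_encode_delta_list([0, 3, 2, 14, 1])
    with pytest.raises(CodecError):
        hex_decode_stream(enc.payload, enc.bit_length, 19)  # wrong m


# -- value list ----------------------------------------------------------------

def test_value_list_examples():
    enc = encode_value_list(OccurrenceMap.from_positions(20, [1, 2, 3]))
    assert enc.bit_length == 15  # 3 indices x ceil(log2 20) = 5 bits
    enc2 = encode_value_list(OccurrenceMap.from_positions(2, [2]))
    assert enc2.bit_length == 1
    assert decode_occurrence(enc2, 2) == OccurrenceMap.from_positions(2, [2])


def test_value_list_gate():
    omap = OccurrenceMap(np.ones(20, dtype=bool))  # t*ceil(log2 m) = 100 > 64
    with pytest.raises(EncodingNotApplicable):
        encode_value_list(omap)
    with pytest.raises(ValueError, match="never stored"):
        encode_value_list(OccurrenceMap(np.zeros(8, dtype=bool)))


@given(occurrence_maps(max_m=4096, min_t=1))
def test_value_list_roundtrip_when_applicable(omap):
    try:
        enc = encode_value_list(omap)
    except EncodingNotApplicable:
        return
    assert decode_occurrence(enc, omap.m) == omap


# -- bitmap --------------------------------------------------------------------

def test_bitmap_bit_order():
    enc = encode_bitmap(OccurrenceMap.from_positions(8, [1]))
    assert enc.payload == b"\x80"  # experiment 1 = MSB of byte 0
    assert encode_bitmap(OccurrenceMap(np.zeros(8, dtype=bool))).payload == b"\x00"
    assert decode_occurrence(enc, 8) == OccurrenceMap.from_positions(8, [1])


# -- shortest-code dispatch ----------------------------------------------------

def test_choose_encoding_examples(rng):
    sparse = choose_encoding(OccurrenceMap.from_positions(10_000, [3, 77]))
    assert sparse.kind == EncodingKind.VALUE_LIST and sparse.bit_length == 28

    dense = choose_encoding(OccurrenceMap(np.ones(20, dtype=bool)))
    assert dense.kind == EncodingKind.DELTA_LIST and dense.bit_length == 16

    noisy = choose_encoding(OccurrenceMap(rng.random(512) < 0.5))
    assert noisy.kind == EncodingKind.BITMAP and noisy.bit_length == 512


@given(occurrence_maps(max_m=4096, min_t=1))
def test_choose_encoding_is_minimal_and_lossless(omap):
    enc = choose_encoding(omap)
    assert decode_occurrence(enc, omap.m) == omap
    lengths = [hex_encode_delta_list(encode_delta_list(omap)).bit_length, omap.m]
    try:
        lengths.append(encode_value_list(omap).bit_length)
    except EncodingNotApplicable:
        width = max(1, int(np.ceil(np.log2(omap.m))))
        assert omap.t * width > 64 or omap.m < 2  # the gate, never bypassed
        assert enc.kind != EncodingKind.VALUE_LIST
    assert enc.bit_length <= min(lengths)


@given(occurrence_maps(max_m=4096, min_t=1))
def test_all_codec_roundtrips(omap):
    for encoder in (encode_bitmap, lambda m: hex_encode_delta_list(encode_delta_list(m))):
        assert decode_occurrence(encoder(omap), omap.m) == omap
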