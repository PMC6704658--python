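"""Record codec and block store: round trips, determinism, size direction."""

import copy
import json
import os

import pytest

from genoquery import store
from genoquery.store import (
    StoreError, decode_record, decode_varint, encode_record, encode_varint,
    export_jsonl, read_store, read_store_blocks, write_store,
)

from conftest import make_record


@pytest.mark.parametrize("value, expected", [
    (0, b"\x00"),
    (1, b"\x01"),
    (127, b"\x7f"),
    (128, b"\x80\x01"),
    (300, b"\xac\x02"),   # base-128 varint worked example
    (2 ** 32, b"\x80\x80\x80\x80\x10"),
])
def test_varint_encoding(value, expected):
    assert encode_varint(value) == expected
    decoded, offset = decode_varint(expected, 0)
    assert (decoded, offset) == (value, len(expected))


def test_varint_rejects_negative():
    with pytest.raises(StoreError):
        encode_varint(-1)


def test_encode_decode_round_trip_hand_built():
    record = make_record(n_exons=3)
    assert decode_record(encode_record(record)) == record


def test_encode_is_deterministic():
    record = make_record(n_exons=2)
    assert encode_record(record) == encode_record(copy.deepcopy(record))


def test_round_trip_on_simulated_records(light_corpus):
    for record in light_corpus.records()[:100]:
        assert decode_record(encode_record(record)) == record


def test_optional_fields_absent_vs_present():
    record = make_record()
    base = encode_record(record)
    record.sequences[0].features[0].score = 0.5
    record.sequences[0].features[0].phase = 2
    with_opts = encode_record(record)
    assert len(with_opts) > len(base)
    decoded = decode_record(with_opts)
    assert decoded.sequences[0].features[0].score == 0.5
    assert decoded.sequences[0].features[0].phase == 2
    assert decode_record(base).sequences[0].features[0].score is None


def test_unknown_field_id_is_skipped():
    record = make_record()
    payload = encode_record(record)
    extra = encode_varint((99 << 3) | 0) + encode_varint(12345)
    assert decode_record(payload + extra) == record
    extra_str = encode_varint((77 << 3) | 2) + encode_varint(3) + b"abc"
    assert decode_record(payload + extra_str) == record


def test_truncated_payload_reports_offset():
    payload = encode_record(make_record())
    with pytest.raises(StoreError, match="byte offset"):
        decode_record(payload[:-1])
    with pytest.raises(StoreError, match="truncated varint"):
        decode_varint(b"\xff", 0)


def test_invalid_record_is_rejected_with_violations():
    record = make_record()
    record.taxid = 0
    with pytest.raises(StoreError, match="taxid"):
        encode_record(record)


def test_block_partitioning_300_records(tmp_path):
    records = [make_record(accession=f"GCF_{i:09d}.1") for i in range(300)]
    path = tmp_path / "db.bgsf"
    assert write_store(records, path, block_records=256) == 300
    sizes = [len(block) for block in read_store_blocks(path)]
    assert sizes == [256, 44]


def test_store_round_trip_preserves_order(tmp_path):
    records = [make_record(accession=f"GCF_{i:09d}.1", total_length=100 + i)
               for i in range(20)]
    path = tmp_path / "db.bgsf"
    write_store(records, path, block_records=7)
    assert list(read_store(path)) == records


def test_empty_store(tmp_path):
    path = tmp_path / "db.bgsf"
    assert write_store([], path) == 0
    assert list(read_store(path)) == []


def test_store_files_byte_identical_across_runs(tmp_path):
    records = [make_record(accession=f"GCF_{i:09d}.1") for i in range(10)]
    p1, p2 = tmp_path / "a.bgsf", tmp_path / "b.bgsf"
    write_store(records, p1)
    write_store(records, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_uncompressed_flag_round_trip(tmp_path):
    records = [make_record(accession=f"GCF_{i:09d}.1") for i in range(5)]
    path = tmp_path / "db.bgsf"
    write_store(records, path, compress=False)
    assert list(read_store(path)) == records


def test_bad_magic_and_unknown_flags_rejected(tmp_path):
    path = tmp_path / "bad.bgsf"
    path.write_bytes(b"NOPE!" + bytes(9))
    with pytest.raises(StoreError, match="not a genoquery store"):
        list(read_store(path))
    path.write_bytes(store.MAGIC + b"\x02" + bytes(8))
    with pytest.raises(StoreError, match="unknown store flag"):
        list(read_store(path))


def test_export_jsonl_shape(tmp_path):
    records = [make_record(accession=f"GCF_{i:09d}.1", taxid=123 + i)
               for i in range(3)]
    path = tmp_path / "db.jsonl"
    assert export_jsonl(records, path) == 3
    lines = path.read_text().splitlines()
    assert len(lines) == 3
    obj = json.loads(lines[0])
    assert obj["taxid"] == 123
    assert list(obj) == sorted(obj)
    assert obj["assembly"]["total_length"] == records[0].assembly.total_length


def test_export_jsonl_empty(tmp_path):
    path = tmp_path / "empty.jsonl"
    assert export_jsonl([], path) == 0
    assert path.read_bytes() == b""
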