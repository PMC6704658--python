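"""Compact binary record store: the single-machine sequence-file analogue.

Records are serialized with a deterministic tag-length-value codec modeled
on protocol buffers: each present field is written in ascending field-id
order as a key varint ``(field_id << 3) | wire_type`` followed by the
payload. Wire types:

* 0 — non-negative integer as a base-128 little-endian varint
* 1 — 64-bit little-endian IEEE-754 double (used for Feature.score)
* 2 — varint byte length + payload (UTF-8 string or nested record)

Repeated fields are written as repeated keys in element order; absent
optional fields are omitted entirely, so encoding is canonical: equal
records produce byte-identical output. Unknown field ids are skipped on
decode using their wire type, which gives forward compatibility.

Field-id tables (fixed; changing them breaks stored files):

    GenomeRecord: 1 refseq_accession(s) 2 taxid(v) 3 organism_name(s)
                  4 lineage(s, repeated) 5 release_year(v) 6 assembly(m)
                  7 sequences(m, repeated)
    AssemblyMeta: 1 assemblers(m, repeated) 2 total_length(v)
                  3 total_gap_length(v) 4 scaffold_n50(v) 5 scaffold_count(v)
                  6 contig_n50(v) 7 contig_count(v)
    AssemblerRec: 1 name(s) 2 desc(s)
    SequenceRec:  1 header(s) 2 accession(s) 3 length(v)
                  4 features(m, repeated) 5 seq(s, optional)
    FeatureRec:   1 seqid(s) 2 source(s) 3 ftype(s) 4 start(v) 5 end(v)
                  6 score(d, optional) 7 strand(s) 8 phase(v, optional)
                  9 attributes(m, repeated) 10 parent(s, optional)
    AttributeRec: 1 tag(s) 2 value(s)

The store file is ``StoreHeader`` (magic ``BGSF1``, one flags byte with bit
0 = per-block DEFLATE, record count as u64 LE) followed by blocks. A block
is three u32 LE words (compressed size, raw size, record count) and the
payload; inside a block each record is prefixed with its varint byte length
so the concatenation is self-delimiting. All multi-byte integers are
little-endian. Identical inputs and settings yield byte-identical files.
"""

from __future__ import annotations

import json
import struct
import zlib
from dataclasses import asdict
from typing import BinaryIO, Iterable, Iterator, Union
import os

from .schema import (
    AssemblerRec,
    AssemblyMeta,
    AttributeRec,
    FeatureRec,
    GenomeRecord,
    SequenceRec,
    validate,
)

__all__ = [
    "StoreError",
    "encode_record",
    "decode_record",
    "write_store",
    "read_store",
    "read_store_blocks",
    "read_store_header",
    "export_jsonl",
    "encode_varint",
    "decode_varint",
    "MAGIC",
]

MAGIC = b"BGSF1"
FLAG_COMPRESSED = 0x01
DEFAULT_BLOCK_RECORDS = 256


class StoreError(ValueError):
    """Raised for invalid records, corrupt files, or unknown format bits."""


# ---------------------------------------------------------------------------
# varint + TLV primitives

def encode_varint(value: int) -> bytes:
    if value < 0:
        raise StoreError(f"varint cannot encode negative value {value}")
    out = bytearray()
    while True:
        b = value & 0x7F
        value >>= 7
        if value:
            out.append(b | 0x80)
        else:
            out.append(b)
            return bytes(out)


def decode_varint(data: bytes, offset: int) -> tuple[int, int]:
    """Decode a varint at offset; returns (value, new offset)."""
    result = 0
    shift = 0
    pos = offset
    while True:
        if pos >= len(data):
            raise StoreError(f"truncated varint at byte offset {offset}")
        b = data[pos]
        result |= (b & 0x7F) << shift
        pos += 1
        if not (b & 0x80):
            return result, pos
        shift += 7
        if shift > 63:
            raise StoreError(f"varint too long at byte offset {offset}")


def _key(field_id: int, wire_type: int) -> bytes:
    return encode_varint((field_id << 3) | wire_type)


def _emit_varint_field(out: bytearray, field_id: int, value: int) -> None:
    out += _key(field_id, 0)
    out += encode_varint(value)


def _emit_double_field(out: bytearray, field_id: int, value: float) -> None:
    out += _key(field_id, 1)
    out += struct.pack("<d", value)


def _emit_bytes_field(out: bytearray, field_id: int, payload: bytes) -> None:
    out += _key(field_id, 2)
    out += encode_varint(len(payload))
    out += payload


def _emit_str_field(out: bytearray, field_id: int, value: str) -> None:
    _emit_bytes_field(out, field_id, value.encode("utf-8"))


# ---------------------------------------------------------------------------
# per-type encoders

def _encode_attribute(a: AttributeRec) -> bytes:
    out = bytearray()
    _emit_str_field(out, 1, a.tag)
    _emit_str_field(out, 2, a.value)
    return bytes(out)


def _encode_feature(f: FeatureRec) -> bytes:
    out = bytearray()
    _emit_str_field(out, 1, f.seqid)
    _emit_str_field(out, 2, f.source)
    _emit_str_field(out, 3, f.ftype)
    _emit_varint_field(out, 4, f.start)
    _emit_varint_field(out, 5, f.end)
    if f.score is not None:
        _emit_double_field(out, 6, f.score)
    _emit_str_field(out, 7, f.strand)
    if f.phase is not None:
        _emit_varint_field(out, 8, f.phase)
    for a in f.attributes:
        _emit_bytes_field(out, 9, _encode_attribute(a))
    if f.parent is not None:
        _emit_str_field(out, 10, f.parent)
    return bytes(out)


def _encode_sequence(s: SequenceRec) -> bytes:
    out = bytearray()
    _emit_str_field(out, 1, s.header)
    _emit_str_field(out, 2, s.accession)
    _emit_varint_field(out, 3, s.length)
    for f in s.features:
        _emit_bytes_field(out, 4, _encode_feature(f))
    if s.seq is not None:
        _emit_str_field(out, 5, s.seq)
    return bytes(out)


def _encode_assembler(a: AssemblerRec) -> bytes:
    out = bytearray()
    _emit_str_field(out, 1, a.name)
    _emit_str_field(out, 2, a.desc)
    return bytes(out)


def _encode_assembly(m: AssemblyMeta) -> bytes:
    out = bytearray()
    for a in m.assemblers:
        _emit_bytes_field(out, 1, _encode_assembler(a))
    _emit_varint_field(out, 2, m.total_length)
    _emit_varint_field(out, 3, m.total_gap_length)
    _emit_varint_field(out, 4, m.scaffold_n50)
    _emit_varint_field(out, 5, m.scaffold_count)
    _emit_varint_field(out, 6, m.contig_n50)
    _emit_varint_field(out, 7, m.contig_count)
    return bytes(out)


def encode_record(record: GenomeRecord) -> bytes:
    """Serialize a valid GenomeRecord to its canonical byte string."""
    violations = validate(record)
    if violations:
        raise StoreError("invalid record: " + "; ".join(violations))
    out = bytearray()
    _emit_str_field(out, 1, record.refseq_accession)
    _emit_varint_field(out, 2, record.taxid)
    _emit_str_field(out, 3, record.organism_name)
    for clade in record.lineage:
        _emit_str_field(out, 4, clade)
    _emit_varint_field(out, 5, record.release_year)
    _emit_bytes_field(out, 6, _encode_assembly(record.assembly))
    for s in record.sequences:
        _emit_bytes_field(out, 7, _encode_sequence(s))
    return bytes(out)


# ---------------------------------------------------------------------------
# decoding

def _iter_fields(data: bytes) -> Iterator[tuple[int, int, object, int]]:
    """Yield (field_id, wire_type, payload, offset) over a TLV byte string.

    Payload is int for wire 0, float for wire 1, bytes for wire 2.
    """
    pos = 0
    n = len(data)
    while pos < n:
        start = pos
        key, pos = decode_varint(data, pos)
        field_id, wire = key >> 3, key & 0x07
        if wire == 0:
            value, pos = decode_varint(data, pos)
            yield field_id, wire, value, start
        elif wire == 1:
            if pos + 8 > n:
                raise StoreError(f"truncated double at byte offset {pos}")
            (value,) = struct.unpack_from("<d", data, pos)
            pos += 8
            yield field_id, wire, value, start
        elif wire == 2:
            length, pos = decode_varint(data, pos)
            if pos + length > n:
                raise StoreError(f"truncated payload at byte offset {pos}")
            yield field_id, wire, data[pos:pos + length], start
            pos += length
        else:
            raise StoreError(f"unknown wire type {wire} at byte offset {start}")


def _expect(wire: int, want: int, field_id: int, offset: int) -> None:
    if wire != want:
        raise StoreError(
            f"field {field_id} at byte offset {offset}: wire type {wire}, expected {want}")


def _decode_attribute(data: bytes) -> AttributeRec:
    tag = value = ""
    for fid, wire, payload, off in _iter_fields(data):
        if fid == 1:
            _expect(wire, 2, fid, off)
            tag = payload.decode("utf-8")
        elif fid == 2:
            _expect(wire, 2, fid, off)
            value = payload.decode("utf-8")
    return AttributeRec(tag=tag, value=value)


def _decode_feature(data: bytes) -> FeatureRec:
    f = FeatureRec(seqid="", source="", ftype="", start=1, end=1)
    for fid, wire, payload, off in _iter_fields(data):
        if fid == 1:
            f.seqid = payload.decode("utf-8")
        elif fid == 2:
            f.source = payload.decode("utf-8")
        elif fid == 3:
            f.ftype = payload.decode("utf-8")
        elif fid == 4:
            f.start = payload
        elif fid == 5:
            f.end = payload
        elif fid == 6:
            _expect(wire, 1, fid, off)
            f.score = payload
        elif fid == 7:
            f.strand = payload.decode("utf-8")
        elif fid == 8:
            f.phase = payload
        elif fid == 9:
            f.attributes.append(_decode_attribute(payload))
        elif fid == 10:
            f.parent = payload.decode("utf-8")
    return f


def _decode_sequence(data: bytes) -> SequenceRec:
    s = SequenceRec(header="", accession="")
    for fid, wire, payload, off in _iter_fields(data):
        if fid == 1:
            s.header = payload.decode("utf-8")
        elif fid == 2:
            s.accession = payload.decode("utf-8")
        elif fid == 3:
            s.length = payload
        elif fid == 4:
            s.features.append(_decode_feature(payload))
        elif fid == 5:
            s.seq = payload.decode("utf-8")
    return s


def _decode_assembler(data: bytes) -> AssemblerRec:
    name = desc = ""
    for fid, wire, payload, off in _iter_fields(data):
        if fid == 1:
            name = payload.decode("utf-8")
        elif fid == 2:
            desc = payload.decode("utf-8")
    return AssemblerRec(name=name, desc=desc)


def _decode_assembly(data: bytes) -> AssemblyMeta:
    m = AssemblyMeta()
    for fid, wire, payload, off in _iter_fields(data):
        if fid == 1:
            m.assemblers.append(_decode_assembler(payload))
        elif fid == 2:
            m.total_length = payload
        elif fid == 3:
            m.total_gap_length = payload
        elif fid == 4:
            m.scaffold_n50 = payload
        elif fid == 5:
            m.scaffold_count = payload
        elif fid == 6:
            m.contig_n50 = payload
        elif fid == 7:
            m.contig_count = payload
    return m


def decode_record(data: bytes) -> GenomeRecord:
    """Exact inverse of encode_record; unknown field ids are skipped."""
    r = GenomeRecord(refseq_accession="", taxid=1)
    for fid, wire, payload, off in _iter_fields(data):
        if fid == 1:
            r.refseq_accession = payload.decode("utf-8")
        elif fid == 2:
            r.taxid = payload
        elif fid == 3:
            r.organism_name = payload.decode("utf-8")
        elif fid == 4:
            r.lineage.append(payload.decode("utf-8"))
        elif fid == 5:
            r.release_year = payload
        elif fid == 6:
            _expect(wire, 2, fid, off)
            r.assembly = _decode_assembly(payload)
        elif fid == 7:
            r.sequences.append(_decode_sequence(payload))
    return r


# ---------------------------------------------------------------------------
# store file

_HEADER = struct.Struct("<5sBQ")
_BLOCK_HEAD = struct.Struct("<III")


def write_store(
    records: Iterable[GenomeRecord],
    path: Union[str, os.PathLike],
    block_records: int = DEFAULT_BLOCK_RECORDS,
    compress: bool = True,
) -> int:
    """Write records to a block store file; returns the record count."""
    if block_records < 1:
        raise StoreError("block_records must be >= 1")
    flags = FLAG_COMPRESSED if compress else 0
    count = 0
    with open(path, "wb") as fh:
        fh.write(_HEADER.pack(MAGIC, flags, 0))
        buf = bytearray()
        in_block = 0

        def flush() -> None:
            nonlocal buf, in_block
            if not in_block:
                return
            raw = bytes(buf)
            payload = zlib.compress(raw, 6) if compress else raw
            fh.write(_BLOCK_HEAD.pack(len(payload), len(raw), in_block))
            fh.write(payload)
            buf = bytearray()
            in_block = 0

        for record in records:
            encoded = encode_record(record)
            buf += encode_varint(len(encoded))
            buf += encoded
            in_block += 1
            count += 1
            if in_block >= block_records:
                flush()
        flush()
        fh.seek(0)
        fh.write(_HEADER.pack(MAGIC, flags, count))
    return count


def read_store_header(fh: BinaryIO) -> tuple[int, int]:
    """Read and check the store header; returns (flags, record_count)."""
    head = fh.read(_HEADER.size)
    if len(head) != _HEADER.size:
        raise StoreError("truncated store header")
    magic, flags, record_count = _HEADER.unpack(head)
    if magic != MAGIC:
        raise StoreError("not a genoquery store (bad magic)")
    if flags & ~FLAG_COMPRESSED:
        raise StoreError(f"unknown store flag bits: 0x{flags & ~FLAG_COMPRESSED:02x}")
    return flags, record_count


def read_store_blocks(path: Union[str, os.PathLike]) -> Iterator[list[GenomeRecord]]:
    """Yield one list of records per block, in file order (streaming)."""
    with open(path, "rb") as fh:
        flags, record_count = read_store_header(fh)
        compressed = bool(flags & FLAG_COMPRESSED)
        seen = 0
        while True:
            head = fh.read(_BLOCK_HEAD.size)
            if not head:
                break
            if len(head) != _BLOCK_HEAD.size:
                raise StoreError("truncated block header")
            payload_size, raw_size, n_records = _BLOCK_HEAD.unpack(head)
            payload = fh.read(payload_size)
            if len(payload) != payload_size:
                raise StoreError("truncated block payload")
            raw = zlib.decompress(payload) if compressed else payload
            if len(raw) != raw_size:
                raise StoreError(
                    f"block raw size mismatch: header says {raw_size}, got {len(raw)}")
            block: list[GenomeRecord] = []
            pos = 0
            for _ in range(n_records):
                length, pos = decode_varint(raw, pos)
                if pos + length > len(raw):
                    raise StoreError(f"truncated record at block offset {pos}")
                block.append(decode_record(raw[pos:pos + length]))
                pos += length
            seen += n_records
            yield block
        if seen != record_count:
            raise StoreError(
                f"record count mismatch: header says {record_count}, found {seen}")


def read_store(path: Union[str, os.PathLike]) -> Iterator[GenomeRecord]:
    """Yield records in write order, streaming one block at a time."""
    for block in read_store_blocks(path):
        yield from block


# ---------------------------------------------------------------------------
# JSONL export

def export_jsonl(records: Iterable[GenomeRecord], path: Union[str, os.PathLike]) -> int:
    """Write one sorted-key JSON object per genome per line; returns line count."""
    count = 0
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for record in records:
            fh.write(json.dumps(asdict(record), sort_keys=True,
                               separators=(",", ":"), ensure_ascii=False))
            fh.write("\n")
            count += 1
    return count
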