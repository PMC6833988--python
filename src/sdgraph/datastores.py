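"""On-disk, randomly accessible read datastores.

A datastore packs read sequences (2 bits per base, qualities dropped) into a
single container file with a trailing offset index, so any read can be fetched
with one seek without loading the store into memory.  Reads are 1-based and
dense; in a paired store reads ``2i-1`` and ``2i`` are mates (r1/r2
interleaved).

Non-ACGT characters are stored as ``A`` and their positions recorded in an
exceptions table; :meth:`ReadDatastore.get_read_masked` returns them as ``N``
so k-mer based consumers skip windows that touch them.

Container layout (all integers little-endian)::

    magic   b"SDGDS\\x00"
    u16     format version (1)
    u8      store type: 1 = paired, 2 = long
    u64     read count
    u64     index offset (from file start)
    ...     packed read payloads, each padded to a whole byte
    @index: u64[count] payload offsets, u32[count] read lengths,
            u64 n_exceptions, u64[n] read ids, u32[n] positions

Rebuilding a store from identical inputs is byte-identical.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterator

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._binio import Reader, Writer, check_magic
from ._kmers import encode

MAGIC = b"SDGDS\x00"
VERSION = 1
TYPE_PAIRED = 1
TYPE_LONG = 2

PAIRED_EXT = ".prseq"
LONG_EXT = ".loseq"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _open_fastq(path) -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _iter_fastq(path) -> Iterator[str]:
    """Yield read sequences from a (possibly gzipped) FASTQ file."""
    record = 0
    with _open_fastq(path) as fh:
        try:
            for _title, seq, _qual in FastqGeneralIterator(fh):
                record += 1
                yield seq
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ {path!r} after record {record}: {exc}") from exc


def _pack(seq: str) -> tuple[bytes, int, list[int]]:
    """2-bit pack a read; returns (payload, length, non-ACGT positions)."""
    vals = encode(seq)
    exc = np.flatnonzero(vals > 3)
    if exc.size:
        vals = vals.copy()
        vals[exc] = 0
    pad = (-len(vals)) % 4
    if pad:
        vals = np.concatenate([vals, np.zeros(pad, dtype=np.uint8)])
    q = vals.reshape(-1, 4)
    payload = (q[:, 0] << 6) | (q[:, 1] << 4) | (q[:, 2] << 2) | q[:, 3]
    return payload.astype(np.uint8).tobytes(), len(seq), [int(p) for p in exc]


def _unpack(payload: bytes, length: int) -> str:
    b = np.frombuffer(payload, dtype=np.uint8)
    out = np.empty((len(b), 4), dtype=np.uint8)
    out[:, 0] = (b >> 6) & 3
    out[:, 1] = (b >> 4) & 3
    out[:, 2] = (b >> 2) & 3
    out[:, 3] = b & 3
    return _BASES[out.reshape(-1)[:length]].tobytes().decode("ascii")


class ReadDatastore:
    """Random-access reader over a datastore container file."""

    store_type: int

    def __init__(self, path):
        self.path = Path(path)
        self.bytes_read = 0  # payload bytes fetched by get_read, for instrumentation
        with open(self.path, "rb") as fh:
            r = Reader(fh)
            check_magic(r, MAGIC, "read datastore")
            version = r.u16()
            if version != VERSION:
                raise ValueError(f"unsupported datastore version {version}")
            self.store_type = r.u8()
            self.count = r.u64()
            index_offset = r.u64()
            fh.seek(index_offset)
            self._offsets = r.array(np.uint64)
            self._lengths = r.array(np.uint32)
            exc_ids = r.array(np.uint64)
            exc_pos = r.array(np.uint32)
        self._exceptions: dict[int, list[int]] = {}
        for rid, pos in zip(exc_ids.tolist(), exc_pos.tolist()):
            self._exceptions.setdefault(rid, []).append(pos)
        self._fh = open(self.path, "rb")

    def __len__(self) -> int:
        return self.count

    def _payload(self, read_id: int) -> tuple[bytes, int]:
        if not 1 <= read_id <= self.count:
            raise IndexError(f"read id {read_id} out of range 1..{self.count}")
        length = int(self._lengths[read_id - 1])
        nbytes = (length + 3) // 4
        self._fh.seek(int(self._offsets[read_id - 1]))
        payload = self._fh.read(nbytes)
        self.bytes_read += nbytes
        return payload, length

    def get_read(self, read_id: int) -> str:
        """The stored sequence of a read (non-ACGT input shows as ``A``)."""
        return _unpack(*self._payload(read_id))

    def get_read_masked(self, read_id: int) -> str:
        """Like :meth:`get_read` but flagged non-ACGT positions become ``N``."""
        seq = self.get_read(read_id)
        exc = self._exceptions.get(read_id)
        if not exc:
            return seq
        chars = list(seq)
        for p in exc:
            chars[p] = "N"
        return "".join(chars)

    def iter_reads(self, masked: bool = True) -> Iterator[str]:
        get = self.get_read_masked if masked else self.get_read
        for rid in range(1, self.count + 1):
            yield get(rid)

    def flagged_reads(self) -> dict[int, list[int]]:
        return {k: list(v) for k, v in self._exceptions.items()}

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


class PairedReadDatastore(ReadDatastore):
    """Interleaved paired-end store: reads 2i-1 and 2i are mates."""

    def __init__(self, path):
        super().__init__(path)
        if self.store_type != TYPE_PAIRED:
            raise ValueError(f"{self.path} is not a paired-read datastore")

    def mate(self, read_id: int) -> int:
        return read_id + 1 if read_id % 2 == 1 else read_id - 1


class LongReadDatastore(ReadDatastore):
    """Variable-length single-read store (long reads)."""

    def __init__(self, path):
        super().__init__(path)
        if self.store_type != TYPE_LONG:
            raise ValueError(f"{self.path} is not a long-read datastore")


def _write_store(path: Path, store_type: int, sequences: Iterator[str]) -> Path:
    offsets: list[int] = []
    lengths: list[int] = []
    exc_ids: list[int] = []
    exc_pos: list[int] = []
    header_size = len(MAGIC) + 2 + 1 + 8 + 8
    with open(path, "wb") as fh:
        w = Writer(fh)
        w.raw(MAGIC)
        w.u16(VERSION)
        w.u8(store_type)
        w.u64(0)  # read count, patched below
        w.u64(0)  # index offset, patched below
        pos = header_size
        count = 0
        for seq in sequences:
            payload, length, exc = _pack(seq)
            count += 1
            offsets.append(pos)
            lengths.append(length)
            for p in exc:
                exc_ids.append(count)
                exc_pos.append(p)
            fh.write(payload)
            pos += len(payload)
        index_offset = pos
        w.array(np.asarray(offsets, dtype=np.uint64))
        w.array(np.asarray(lengths, dtype=np.uint32))
        w.array(np.asarray(exc_ids, dtype=np.uint64))
        w.array(np.asarray(exc_pos, dtype=np.uint32))
        fh.seek(header_size - 16)
        w.u64(count)
        w.u64(index_offset)
    return path


def _interleave(r1_path, r2_path) -> Iterator[str]:
    it1, it2 = _iter_fastq(r1_path), _iter_fastq(r2_path)
    n = 0
    while True:
        s1 = next(it1, None)
        s2 = next(it2, None)
        if s1 is None and s2 is None:
            return
        if s1 is None or s2 is None:
            longer = "r2" if s1 is None else "r1"
            raise ValueError(
                f"unequal FASTQ record counts: {longer} still has records after pair {n}"
            )
        n += 1
        yield s1
        yield s2


def build_paired_datastore(fastq_r1, fastq_r2, prefix) -> Path:
    """Build a ``<prefix>.prseq`` paired store from two FASTQ files."""
    return _write_store(Path(str(prefix) + PAIRED_EXT), TYPE_PAIRED, _interleave(fastq_r1, fastq_r2))


def build_long_datastore(fastq, prefix) -> Path:
    """Build a ``<prefix>.loseq`` long-read store from one FASTQ file."""
    return _write_store(Path(str(prefix) + LONG_EXT), TYPE_LONG, _iter_fastq(fastq))


def open_datastore(path) -> ReadDatastore:
    """Open a datastore file as the appropriate typed reader."""
    probe = ReadDatastore(path)
    t = probe.store_type
    probe.close()
    if t == TYPE_PAIRED:
        return PairedReadDatastore(path)
    if t == TYPE_LONG:
        return LongReadDatastore(path)
    raise ValueError(f"unknown datastore type byte {t} in {path}")
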