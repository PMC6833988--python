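"""Little-endian binary container primitives shared by the on-disk formats.

All container files in this package (read datastores, k-mer counters,
workspaces) use the same primitives: fixed-width little-endian integers,
u64-length-prefixed UTF-8 strings, and u64-length-prefixed numpy arrays of a
declared dtype.  Writers emit fields in a fixed order, so rebuilding a
container from identical inputs is byte-identical.
"""

from __future__ import annotations

import struct
from typing import BinaryIO

import numpy as np


class Writer:
    def __init__(self, fh: BinaryIO):
        self.fh = fh

    def raw(self, data: bytes) -> None:
        self.fh.write(data)

    def u8(self, v: int) -> None:
        self.fh.write(struct.pack("<B", v))

    def u16(self, v: int) -> None:
        self.fh.write(struct.pack("<H", v))

    def u32(self, v: int) -> None:
        self.fh.write(struct.pack("<I", v))

    def u64(self, v: int) -> None:
        self.fh.write(struct.pack("<Q", v))

    def i64(self, v: int) -> None:
        self.fh.write(struct.pack("<q", v))

    def string(self, s: str) -> None:
        data = s.encode("utf-8")
        self.u64(len(data))
        self.fh.write(data)

    def array(self, arr: np.ndarray) -> None:
        arr = np.ascontiguousarray(arr)
        self.u64(arr.size)
        self.fh.write(arr.tobytes())


class Reader:
    def __init__(self, fh: BinaryIO):
        self.fh = fh

    def raw(self, n: int) -> bytes:
        data = self.fh.read(n)
        if len(data) != n:
            raise EOFError(f"truncated container: wanted {n} bytes, got {len(data)}")
        return data

    def u8(self) -> int:
        return struct.unpack("<B", self.raw(1))[0]

    def u16(self) -> int:
        return struct.unpack("<H", self.raw(2))[0]

    def u32(self) -> int:
        return struct.unpack("<I", self.raw(4))[0]

    def u64(self) -> int:
        return struct.unpack("<Q", self.raw(8))[0]

    def i64(self) -> int:
        return struct.unpack("<q", self.raw(8))[0]

    def string(self) -> str:
        n = self.u64()
        return self.raw(n).decode("utf-8")

    def array(self, dtype) -> np.ndarray:
        n = self.u64()
        dtype = np.dtype(dtype)
        return np.frombuffer(self.raw(n * dtype.itemsize), dtype=dtype).copy()


def check_magic(reader: Reader, magic: bytes, kind: str) -> None:
    got = reader.raw(len(magic))
    if got != magic:
        raise ValueError(f"not a {kind} container (bad magic {got!r})")
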