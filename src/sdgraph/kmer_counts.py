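"""Graph k-mer indexing and named count vectors (sect-style coverage).

A :class:`KmerCounter` indexes every canonical k-mer (k odd, <= 31) occurring
in the active node sequences of a graph, and holds named count vectors over
those indexed k-mers.  The graph's own occurrence count is always present
under the reserved name ``"sdg"``.  Further counts can be added from read
datastores or FASTQ files; read k-mers absent from the graph index are
ignored.  Counts saturate at 2**32 - 1 instead of overflowing.

Projecting a count over a node or path sequence gives the per-position
coverage vector used for content analyses (e.g. parental coverage of
haplotype nodes in a trio).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._binio import Reader, Writer, check_magic
from ._kmers import canonical_codes, iter_canonical_batches
from .datastores import ReadDatastore, _iter_fastq

MAGIC = b"SDGKC\x00"
VERSION = 1
GRAPH_COUNT_NAME = "sdg"
SATURATION = np.uint64(2**32 - 1)


def _check_k(k: int) -> None:
    if k > 31:
        raise ValueError(f"k={k} not supported; the counter index is limited to k <= 31")
    if k % 2 == 0 or k < 3:
        raise ValueError(f"k must be odd and >= 3, got {k}")


class KmerCounter:
    """Canonical k-mer index over a graph plus named count vectors."""

    def __init__(self, name: str, k: int, codes: np.ndarray, counts: dict[str, np.ndarray]):
        self.name = name
        self.k = k
        self._codes = codes  # sorted uint64 canonical codes
        self._counts = counts  # name -> uint64 vector, len == len(codes)

    # -- construction -------------------------------------------------------
    @classmethod
    def from_graph(cls, graph, name: str, k: int = 31) -> "KmerCounter":
        """Index all canonical k-mers of the graph's active nodes.

        The per-k-mer occurrence count across node sequences is stored under
        the reserved ``"sdg"`` count name.
        """
        _check_k(k)
        seqs = (graph.node_sequence(nid) for nid in graph.active_node_ids())
        batches = list(iter_canonical_batches(seqs, k))
        if batches:
            allc = np.concatenate(batches)
            codes, counts = np.unique(allc, return_counts=True)
        else:
            codes = np.empty(0, dtype=np.uint64)
            counts = np.empty(0, dtype=np.uint64)
        return cls(name, k, codes, {GRAPH_COUNT_NAME: counts.astype(np.uint64)})

    # -- queries ------------------------------------------------------------
    def __len__(self) -> int:
        return len(self._codes)

    def count_names(self) -> list[str]:
        return list(self._counts)

    def get_count(self, count_name: str) -> np.ndarray:
        if count_name not in self._counts:
            raise KeyError(f"no count named {count_name!r} in counter {self.name!r}")
        return self._counts[count_name]

    # -- adding counts ------------------------------------------------------
    def add_count(self, count_name: str, source) -> None:
        """Add a named count from a datastore, FASTQ path(s), or sequences.

        Every read k-mer whose canonical form is indexed increments its slot;
        all other k-mers are ignored.
        """
        if count_name in self._counts:
            raise ValueError(f"count {count_name!r} already exists in counter {self.name!r}")
        self._counts[count_name] = self._count_sequences(self._resolve(source))

    def _resolve(self, source) -> Iterable[str]:
        if isinstance(source, ReadDatastore):
            return source.iter_reads(masked=True)
        if isinstance(source, (str, Path)):
            return _iter_fastq(source)
        if isinstance(source, (list, tuple)) and source and isinstance(source[0], (str, Path)):
            # a list of FASTQ paths if they all exist on disk, else raw sequences
            try:
                are_paths = all(Path(p).exists() for p in source)
            except (OSError, ValueError):
                are_paths = False
            if are_paths:
                def chain():
                    for p in source:
                        yield from _iter_fastq(p)
                return chain()
            return [str(s) for s in source]
        return source

    def _slots(self, codes: np.ndarray) -> np.ndarray:
        """Index slot for each code, or -1 where the code is not indexed."""
        out = np.full(len(codes), -1, dtype=np.int64)
        n = len(self._codes)
        if n == 0 or len(codes) == 0:
            return out
        idx = np.searchsorted(self._codes, codes)
        clipped = np.minimum(idx, n - 1)
        hit = (idx < n) & (self._codes[clipped] == codes)
        out[hit] = idx[hit]
        return out

    def _count_sequences(self, sequences: Iterable[str]) -> np.ndarray:
        vec = np.zeros(len(self._codes), dtype=np.uint64)
        for batch in iter_canonical_batches(sequences, self.k):
            slots = self._slots(batch)
            slots = slots[slots >= 0]
            np.add.at(vec, slots, 1)
        return np.minimum(vec, SATURATION)

    # -- projection ---------------------------------------------------------
    def project(self, count_name: str, sequence: str) -> list[int]:
        """Coverage of ``sequence`` by a named count: one entry per k-mer.

        Position ``i`` holds the stored count of the canonical k-mer starting
        at ``i``; k-mers absent from the index (or windows touching non-ACGT
        characters) report 0.
        """
        vec = self.get_count(count_name)
        canon, _, valid = canonical_codes(sequence, self.k)
        out = np.zeros(len(canon), dtype=np.uint64)
        slots = self._slots(canon)
        hit = valid & (slots >= 0)
        out[hit] = vec[slots[hit]]
        return [int(v) for v in out]

    def count_zeros(self, count_name: str, sequence: str) -> int:
        """Number of zero entries in :meth:`project` — the 'fully covered'
        predicate is ``count_zeros(...) == 0``."""
        return self.project(count_name, sequence).count(0)

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> Path:
        path = Path(path)
        with open(path, "wb") as fh:
            w = Writer(fh)
            w.raw(MAGIC)
            w.u16(VERSION)
            w.string(self.name)
            w.u32(self.k)
            w.array(self._codes.astype(np.uint64))
            w.u64(len(self._counts))
            for cname in self._counts:
                w.string(cname)
                w.array(self._counts[cname].astype(np.uint64))
        return path

    @classmethod
    def load(cls, path) -> "KmerCounter":
        with open(path, "rb") as fh:
            r = Reader(fh)
            check_magic(r, MAGIC, "k-mer counter")
            version = r.u16()
            if version != VERSION:
                raise ValueError(f"unsupported counter version {version}")
            name = r.string()
            k = r.u32()
            codes = r.array(np.uint64)
            counts = {}
            for _ in range(r.u64()):
                cname = r.string()
                counts[cname] = r.array(np.uint64)
        return cls(name, k, codes, counts)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, KmerCounter)
            and self.name == other.name
            and self.k == other.k
            and np.array_equal(self._codes, other._codes)
            and self._counts.keys() == other._counts.keys()
            and all(np.array_equal(v, other._counts[k]) for k, v in self._counts.items())
        )
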