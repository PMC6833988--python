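"""The workspace: one base graph, alternative linkage, data and projections.

A :class:`WorkSpace` binds a single :class:`SequenceDistanceGraph`, any number
of :class:`DistanceGraph` link sets over its nodes, registered read datastores
(each with its mapper's state) and registered k-mer counters, plus a journal
of the operations applied.  It can be dumped to and loaded from a single
container file, decoupling expensive stages (datastore building, mapping,
counting) from downstream analysis.

Raw reads and k-mer counts stay in their own files and are referenced from
the workspace by relative path; a workspace whose referenced files are
missing still loads, with those handles detached (graph-only analyses keep
working; data queries on detached handles raise).

Container layout: magic ``b"SDGWS\\x00"``, u16 version, then the journal,
the base graph (tombstones preserved so ids are stable), the distance
graphs, the datastore registrations with their mappers' state, and the
counter references, all via the little-endian primitives in ``_binio``.
"""

from __future__ import annotations

import os
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np

from ._binio import Reader, Writer, check_magic
from .datastores import (
    TYPE_LONG,
    TYPE_PAIRED,
    LongReadDatastore,
    PairedReadDatastore,
)
from .graph_core import DistanceGraph, GraphError, SequenceDistanceGraph
from .kmer_counts import KmerCounter
from .mappers import LongReadMapper, PairedReadMapper, LongReadMapping, PairedReadMapping

MAGIC = b"SDGWS\x00"
VERSION = 1


class DatastoreHandle:
    """A datastore registered in a workspace, with its mapper."""

    def __init__(self, ws: "WorkSpace", name: str, path: Path, store_type: int):
        self.name = name
        self.path = Path(path)
        self.store_type = store_type
        self.store = None
        if self.path.exists():
            cls = PairedReadDatastore if store_type == TYPE_PAIRED else LongReadDatastore
            self.store = cls(self.path)
        if store_type == TYPE_PAIRED:
            self.mapper = PairedReadMapper(ws.sdg, self.store)
        else:
            self.mapper = LongReadMapper(ws.sdg, self.store)

    @property
    def detached(self) -> bool:
        return self.store is None

    def __repr__(self) -> str:
        kind = "paired" if self.store_type == TYPE_PAIRED else "long"
        state = "detached" if self.detached else f"{len(self.store)} reads"
        return f"<{kind} datastore {self.name!r}: {state}>"


class WorkSpace:
    """The in-memory status of a whole analysis; persistable to one file."""

    def __init__(self, path=None):
        self.sdg = SequenceDistanceGraph()
        self.sdg._ws = self
        self.distance_graphs: list[DistanceGraph] = []
        self.paired_reads_datastores: list[DatastoreHandle] = []
        self.long_reads_datastores: list[DatastoreHandle] = []
        self.kmer_counters: list[KmerCounter] = []
        self._counter_paths: dict[str, Optional[Path]] = {}
        self.journal: list[str] = []
        if path is not None:
            self._load(Path(path))

    # -- journal --------------------------------------------------------------
    def log(self, message: str) -> str:
        stamp = datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")
        entry = f"{stamp} {message}"
        self.journal.append(entry)
        return entry

    # -- datastores -----------------------------------------------------------
    def _register(self, path, expected_type: int, name: Optional[str]) -> DatastoreHandle:
        path = Path(path)
        for handle in self.all_datastores():
            if handle.path.resolve() == path.resolve():
                raise ValueError(f"datastore {path} is already registered")
        if path.exists():
            probe = PairedReadDatastore if expected_type == TYPE_PAIRED else LongReadDatastore
            probe(path).close()  # raises on wrong container type
        handle = DatastoreHandle(self, name or path.stem, path, expected_type)
        target = (
            self.paired_reads_datastores
            if expected_type == TYPE_PAIRED
            else self.long_reads_datastores
        )
        target.append(handle)
        kind = "paired" if expected_type == TYPE_PAIRED else "long"
        self.log(f"added {kind} reads datastore {handle.name!r} from {path}")
        return handle

    def add_paired_reads_datastore(self, path, name: Optional[str] = None) -> DatastoreHandle:
        return self._register(path, TYPE_PAIRED, name)

    def add_long_reads_datastore(self, path, name: Optional[str] = None) -> DatastoreHandle:
        return self._register(path, TYPE_LONG, name)

    def all_datastores(self) -> list[DatastoreHandle]:
        return [*self.paired_reads_datastores, *self.long_reads_datastores]

    # -- counters ---------------------------------------------------------------
    def create_kmer_counter(self, name: str, k: int = 31) -> KmerCounter:
        """Build a counter over the current base graph and register it."""
        if any(c.name == name for c in self.kmer_counters):
            raise ValueError(f"a k-mer counter named {name!r} is already registered")
        counter = KmerCounter.from_graph(self.sdg, name, k)
        self.kmer_counters.append(counter)
        self._counter_paths[name] = None
        self.log(f"created k-mer counter {name!r} at k={k} ({len(counter)} k-mers)")
        return counter

    def add_kmer_counter(self, path) -> KmerCounter:
        """Register a counter loaded from an existing ``.sdgkc`` file."""
        counter = KmerCounter.load(path)
        if any(c.name == counter.name for c in self.kmer_counters):
            raise ValueError(f"a k-mer counter named {counter.name!r} is already registered")
        self.kmer_counters.append(counter)
        self._counter_paths[counter.name] = Path(path)
        self.log(f"added k-mer counter {counter.name!r} from {path}")
        return counter

    def get_kmer_counter(self, name: str) -> KmerCounter:
        for c in self.kmer_counters:
            if c.name == name:
                return c
        raise KeyError(f"no k-mer counter named {name!r} in workspace")

    # -- distance graphs ----------------------------------------------------------
    def add_distance_graph(self, dg: DistanceGraph) -> DistanceGraph:
        if dg.sdg is not self.sdg:
            raise GraphError("distance graph is not over this workspace's base graph")
        self.distance_graphs.append(dg)
        self.log(f"added distance graph {dg.name!r} ({len(dg.all_links())} links)")
        return dg

    def get_distance_graph(self, name: str) -> DistanceGraph:
        for dg in self.distance_graphs:
            if dg.name == name:
                return dg
        raise KeyError(f"no distance graph named {name!r} in workspace")

    # -- status ---------------------------------------------------------------
    def status(self) -> str:
        lines = [
            f"graph: {self.sdg.node_count()} nodes, {len(self.sdg.all_links())} links",
            f"distance graphs: {len(self.distance_graphs)}"
            + ("".join(f"\n  - {dg.name}: {len(dg.all_links())} links" for dg in self.distance_graphs)),
            f"datastores: {len(self.all_datastores())}"
            + ("".join(f"\n  - {h!r}" for h in self.all_datastores())),
            f"k-mer counters: {len(self.kmer_counters)}"
            + ("".join(f"\n  - {c.name} (k={c.k}, {len(c)} k-mers, counts: {', '.join(c.count_names())})" for c in self.kmer_counters)),
            f"journal: {len(self.journal)} entries",
        ]
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------------
    def save(self, path) -> Path:
        path = Path(path)
        ws_dir = path.resolve().parent
        with open(path, "wb") as fh:
            w = Writer(fh)
            w.raw(MAGIC)
            w.u16(VERSION)
            # journal
            w.u64(len(self.journal))
            for entry in self.journal:
                w.string(entry)
            # base graph (tombstones kept: ids are stable)
            max_id = len(self.sdg._sequences) - 1
            w.u64(max_id)
            for nid in range(1, max_id + 1):
                seq = self.sdg._sequences[nid]
                w.u8(1 if seq is not None else 0)
                w.string(seq or "")
            self._write_links(w, self.sdg)
            # distance graphs
            w.u64(len(self.distance_graphs))
            for dg in self.distance_graphs:
                w.string(dg.name)
                self._write_links(w, dg)
            # datastores + mapper state
            w.u64(len(self.paired_reads_datastores))
            for h in self.paired_reads_datastores:
                w.string(h.name)
                w.string(os.path.relpath(h.path.resolve(), ws_dir))
                w.u32(h.mapper.k)
                w.u64(len(h.mapper.mappings))
                for m in h.mapper.mappings:
                    w.u64(m.read_id)
                    w.i64(m.node)
                    w.i64(m.first_offset)
                    w.i64(m.last_offset)
                    w.i64(m.hit_count)
            w.u64(len(self.long_reads_datastores))
            for h in self.long_reads_datastores:
                w.string(h.name)
                w.string(os.path.relpath(h.path.resolve(), ws_dir))
                w.u32(h.mapper.k)
                w.u32(h.mapper.min_hits)
                w.u32(h.mapper.max_gap)
                w.u64(len(h.mapper.mappings))
                for m in h.mapper.mappings:
                    w.u64(m.read_id)
                    w.i64(m.node)
                    w.i64(m.read_start)
                    w.i64(m.read_end)
                    w.i64(m.node_start)
                    w.i64(m.node_end)
                    w.i64(m.score)
            # counters: written next to the workspace, referenced by path
            w.u64(len(self.kmer_counters))
            for c in self.kmer_counters:
                cpath = self._counter_paths.get(c.name)
                if cpath is None:
                    cpath = path.with_name(f"{path.stem}.{c.name}.sdgkc")
                    self._counter_paths[c.name] = cpath
                c.save(cpath)
                w.string(os.path.relpath(Path(cpath).resolve(), ws_dir))
        return path

    @staticmethod
    def _write_links(w: Writer, graph) -> None:
        links = graph.all_links()
        w.u64(len(links))
        for ln in links:
            w.i64(ln.end_a)
            w.i64(ln.end_b)
            w.i64(ln.distance)
            if ln.support is None:
                w.u8(0)
                w.u64(0)
            else:
                w.u8(1)
                w.u64(ln.support)

    @staticmethod
    def _read_links(r: Reader, graph) -> None:
        for _ in range(r.u64()):
            ea, eb, d = r.i64(), r.i64(), r.i64()
            has_support = r.u8()
            support = r.u64()
            graph.add_link(ea, eb, d, support if has_support else None)

    def _load(self, path: Path) -> None:
        ws_dir = path.resolve().parent
        with open(path, "rb") as fh:
            r = Reader(fh)
            check_magic(r, MAGIC, "workspace")
            version = r.u16()
            if version != VERSION:
                raise ValueError(f"unsupported workspace version {version}")
            self.journal = [r.string() for _ in range(r.u64())]
            max_id = r.u64()
            for nid in range(1, max_id + 1):
                active = r.u8()
                seq = r.string()
                if active:
                    self.sdg._add_node_with_id(nid, seq)
                else:
                    while len(self.sdg._sequences) <= nid:
                        self.sdg._sequences.append(None)
            self._read_links(r, self.sdg)
            for _ in range(r.u64()):
                dg = DistanceGraph(self.sdg, name=r.string())
                self._read_links(r, dg)
                self.distance_graphs.append(dg)
            for _ in range(r.u64()):
                name = r.string()
                rel = r.string()
                handle = DatastoreHandle(self, name, ws_dir / rel, TYPE_PAIRED)
                handle.mapper.k = r.u32()
                mappings = []
                for _ in range(r.u64()):
                    mappings.append(
                        PairedReadMapping(r.u64(), r.i64(), r.i64(), r.i64(), r.i64())
                    )
                handle.mapper.mappings = mappings
                for m in mappings:
                    handle.mapper._node_reads.setdefault(abs(m.node), []).append(m.read_id)
                self.paired_reads_datastores.append(handle)
            for _ in range(r.u64()):
                name = r.string()
                rel = r.string()
                handle = DatastoreHandle(self, name, ws_dir / rel, TYPE_LONG)
                handle.mapper.k = r.u32()
                handle.mapper.min_hits = r.u32()
                handle.mapper.max_gap = r.u32()
                mappings = []
                for _ in range(r.u64()):
                    mappings.append(
                        LongReadMapping(
                            r.u64(), r.i64(), r.i64(), r.i64(), r.i64(), r.i64(), r.i64()
                        )
                    )
                handle.mapper.mappings = mappings
                for m in mappings:
                    lst = handle.mapper._node_reads.setdefault(abs(m.node), [])
                    if not lst or lst[-1] != m.read_id:
                        lst.append(m.read_id)
                self.long_reads_datastores.append(handle)
            for _ in range(r.u64()):
                rel = r.string()
                cpath = ws_dir / rel
                if cpath.exists():
                    counter = KmerCounter.load(cpath)
                    self.kmer_counters.append(counter)
                    self._counter_paths[counter.name] = cpath
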