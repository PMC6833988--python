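"""Read-to-graph mappers.

Paired (short) reads are mapped through a *unique* k-mer index: only k-mers
occurring exactly once across all node sequences anchor reads, and a read is
mapped only when all its anchors fall on a single node — reads whose anchors
span several nodes are left unmapped.

Long reads are mapped through a short non-unique k-mer index (k=15 by
default, 7..15 allowed).  Every index hit is kept, hits are grouped per
oriented node and chained when colinear in read and node coordinates; all
chains with enough hits are reported, and filtering is left to later stages
(e.g. the linkage maker's span/identity thresholds).

Node coordinates in long-read mappings are in the *oriented* node (the node
as traversed by the read), so ``node_start < node_end`` always holds and a
mapping near ``node_end == len(node)`` touches the node's outgoing end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kmers import canonical_codes
from .graph_core import GraphError


@dataclass(frozen=True)
class PairedReadMapping:
    read_id: int
    node: int  # signed: orientation of the read on the node
    first_offset: int  # first matched read offset
    last_offset: int  # last matched read offset (k-mer start)
    hit_count: int


@dataclass(frozen=True)
class LongReadMapping:
    read_id: int
    node: int  # signed
    read_start: int
    read_end: int
    node_start: int  # oriented node coordinates
    node_end: int
    score: int  # matched k-mer count


def _graph_kmer_arrays(graph, k: int):
    """(codes, node, pos, fwd_is_canon) over all active node sequences."""
    codes, nodes, poss, fwds = [], [], [], []
    for nid in graph.active_node_ids():
        seq = graph.node_sequence(nid)
        if len(seq) < k:
            continue
        canon, fwd, valid = canonical_codes(seq, k)
        codes.append(canon[valid])
        poss.append(np.flatnonzero(valid).astype(np.int64))
        nodes.append(np.full(int(valid.sum()), nid, dtype=np.int64))
        fwds.append(fwd[valid])
    if not codes:
        e = np.empty(0, dtype=np.uint64)
        ei = np.empty(0, dtype=np.int64)
        return e, ei, ei.copy(), np.empty(0, dtype=bool)
    return (
        np.concatenate(codes),
        np.concatenate(nodes),
        np.concatenate(poss),
        np.concatenate(fwds),
    )


class UniqueKmerIndex:
    """Canonical k-mers occurring exactly once across all node sequences."""

    def __init__(self, graph, k: int = 31):
        if k % 2 == 0 or not 3 <= k <= 31:
            raise ValueError(f"unique index k must be odd and in 3..31, got {k}")
        self.k = k
        codes, nodes, poss, fwds = _graph_kmer_arrays(graph, k)
        order = np.argsort(codes, kind="stable")
        codes, nodes, poss, fwds = codes[order], nodes[order], poss[order], fwds[order]
        if len(codes):
            boundary = np.concatenate([[True], codes[1:] != codes[:-1], [True]])
            starts = np.flatnonzero(boundary[:-1])
            ends = np.flatnonzero(boundary[1:]) + 1
            single = (ends - starts) == 1
            keep = starts[single]
        else:
            keep = np.empty(0, dtype=np.int64)
        self.codes = codes[keep]
        self.node = nodes[keep]
        self.pos = poss[keep]
        self.fwd = fwds[keep]

    def __len__(self) -> int:
        return len(self.codes)

    def lookup(self, canon: np.ndarray) -> np.ndarray:
        """Index row per query code, or -1 where not uniquely indexed."""
        out = np.full(len(canon), -1, dtype=np.int64)
        if len(self.codes) == 0 or len(canon) == 0:
            return out
        idx = np.searchsorted(self.codes, canon)
        clipped = np.minimum(idx, len(self.codes) - 1)
        hit = (idx < len(self.codes)) & (self.codes[clipped] == canon)
        out[hit] = idx[hit]
        return out


class PairedReadMapper:
    """Maps each short read to at most one node via unique k-mer anchors."""

    def __init__(self, graph, datastore, k: int = 31):
        self.graph = graph
        self.datastore = datastore
        self.k = k
        self.mappings: list[PairedReadMapping] = []
        self._node_reads: dict[int, list[int]] = {}

    def map_reads(self) -> list[PairedReadMapping]:
        index = UniqueKmerIndex(self.graph, self.k)
        mappings = []
        for rid in range(1, len(self.datastore) + 1):
            m = self._map_one(index, rid, self.datastore.get_read_masked(rid))
            if m is not None:
                mappings.append(m)
        mappings.sort(key=lambda m: (m.read_id, abs(m.node), m.node < 0, m.first_offset))
        self.mappings = mappings
        self._node_reads = {}
        for m in mappings:
            self._node_reads.setdefault(abs(m.node), []).append(m.read_id)
        return mappings

    def _map_one(self, index: UniqueKmerIndex, rid: int, seq: str):
        if len(seq) < index.k:
            return None
        canon, fwd_r, valid = canonical_codes(seq, index.k)
        rows = index.lookup(canon)
        hit = valid & (rows >= 0)
        if not hit.any():
            return None
        rows = rows[hit]
        offsets = np.flatnonzero(hit)
        nodes = index.node[rows]
        if len(np.unique(nodes)) != 1:
            return None  # anchors on multiple nodes: leave unmapped
        same = fwd_r[hit] == index.fwd[rows]
        n_fwd = int(same.sum())
        sign = 1 if n_fwd * 2 >= len(rows) else -1
        return PairedReadMapping(
            read_id=rid,
            node=sign * int(nodes[0]),
            first_offset=int(offsets[0]),
            last_offset=int(offsets[-1]),
            hit_count=len(rows),
        )

    def reads_on_node(self, node_id: int) -> list[int]:
        if not self.graph.is_active(abs(node_id)):
            raise GraphError(f"node {abs(node_id)} is deleted or unknown")
        return list(self._node_reads.get(abs(node_id), ()))


class LongReadMapper:
    """Multi-mapping long-read mapper over a short non-unique k-mer index.

    Tunables (plain attributes, read at :meth:`map_reads` time):

    * ``k`` — anchor k-mer size, odd, 7..15 (default 15);
    * ``min_hits`` — minimum anchors per reported chain (default 5);
    * ``max_gap`` — maximum read-coordinate gap inside a chain, bp (500);
    * ``diag_band`` — diagonal tolerance when grouping colinear anchors (500);
    * ``delta_band`` — fractional disagreement allowed between read and node
      coordinate deltas of consecutive anchors (0.2).
    """

    def __init__(self, graph, datastore, k: int = 15):
        self.graph = graph
        self.datastore = datastore
        self.k = k
        self.min_hits = 5
        self.max_gap = 500
        self.diag_band = 500
        self.delta_band = 0.2
        self.mappings: list[LongReadMapping] = []
        self._node_reads: dict[int, list[int]] = {}

    # -- index ---------------------------------------------------------------
    def _build_index(self):
        if self.k % 2 == 0 or not 7 <= self.k <= 15:
            raise ValueError(f"long-read index k must be odd and in 7..15, got {self.k}")
        codes, nodes, poss, fwds = _graph_kmer_arrays(self.graph, self.k)
        order = np.lexsort((poss, nodes, codes))
        self._codes = codes[order]
        self._node = nodes[order]
        self._pos = poss[order]
        self._fwd = fwds[order]
        nid = self.graph.active_node_ids()
        size = (max(nid) + 1) if nid else 1
        self._nlen = np.zeros(size, dtype=np.int64)
        for n in nid:
            self._nlen[n] = self.graph.node_length(n)

    # -- mapping ---------------------------------------------------------------
    def map_reads(self) -> list[LongReadMapping]:
        self._build_index()
        mappings: list[LongReadMapping] = []
        for rid in range(1, len(self.datastore) + 1):
            mappings.extend(self._map_one(rid, self.datastore.get_read_masked(rid)))
        mappings.sort(key=lambda m: (m.read_id, abs(m.node), m.node < 0, m.read_start))
        self.mappings = mappings
        self._node_reads = {}
        for m in mappings:
            self._node_reads.setdefault(abs(m.node), [])
            if not self._node_reads[abs(m.node)] or self._node_reads[abs(m.node)][-1] != m.read_id:
                self._node_reads[abs(m.node)].append(m.read_id)
        return mappings

    def _map_one(self, rid: int, seq: str) -> list[LongReadMapping]:
        k = self.k
        if len(seq) < k:
            return []
        canon, fwd_r, valid = canonical_codes(seq, k)
        qpos = np.flatnonzero(valid)
        c = canon[qpos]
        fr = fwd_r[qpos]
        lo = np.searchsorted(self._codes, c, side="left")
        hi = np.searchsorted(self._codes, c, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            return []
        rep = np.repeat(np.arange(len(c)), counts)
        offs = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
        rows = np.repeat(lo, counts) + offs
        rp = qpos[rep]
        node = self._node[rows]
        npos = self._pos[rows]
        rel_fwd = fr[rep] == self._fwd[rows]
        npos_o = np.where(rel_fwd, npos, self._nlen[node] - k - npos)
        signed = np.where(rel_fwd, node, -node)
        diag = rp - npos_o
        order = np.lexsort((rp, diag, signed))
        signed, rp, npos_o, diag = signed[order], rp[order], npos_o[order], diag[order]

        out: list[LongReadMapping] = []
        i = 0
        n = len(signed)
        while i < n:
            j = i
            while (
                j + 1 < n
                and signed[j + 1] == signed[i]
                and diag[j + 1] - diag[j] <= self.diag_band
            ):
                j += 1
            self._chain_group(out, rid, int(signed[i]), rp[i : j + 1], npos_o[i : j + 1])
            i = j + 1
        return out

    def _chain_group(self, out, rid: int, signed: int, rp: np.ndarray, npo: np.ndarray) -> None:
        order = np.lexsort((npo, rp))
        rp, npo = rp[order], npo[order]
        chain_r: list[int] = []
        chain_n: list[int] = []

        def flush():
            if len(chain_r) >= self.min_hits:
                out.append(
                    LongReadMapping(
                        read_id=rid,
                        node=signed,
                        read_start=int(chain_r[0]),
                        read_end=int(chain_r[-1]) + self.k,
                        node_start=int(chain_n[0]),
                        node_end=int(chain_n[-1]) + self.k,
                        score=len(chain_r),
                    )
                )
            chain_r.clear()
            chain_n.clear()

        for r, p in zip(rp.tolist(), npo.tolist()):
            if not chain_r:
                chain_r.append(r)
                chain_n.append(p)
                continue
            dr = r - chain_r[-1]
            dn = p - chain_n[-1]
            if dn < 0:
                continue  # non-monotone anchor: noise
            if dr > self.max_gap:
                flush()
                chain_r.append(r)
                chain_n.append(p)
                continue
            if abs(dr - dn) > max(10, self.delta_band * max(dr, dn)):
                continue  # deltas disagree beyond the band: noise
            chain_r.append(r)
            chain_n.append(p)
        flush()

    def reads_on_node(self, node_id: int) -> list[int]:
        if not self.graph.is_active(abs(node_id)):
            raise GraphError(f"node {abs(node_id)} is deleted or unknown")
        return list(self._node_reads.get(abs(node_id), ()))
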