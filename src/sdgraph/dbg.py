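"""Compacted de Bruijn graph construction from a paired-read datastore.

Canonical k-mers (k odd, 15..63 for assembly; the counting primitive accepts
any odd k <= 63) are counted across the reads, k-mers below ``min_coverage``
are discarded, and the survivors are compacted into unitigs: maximal paths
whose internal junctions have a single extension on both sides.  Unitigs
become the nodes of a new sequence graph whose links all carry the dBG
overlap distance -(k-1).  No tip clipping or bubble popping is performed:
heterozygous bubbles are data, not noise, for downstream trio analyses.

The resulting graph is wrapped in a workspace carrying a k=31 counter with
the graph's own k-mer count and the datastore's read count pre-added.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from ._dna import canonical_kmer, reverse_complement
from ._kmers import (
    decode_code,
    decode_many_2word,
    iter_canonical_batches,
    iter_canonical_batches_2word,
)
from .datastores import ReadDatastore


@dataclass
class DbgParams:
    """Assembly parameters: odd k in 15..63, and a minimum k-mer coverage."""

    k: int = 63
    min_coverage: int = 2

    def validate(self) -> None:
        if self.k % 2 == 0:
            raise ValueError(f"k must be odd (canonical k-mers), got {self.k}")
        if not 15 <= self.k <= 63:
            raise ValueError(f"assembly k must be in 15..63, got {self.k}")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")


def _source_sequences(source) -> Iterable[str]:
    if isinstance(source, ReadDatastore):
        return source.iter_reads(masked=True)
    return source


def count_canonical_kmers(source, k: int, min_coverage: int = 1) -> dict[str, int]:
    """Count canonical k-mers over a datastore or an iterable of sequences.

    Counts are summed over both strands; k-mers seen fewer than
    ``min_coverage`` times are dropped.  k must be odd and <= 63; it is an
    error if no read contributes a single k-mer.
    """
    if k % 2 == 0:
        raise ValueError(f"k must be odd (canonical k-mers), got {k}")
    if not 3 <= k <= 63:
        raise ValueError(f"k must be in 3..63, got {k}")
    seqs = _source_sequences(source)
    if k <= 31:
        batches = list(iter_canonical_batches(seqs, k))
        if not batches or sum(len(b) for b in batches) == 0:
            raise ValueError(f"no k-mer of length {k} found in any read")
        codes, counts = np.unique(np.concatenate(batches), return_counts=True)
        keep = counts >= min_coverage
        return {
            decode_code(c, k): int(n)
            for c, n in zip(codes[keep].tolist(), counts[keep].tolist())
        }
    pairs = list(iter_canonical_batches_2word(seqs, k))
    if not pairs or sum(len(h) for h, _ in pairs) == 0:
        raise ValueError(f"no k-mer of length {k} found in any read")
    stacked = np.stack(
        [np.concatenate([h for h, _ in pairs]), np.concatenate([l for _, l in pairs])],
        axis=1,
    )
    uniq, counts = np.unique(stacked, axis=0, return_counts=True)
    keep = counts >= min_coverage
    uniq, counts = uniq[keep], counts[keep]
    kmers = decode_many_2word(uniq[:, 0], uniq[:, 1], k)
    return {km: int(n) for km, n in zip(kmers, counts.tolist())}


def compact_unitigs(kmers: set[str], k: int) -> list[str]:
    """Compact a canonical k-mer set into maximal unitig sequences.

    Each input k-mer occurs in exactly one unitig.  Unitig sequences are
    stored as the lexicographic minimum of the sequence and its reverse
    complement.  Isolated cycles (e.g. a circular genome) yield a single
    unitig whose first k-1 and last k-1 bases repeat.
    """

    def exts(km: str, forward: bool) -> list[str]:
        if forward:
            core = km[1:]
            return [core + b for b in "ACGT" if canonical_kmer(core + b) in kmers]
        core = km[:-1]
        return [b + core for b in "ACGT" if canonical_kmer(b + core) in kmers]

    used: set[str] = set()
    unitigs: list[str] = []
    for start in sorted(kmers):
        if start in used:
            continue
        walk = [start]
        walk_set = {start}
        cur = start
        while True:  # forward
            fs = exts(cur, True)
            if len(fs) != 1:
                break
            nxt = fs[0]
            if len(exts(nxt, False)) != 1:
                break
            cn = canonical_kmer(nxt)
            if cn in used or cn in walk_set:
                break
            walk.append(nxt)
            walk_set.add(cn)
            cur = nxt
        back: list[str] = []
        cur = start
        while True:  # backward
            ps = exts(cur, False)
            if len(ps) != 1:
                break
            prv = ps[0]
            if len(exts(prv, True)) != 1:
                break
            cp = canonical_kmer(prv)
            if cp in used or cp in walk_set:
                break
            back.append(prv)
            walk_set.add(cp)
            cur = prv
        walk = back[::-1] + walk
        used |= walk_set
        seq = walk[0] + "".join(w[-1] for w in walk[1:])
        rc = reverse_complement(seq)
        unitigs.append(min(seq, rc))
    return unitigs


def graph_from_unitigs(unitigs: list[str], kmers: set[str], k: int):
    """Build a sequence graph with one node per unitig and -(k-1) links."""
    from .graph_core import SequenceDistanceGraph

    g = SequenceDistanceGraph()
    entry: dict[str, int] = {}
    for seq in unitigs:
        nid = g.add_node(seq)
        entry[seq[:k]] = nid
        entry[reverse_complement(seq)[:k]] = -nid
    for nid, seq in enumerate(unitigs, start=1):
        for signed, oriented in ((nid, seq), (-nid, reverse_complement(seq))):
            last = oriented[-k:]
            core = last[1:]
            for b in "ACGT":
                nxt = core + b
                if canonical_kmer(nxt) in kmers and nxt in entry:
                    g.add_link(-signed, entry[nxt], -(k - 1))
    return g


def build_dbg(
    datastore,
    params: DbgParams | None = None,
    counter_name: str = "main",
    counter_k: int = 31,
    count_name: str = "PE",
):
    """Assemble a datastore into a workspace with a compacted dBG base graph.

    The returned workspace has the datastore registered and a k-mer counter
    (k=31 by default) with the graph count plus the reads' count under
    ``count_name``.
    """
    from .workspace import WorkSpace

    params = params or DbgParams()
    params.validate()
    if isinstance(datastore, ReadDatastore) and len(datastore) == 0:
        raise ValueError("datastore is empty; nothing to assemble")
    counts = count_canonical_kmers(datastore, params.k, params.min_coverage)
    if not counts:
        raise ValueError(
            f"no k-mer survived min_coverage={params.min_coverage} at k={params.k}"
        )
    kmers = set(counts)
    unitigs = compact_unitigs(kmers, params.k)
    graph = graph_from_unitigs(unitigs, kmers, params.k)

    ws = WorkSpace()
    ws.sdg._sequences = graph._sequences
    ws.sdg._links = graph._links
    ws.sdg._link_keys = graph._link_keys
    ws.log(
        f"built dBG at k={params.k}, min_coverage={params.min_coverage}: "
        f"{ws.sdg.node_count()} unitigs, {len(ws.sdg.all_links())} links"
    )
    if isinstance(datastore, ReadDatastore):
        ws.add_paired_reads_datastore(datastore.path)
    counter = ws.create_kmer_counter(counter_name, counter_k)
    counter.add_count(count_name, datastore)
    ws.log(f"added read k-mer count {count_name!r} to counter {counter_name!r}")
    return ws
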