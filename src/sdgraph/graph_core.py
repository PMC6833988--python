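"""Sequence distance graph data model.

Nodes hold DNA sequences in a single stored orientation.  Every node ``n``
has two ends: ``-n`` is the end reached when traversing the stored sequence
forward (the tail) and ``+n`` is the head.  Links join node ends and carry a
signed distance in bp: negative distances are overlaps between the adjacent
sequences, positive distances are gaps of unknown sequence, zero means the
sequences abut.

Traversal convention (which the whole framework builds on):

* the *next* neighbours of the signed view ``s`` are the links incident to
  end ``-s``; the neighbour's view id is the link's other end verbatim;
* the *previous* neighbours of ``s`` are the links incident to end ``s``;
  the neighbour's view id is the negation of the link's other end.

So ``add_link(-a, b, d)`` states "a forward, then b forward, at distance d".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from ._dna import normalize_node_sequence, reverse_complement


class GraphError(ValueError):
    """Raised for invalid graph operations (bad ids, bad links, bad paths)."""


@dataclass(frozen=True)
class Link:
    """A symmetric link between two signed node ends.

    ``(a, b, d)`` and ``(b, a, d)`` denote the same link.  ``support`` is an
    optional provenance tag (e.g. the id of the read that implied the link in
    a multi-linkage graph); links differing only in support are distinct.
    """

    end_a: int
    end_b: int
    distance: int
    support: Optional[int] = None

    def key(self) -> tuple:
        a, b = sorted((self.end_a, self.end_b))
        return (a, b, self.distance, self.support)

    def other_end(self, end: int) -> int:
        if end == self.end_a:
            return self.end_b
        if end == self.end_b:
            return self.end_a
        raise GraphError(f"end {end} is not part of link {self}")


class LinkView:
    """A link as seen from one node: a distance plus the neighbour view."""

    __slots__ = ("_distance", "_node", "_support")

    def __init__(self, distance: int, node: "NodeView", support: Optional[int] = None):
        self._distance = distance
        self._node = node
        self._support = support

    def distance(self) -> int:
        return self._distance

    def node(self) -> "NodeView":
        return self._node

    def support(self) -> Optional[int]:
        return self._support

    def __repr__(self) -> str:
        return f"<LinkView: {self._distance}bp to Node {self._node.node_id()}>"


class NodeView:
    """A signed handle on a node of a (distance) graph.

    The sign encodes orientation: view ``-n`` exposes the reverse complement
    of node ``n``'s stored sequence, and its neighbours are mirrored
    accordingly.
    """

    __slots__ = ("_graph", "_id")

    def __init__(self, graph: "_LinkHolder", node_id: int):
        self._graph = graph
        self._id = node_id

    # -- identity ---------------------------------------------------------
    def node_id(self) -> int:
        return self._id

    def graph(self) -> "_LinkHolder":
        return self._graph

    def rc(self) -> "NodeView":
        return NodeView(self._graph, -self._id)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, NodeView)
            and other._id == self._id
            and other._graph is self._graph
        )

    def __hash__(self) -> int:
        return hash((id(self._graph), self._id))

    def __repr__(self) -> str:
        return f"<NodeView: Node {self._id} in {self._graph.name}>"

    # -- sequence ---------------------------------------------------------
    def size(self) -> int:
        return self._graph.node_length(abs(self._id))

    def sequence(self) -> str:
        return self._graph.node_sequence(self._id)

    # -- topology ---------------------------------------------------------
    def next(self) -> list[LinkView]:
        """Links leaving this view's far end, in (distance, node) order."""
        out = []
        for ln in self._graph.links_on_end(-self._id):
            out.append(LinkView(ln.distance, NodeView(self._graph, ln.other_end(-self._id)), ln.support))
        return _sorted_linkviews(out)

    def prev(self) -> list[LinkView]:
        """Links arriving at this view's near end, in (distance, node) order."""
        out = []
        for ln in self._graph.links_on_end(self._id):
            out.append(LinkView(ln.distance, NodeView(self._graph, -ln.other_end(self._id)), ln.support))
        return _sorted_linkviews(out)

    def _end_set(self, end: int) -> frozenset[int]:
        # other-ends of links on `end`, self-links excluded
        return frozenset(
            ln.other_end(end)
            for ln in self._graph.links_on_end(end)
            if abs(ln.other_end(end)) != abs(self._id)
        )

    def parallels(self) -> list["NodeView"]:
        """Other oriented nodes sharing exactly this view's prev and next ends.

        These are the opposite sides of simple bubbles (e.g. the two
        haplotypes of a heterozygous locus in a diploid assembly).  Views with
        an empty side never have parallels.
        """
        my_next = self._end_set(-self._id)
        my_prev = self._end_set(self._id)
        if not my_next or not my_prev:
            return []
        candidates: set[int] = set()
        for x in my_next:
            for ln in self._graph.links_on_end(x):
                t = -ln.other_end(x)
                if abs(t) != abs(self._id):
                    candidates.add(t)
        result = []
        for t in sorted(candidates, key=lambda v: (abs(v), -v)):
            tv = NodeView(self._graph, t)
            if tv._end_set(-t) == my_next and tv._end_set(t) == my_prev:
                result.append(tv)
        return result

    # -- projected data ---------------------------------------------------
    def kmer_coverage(self, counter_name: str, count_name: str) -> list[int]:
        """Per-position k-mer counts of this view's oriented sequence.

        Requires the graph to belong to a workspace carrying the named
        counter.  Position ``i`` holds the count of the canonical k-mer
        starting at ``i``; the reverse view returns the reversed vector.
        """
        ws = self._graph.workspace
        if ws is None:
            raise GraphError("graph is not attached to a workspace with k-mer counters")
        counter = ws.get_kmer_counter(counter_name)
        return counter.project(count_name, self.sequence())

    def mapped_reads(self) -> list[tuple[str, int]]:
        """(datastore name, read id) pairs with >= 1 mapping on this node."""
        ws = self._graph.workspace
        if ws is None:
            raise GraphError("graph is not attached to a workspace with datastores")
        if not self._graph.is_active(abs(self._id)):
            raise GraphError(f"node {abs(self._id)} is deleted or unknown")
        out: list[tuple[str, int]] = []
        for handle in ws.all_datastores():
            for rid in handle.mapper.reads_on_node(abs(self._id)):
                out.append((handle.name, rid))
        return out


def _sorted_linkviews(views: list[LinkView]) -> list[LinkView]:
    return sorted(
        views,
        key=lambda lv: (lv.distance(), abs(lv.node().node_id()), -lv.node().node_id()),
    )


class _LinkHolder:
    """Shared link storage and navigation for sequence and distance graphs."""

    name = "graph"

    def __init__(self):
        self._links: dict[int, list[Link]] = {}
        self._link_keys: set[tuple] = set()

    # node data accessors are provided by subclasses:
    def node_length(self, node_id: int) -> int:  # pragma: no cover - abstract
        raise NotImplementedError

    def node_sequence(self, signed_id: int) -> str:  # pragma: no cover - abstract
        raise NotImplementedError

    def is_active(self, node_id: int) -> bool:  # pragma: no cover - abstract
        raise NotImplementedError

    @property
    def workspace(self):  # pragma: no cover - abstract
        return None

    # -- links ------------------------------------------------------------
    def add_link(self, end_a: int, end_b: int, distance: int, support: Optional[int] = None) -> None:
        """Register a symmetric link between two signed node ends.

        Adding the same (ends, distance, support) twice is a no-op.  Negative
        distances must be shorter than both node sequences.
        """
        for end in (end_a, end_b):
            if end == 0 or not self.is_active(abs(end)):
                raise GraphError(f"unknown or inactive node for end {end}")
        if distance < 0:
            for end in (end_a, end_b):
                if -distance >= self.node_length(abs(end)):
                    raise GraphError(
                        f"overlap of {-distance}bp is not shorter than node {abs(end)} "
                        f"({self.node_length(abs(end))}bp)"
                    )
        link = Link(end_a, end_b, distance, support)
        key = link.key()
        if key in self._link_keys:
            return
        self._link_keys.add(key)
        self._links.setdefault(end_a, []).append(link)
        if end_b != end_a:
            self._links.setdefault(end_b, []).append(link)

    def links_on_end(self, end: int) -> list[Link]:
        return list(self._links.get(end, ()))

    def links_between(self, end_a: int, end_b: int) -> list[Link]:
        return [ln for ln in self._links.get(end_a, ()) if ln.other_end(end_a) == end_b]

    def all_links(self) -> list[Link]:
        """Each stored link exactly once."""
        seen = set()
        out = []
        for links in self._links.values():
            for ln in links:
                k = ln.key()
                if k not in seen:
                    seen.add(k)
                    out.append(ln)
        out.sort(key=lambda ln: ln.key())
        return out

    def _drop_links_of_node(self, node_id: int) -> None:
        for end in (node_id, -node_id):
            for ln in self._links.pop(end, []):
                self._link_keys.discard(ln.key())
                other = ln.other_end(end)
                if abs(other) != node_id and other in self._links:
                    self._links[other] = [l for l in self._links[other] if l.key() != ln.key()]

    # -- views --------------------------------------------------------------
    def get_nodeview(self, signed_id: int) -> NodeView:
        if signed_id == 0 or not self.is_active(abs(signed_id)):
            raise GraphError(f"node {abs(signed_id)} is deleted or unknown")
        return NodeView(self, signed_id)

    def get_all_nodeviews(self) -> list[NodeView]:
        return [NodeView(self, nid) for nid in self.active_node_ids()]

    def active_node_ids(self) -> list[int]:  # pragma: no cover - abstract
        raise NotImplementedError


class SequenceDistanceGraph(_LinkHolder):
    """The base graph: DNA sequences in nodes, signed-end links between them.

    Node ids are 1-based, sequential and stable: deleting a node leaves a
    tombstone and never renumbers.
    """

    name = "SDG"

    def __init__(self):
        super().__init__()
        self._sequences: list[Optional[str]] = [None]  # index 0 unused
        self._ws = None

    # -- nodes --------------------------------------------------------------
    def add_node(self, sequence: str) -> int:
        """Add a node; returns its id (the next sequential integer from 1)."""
        seq = normalize_node_sequence(sequence)
        self._sequences.append(seq)
        return len(self._sequences) - 1

    def _add_node_with_id(self, node_id: int, sequence: str) -> int:
        """Insert a node at a fixed id (used by GFA readers); gaps tombstoned."""
        if node_id < 1:
            raise GraphError(f"node id must be >= 1, got {node_id}")
        seq = normalize_node_sequence(sequence)
        while len(self._sequences) <= node_id:
            self._sequences.append(None)
        if self._sequences[node_id] is not None:
            raise GraphError(f"node id {node_id} already in use")
        self._sequences[node_id] = seq
        return node_id

    def remove_node(self, node_id: int) -> None:
        """Tombstone a node and drop its links; the id is never reused."""
        node_id = abs(node_id)
        if not self.is_active(node_id):
            raise GraphError(f"node {node_id} is deleted or unknown")
        self._drop_links_of_node(node_id)
        self._sequences[node_id] = None

    def is_active(self, node_id: int) -> bool:
        return 0 < node_id < len(self._sequences) and self._sequences[node_id] is not None

    def node_length(self, node_id: int) -> int:
        if not self.is_active(node_id):
            raise GraphError(f"node {node_id} is deleted or unknown")
        return len(self._sequences[node_id])

    def node_sequence(self, signed_id: int) -> str:
        if not self.is_active(abs(signed_id)):
            raise GraphError(f"node {abs(signed_id)} is deleted or unknown")
        seq = self._sequences[abs(signed_id)]
        return seq if signed_id > 0 else reverse_complement(seq)

    def active_node_ids(self) -> list[int]:
        return [i for i, s in enumerate(self._sequences) if s is not None]

    def node_count(self) -> int:
        return len(self.active_node_ids())

    @property
    def sdg(self) -> "SequenceDistanceGraph":
        return self

    @property
    def workspace(self):
        return self._ws

    # -- GFA convenience (see gfa_io) ---------------------------------------
    def write_to_gfa1(self, path) -> None:
        from . import gfa_io

        gfa_io.write_gfa1(self, path)

    def write_to_gfa2(self, path) -> None:
        from . import gfa_io

        gfa_io.write_gfa2(self, path)


class DistanceGraph(_LinkHolder):
    """An alternative link set over the nodes of a base sequence graph.

    Used for longer-range linkage (e.g. scaffolding links recovered from long
    reads) while the node sequences stay in the base graph.
    """

    def __init__(self, sdg: SequenceDistanceGraph, name: str = "DG"):
        super().__init__()
        self.sdg = sdg
        self.name = name

    def is_active(self, node_id: int) -> bool:
        return self.sdg.is_active(node_id)

    def node_length(self, node_id: int) -> int:
        return self.sdg.node_length(node_id)

    def node_sequence(self, signed_id: int) -> str:
        return self.sdg.node_sequence(signed_id)

    def active_node_ids(self) -> list[int]:
        return self.sdg.active_node_ids()

    @property
    def workspace(self):
        return self.sdg.workspace

    def write_to_gfa1(self, path) -> None:
        from . import gfa_io

        gfa_io.write_gfa1(self, path)

    def write_to_gfa2(self, path) -> None:
        from . import gfa_io

        gfa_io.write_gfa2(self, path)


class SequenceDistanceGraphPath:
    """An oriented walk through a graph: a list of signed node ids.

    Consecutive nodes ``(s_i, s_{i+1})`` must be joined by a link between the
    ends ``-s_i`` and ``s_{i+1}``.
    """

    def __init__(self, graph: _LinkHolder, nodes: Optional[Iterable[int]] = None):
        self.graph = graph
        self.nodes: list[int] = list(nodes) if nodes is not None else []

    def reverse(self) -> "SequenceDistanceGraphPath":
        """In-place reversal: [s1..sk] becomes [-sk..-s1]."""
        self.nodes = [-n for n in reversed(self.nodes)]
        return self

    def _link_between(self, a: int, b: int) -> Link:
        links = self.graph.links_between(-a, b)
        if not links:
            raise GraphError(f"no link between nodes {a} and {b} in path")
        distances = {ln.distance for ln in links}
        if len(distances) > 1:
            raise GraphError(
                f"ambiguous linkage between {a} and {b}: distances {sorted(distances)}"
            )
        return links[0]

    def sequence(self, check_overlaps: bool = True) -> str:
        """The path's DNA sequence.

        Overlaps (negative link distances) consume bases, which must match
        between the joined sequences unless ``check_overlaps=False``; gaps
        insert that many ``N`` characters.
        """
        if not self.nodes:
            return ""
        out = self.graph.node_sequence(self.nodes[0])
        for a, b in zip(self.nodes, self.nodes[1:]):
            seq_b = self.graph.node_sequence(b)
            d = self._link_between(a, b).distance
            if d < 0:
                if check_overlaps and out[len(out) + d :] != seq_b[:-d]:
                    raise GraphError(
                        f"overlap mismatch joining {a} and {b}: "
                        f"{out[len(out) + d:]!r} vs {seq_b[:-d]!r}"
                    )
                out += seq_b[-d:]
            else:
                out += "N" * d + seq_b
        return out

    def __repr__(self) -> str:
        return f"<SequenceDistanceGraphPath: {self.nodes}>"


def enumerate_maximal_paths(graph: _LinkHolder, limit: int = 64) -> list[SequenceDistanceGraphPath]:
    """All maximal simple directed paths of a small graph.

    A path and its reverse complement count once.  Paths start at views with
    no previous neighbour and are extended while unvisited next neighbours
    exist; self-links are ignored.  Guarded by a node-count ``limit``.
    """
    active = graph.active_node_ids()
    if len(active) > limit:
        raise GraphError(f"graph has {len(active)} nodes, over the limit of {limit}")

    def nexts(s: int) -> list[int]:
        return [
            ln.other_end(-s)
            for ln in graph.links_on_end(-s)
            if abs(ln.other_end(-s)) != abs(s)
        ]

    def prevs(s: int) -> list[int]:
        return [
            -ln.other_end(s)
            for ln in graph.links_on_end(s)
            if abs(ln.other_end(s)) != abs(s)
        ]

    paths: list[list[int]] = []

    def extend(path: list[int], used: set[int]) -> None:
        exts = [t for t in nexts(path[-1]) if abs(t) not in used]
        if not exts:
            paths.append(list(path))
            return
        for t in sorted(exts, key=lambda v: (abs(v), -v)):
            used.add(abs(t))
            path.append(t)
            extend(path, used)
            path.pop()
            used.discard(abs(t))

    for nid in active:
        for s in (nid, -nid):
            if not prevs(s):
                extend([s], {abs(s)})

    seen: set[tuple[int, ...]] = set()
    result = []
    for p in paths:
        fwd = tuple(p)
        rev = tuple(-n for n in reversed(p))
        key = min(fwd, rev)
        if key not in seen:
            seen.add(key)
            result.append(SequenceDistanceGraphPath(graph, p))
    result.sort(key=lambda sp: tuple(sp.nodes))
    return result
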