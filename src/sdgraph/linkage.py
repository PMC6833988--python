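"""Long-range linkage from long-read mappings, and its collapse.

The :class:`LinkageMaker` turns filtered long-read mappings into a
*multi-linkage* distance graph holding one link per supporting read between
selected node ends (parallel links are preserved, each tagged with its read).
The :class:`LinkageUntangler` collapses a multi-linkage graph into a clean
scaffold graph where every selected node links only to its closest selected
neighbour in each direction, with the distance aggregated as the (lower)
median of the supporting reads' distance estimates.
"""

from __future__ import annotations

from .graph_core import DistanceGraph, GraphError


def lower_median(values) -> int:
    """Median with the lower of the two central values for even counts."""
    s = sorted(values)
    if not s:
        raise ValueError("median of empty set")
    return s[(len(s) - 1) // 2]


class NodeSelection:
    """Per-node boolean flags, indexable by (signed) node id; default False."""

    def __init__(self, graph):
        self._graph = graph
        self._flags: dict[int, bool] = {}

    def __getitem__(self, node_id: int) -> bool:
        return self._flags.get(abs(node_id), False)

    def __setitem__(self, node_id: int, value: bool) -> None:
        self._flags[abs(node_id)] = bool(value)

    def select_by_size(self, min_bp: int) -> None:
        """Flag every active node of ``min_bp`` or more."""
        for nid in self._graph.active_node_ids():
            self._flags[nid] = self._graph.node_length(nid) >= min_bp

    def selected_ids(self) -> list[int]:
        return sorted(n for n, f in self._flags.items() if f and self._graph.is_active(n))

    def count(self) -> int:
        return len(self.selected_ids())


class LinkageMaker:
    """Builds multi-linkage distance graphs from mapping evidence."""

    def __init__(self, graph):
        self.graph = graph.sdg
        self.selected_nodes = NodeSelection(self.graph)

    def select_by_size(self, min_bp: int) -> None:
        self.selected_nodes.select_by_size(min_bp)

    def make_longreads_multilinkage(
        self, mapper, min_map_span_bp: int = 1000, min_pct: float = 10.0
    ) -> DistanceGraph:
        """One link per read between every ordered pair of its filtered mappings.

        Mappings survive when they sit on a selected node, span at least
        ``min_map_span_bp`` of the node, and have a matched-k-mer percentage of
        at least ``min_pct`` over the mapped node span.  Survivors are ordered
        by read coordinate and every ordered pair contributes a link between
        the facing ends; the distance is the read gap between the two mapped
        segments minus the unmapped node tails (possibly negative).  The
        supporting read id is kept on each link, so parallel links are
        preserved rather than merged.
        """
        if not mapper.mappings:
            raise GraphError("long-read mapper has no mappings; run map_reads() first")
        k = mapper.k
        dg = DistanceGraph(self.graph, name="multilinkage")
        by_read: dict[int, list] = {}
        for m in mapper.mappings:
            by_read.setdefault(m.read_id, []).append(m)
        for rid in sorted(by_read):
            survivors = []
            for m in by_read[rid]:
                if not self.selected_nodes[m.node]:
                    continue
                span = m.node_end - m.node_start
                if span < min_map_span_bp:
                    continue
                pct = 100.0 * m.score / max(1, span - k + 1)
                if pct < min_pct:
                    continue
                survivors.append(m)
            survivors.sort(key=lambda m: (m.read_start, m.read_end, abs(m.node)))
            for i, mi in enumerate(survivors):
                len_i = self.graph.node_length(abs(mi.node))
                for mj in survivors[i + 1 :]:
                    if abs(mi.node) == abs(mj.node):
                        continue
                    d = (
                        (mj.read_start - mi.read_end)
                        - (len_i - mi.node_end)
                        - mj.node_start
                    )
                    try:
                        dg.add_link(-mi.node, mj.node, d, support=rid)
                    except GraphError:
                        pass  # overlap estimate longer than a node: spurious pair
        return dg


class LinkageUntangler:
    """Simplifies a multi-linkage graph over a node selection."""

    def __init__(self, dg: DistanceGraph, min_links: int = 3):
        self.dg = dg
        self.min_links = min_links
        self.selected_nodes = NodeSelection(dg)

    def select_by_size(self, min_bp: int) -> None:
        self.selected_nodes.select_by_size(min_bp)

    def make_nextselected_linkage(self) -> DistanceGraph:
        """Link every selected node to its closest selected neighbour per side.

        For each end of each selected node, parallel links to the same
        neighbouring end are aggregated (count = support, distance = lower
        median); neighbour ends backed by fewer than ``min_links`` reads are
        ignored; among the rest the closest by aggregated distance wins (ties:
        higher support, then lower node id).  The result is a new distance
        graph over the same nodes.
        """
        out = DistanceGraph(self.dg.sdg, name="nextselected")
        for nid in self.selected_nodes.selected_ids():
            for end in (-nid, nid):
                groups: dict[int, list[int]] = {}
                for ln in self.dg.links_on_end(end):
                    other = ln.other_end(end)
                    if abs(other) == nid or not self.selected_nodes[other]:
                        continue
                    groups.setdefault(other, []).append(ln.distance)
                best = None
                for other, dists in groups.items():
                    if len(dists) < self.min_links:
                        continue
                    med = lower_median(dists)
                    key = (med, -len(dists), abs(other), other < 0)
                    if best is None or key < best[0]:
                        best = (key, other, med)
                if best is not None:
                    out.add_link(end, best[1], best[2])
        return out

    def deselect_multiconnected(self, dg: DistanceGraph) -> int:
        """Deselect nodes with more than one link on either side of ``dg``.

        Returns the number of nodes whose flag flipped from selected to not.
        """
        flipped = 0
        for nv in dg.get_all_nodeviews():
            if len(nv.prev()) > 1 or len(nv.next()) > 1:
                if self.selected_nodes[nv.node_id()]:
                    flipped += 1
                self.selected_nodes[nv.node_id()] = False
        return flipped
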