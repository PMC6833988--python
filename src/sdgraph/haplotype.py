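"""Haplotype-guided graph walks driven by parental k-mer coverage.

In a child assembly graph with parental read counts attached, a node is
"fully covered" by a parent when its k-mer coverage by that parent's count
has no zeros.  Starting from a fully covered node, a haplotype-pure path can
be grown in both directions by repeatedly stepping to the single next
neighbour that is itself fully covered; the walk stops at branches where the
choice is not unique, so the result depends on the topology of each
haplotype's subgraph.
"""

from __future__ import annotations

from .graph_core import SequenceDistanceGraphPath


def extend_parent_covered_path(
    graph, starting_node: int, counter_name: str, count_name: str
) -> SequenceDistanceGraphPath:
    """Grow a path of nodes fully covered by one parent's k-mer count.

    Returns an empty path when the starting node itself is not fully covered.
    At each step the walk continues only if exactly one next neighbour is
    fully covered and not yet in the path; after the forward extension the
    path is reversed and extended again, so both directions are walked.
    """
    cov_cache: dict[int, bool] = {}

    def fully_covered(nv) -> bool:
        nid = abs(nv.node_id())
        if nid not in cov_cache:
            cov_cache[nid] = nv.kmer_coverage(counter_name, count_name).count(0) == 0
        return cov_cache[nid]

    if not fully_covered(graph.get_nodeview(starting_node)):
        return SequenceDistanceGraphPath(graph, [])
    p = SequenceDistanceGraphPath(graph, [starting_node])
    for _ in (0, 1):
        nv = graph.get_nodeview(p.nodes[-1])
        while nv.next():
            used = {abs(n) for n in p.nodes}
            next_node = 0
            for nl in nv.next():
                if fully_covered(nl.node()):
                    if next_node or abs(nl.node().node_id()) in used:
                        next_node = 0
                        break
                    next_node = nl.node().node_id()
            if next_node == 0:
                break
            p.nodes.append(next_node)
            nv = graph.get_nodeview(next_node)
        p.reverse()
    return p
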