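"""Reusable analysis recipes built on the linkage and counting primitives."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .graph_core import DistanceGraph, NodeView
from .linkage import LinkageMaker, LinkageUntangler


@dataclass
class ScaffoldResult:
    """Stages of the long-read scaffolding recipe, kept for inspection."""

    multilinkage: DistanceGraph
    first_collapse: DistanceGraph
    final: DistanceGraph
    untangler: LinkageUntangler
    deselected: int


def scaffold_with_long_reads(
    graph,
    long_read_mapper,
    min_node_bp: int = 1100,
    min_map_span_bp: int = 1000,
    min_pct: float = 10.0,
    min_links: int = 3,
) -> ScaffoldResult:
    """Scaffold a graph with long-read linkage.

    The recipe: select nodes of ``min_node_bp`` or more; build per-read
    multi-linkage between them (mappings filtered by span and matched-k-mer
    percentage); collapse to closest-selected-neighbour links; deselect every
    node that ends up multi-connected (repeats belong in more than one place);
    collapse again.  On a genome whose repeats are spanned by the long reads
    the final graph links the unique nodes into their genomic order, with the
    repeats disconnected from any linkage.
    """
    lm = LinkageMaker(graph)
    lm.select_by_size(min_node_bp)
    mldg = lm.make_longreads_multilinkage(long_read_mapper, min_map_span_bp, min_pct)
    lu = LinkageUntangler(mldg, min_links=min_links)
    lu.select_by_size(min_node_bp)
    first = lu.make_nextselected_linkage()
    deselected = lu.deselect_multiconnected(first)
    final = lu.make_nextselected_linkage()
    return ScaffoldResult(mldg, first, final, lu, deselected)


def largest_bubble(graph) -> Optional[tuple[NodeView, NodeView]]:
    """The largest node with exactly one parallel, and that parallel.

    In a diploid assembly this is typically the biggest clean heterozygous
    bubble: the two returned views are the two haplotype sides.
    """
    best_size = 0
    best = None
    for nv in graph.get_all_nodeviews():
        if nv.size() > best_size:
            par = nv.parallels()
            if len(par) == 1:
                best_size = nv.size()
                best = (nv, par[0])
    return best
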