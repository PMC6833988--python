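"""Long-read linkage: selection, multilinkage, next-selected collapse."""

from __future__ import annotations

import numpy as np
import pytest

from sdgraph import DistanceGraph, SequenceDistanceGraph, fixtures
from sdgraph._dna import reverse_complement
from sdgraph.datastores import LongReadDatastore, build_long_datastore
from sdgraph.graph_core import GraphError
from sdgraph.linkage import LinkageMaker, LinkageUntangler, lower_median
from sdgraph.mappers import LongReadMapper


def _graph_with_lengths(*lengths):
    rng = np.random.default_rng(2)
    g = SequenceDistanceGraph()
    for n in lengths:
        g.add_node(fixtures.random_sequence(n, rng))
    return g


class TestSelection:
    def test_select_by_size_is_inclusive(self):
        g = _graph_with_lengths(1100, 1099, 5000)
        lm = LinkageMaker(g)
        lm.select_by_size(1100)
        assert lm.selected_nodes.selected_ids() == [1, 3]

    def test_zero_threshold_selects_everything(self):
        g = _graph_with_lengths(10, 50)
        lm = LinkageMaker(g)
        lm.select_by_size(0)
        assert lm.selected_nodes.selected_ids() == [1, 2]

    def test_flags_default_false_and_accept_signed_ids(self):
        g = _graph_with_lengths(100)
        lm = LinkageMaker(g)
        assert lm.selected_nodes[1] is False
        lm.selected_nodes[-1] = True
        assert lm.selected_nodes[1] is True


class TestMedian:
    def test_odd_count(self):
        assert lower_median([3, 5, 7, 9, 100]) == 7

    def test_even_count_takes_lower(self):
        assert lower_median([6, 4]) == 4

    def test_monotone_under_larger_additions(self):
        base = [3, 5, 7, 9, 100]
        m = lower_median(base)
        for extra in (7, 8, 50, 1000):
            assert lower_median(base + [extra]) >= m


@pytest.fixture
def repeat_linkage(tmp_path):
    """Two 2 kb unique nodes separated by a 500 bp repeat, spanned by 20 reads."""
    rng = np.random.default_rng(19)
    u1 = fixtures.random_sequence(2000, rng)
    rep = fixtures.random_sequence(500, rng)
    u2 = fixtures.random_sequence(2000, rng)
    g = SequenceDistanceGraph()
    g.add_node(u1), g.add_node(rep), g.add_node(u2)
    reads = []
    genome = u1 + rep + u2
    for i in range(20):
        read = fixtures._apply_long_errors(genome, 0.02, rng)
        reads.append(read if i % 2 == 0 else reverse_complement(read))
    path = tmp_path / "lr.fastq"
    path.write_text("".join(f"@r{i}\n{s}\n+\n{'I'*len(s)}\n" for i, s in enumerate(reads)))
    store = LongReadDatastore(build_long_datastore(path, tmp_path / "lr"))
    mapper = LongReadMapper(g, store)
    mapper.map_reads()
    return g, mapper


class TestMultilinkage:
    def test_spanning_reads_give_parallel_links_with_plausible_distance(self, repeat_linkage):
        g, mapper = repeat_linkage
        lm = LinkageMaker(g)
        lm.select_by_size(1000)  # the 500 bp repeat stays unselected
        mldg = lm.make_longreads_multilinkage(mapper, 1000, 10)
        links = mldg.links_on_end(-1)
        assert len(links) >= 20  # one per supporting read, preserved
        assert all(ln.other_end(-1) == 3 for ln in links)
        distances = [ln.distance for ln in links]
        assert abs(lower_median(distances) - 500) <= 0.15 * 500
        supports = {ln.support for ln in links}
        assert len(supports) >= 20  # distinct read provenance

    def test_single_surviving_mapping_contributes_nothing(self, repeat_linkage):
        g, mapper = repeat_linkage
        lm = LinkageMaker(g)
        lm.selected_nodes[1] = True  # only one node selected
        mldg = lm.make_longreads_multilinkage(mapper, 1000, 10)
        assert mldg.all_links() == []

    def test_unreachable_span_filter_gives_empty_multilinkage(self, repeat_linkage):
        g, mapper = repeat_linkage
        lm = LinkageMaker(g)
        lm.select_by_size(0)
        mldg = lm.make_longreads_multilinkage(mapper, 10_000, 10)
        assert mldg.all_links() == []

    def test_no_mappings_is_an_error(self):
        g = _graph_with_lengths(2000)
        lm = LinkageMaker(g)
        mapper = type("M", (), {"mappings": [], "k": 15})()
        with pytest.raises(GraphError, match="no mappings"):
            lm.make_longreads_multilinkage(mapper, 1000, 10)


def _mldg_with(g, parallel_links):
    dg = DistanceGraph(g, "ml")
    for (ea, eb, d), support in parallel_links:
        dg.add_link(ea, eb, d, support=support)
    return dg


class TestNextSelectedCollapse:
    def test_parallel_links_collapse_to_lower_median(self):
        g = _graph_with_lengths(2000, 2000)
        dg = _mldg_with(g, [((-1, 2, d), i) for i, d in enumerate([3, 5, 7, 9, 100])])
        lu = LinkageUntangler(dg)
        lu.select_by_size(0)
        ns = lu.make_nextselected_linkage()
        (ln,) = ns.all_links()
        assert (ln.end_a, ln.end_b, ln.distance) in {(-1, 2, 7), (2, -1, 7)}

    def test_closest_neighbour_wins_over_skipping_link(self):
        """Reads spanning A-B, B-C and A-C keep only the adjacent links."""
        g = _graph_with_lengths(2000, 2000, 2000)
        links = []
        for rid in range(4):
            links.append(((-1, 2, 100 + rid), 10 + rid))   # A -> B
            links.append(((-2, 3, 200 + rid), 20 + rid))   # B -> C
            links.append(((-1, 3, 2400 + rid), 30 + rid))  # A -> C (far)
        dg = _mldg_with(g, links)
        lu = LinkageUntangler(dg)
        lu.select_by_size(0)
        ns = lu.make_nextselected_linkage()
        pairs = {(ln.end_a, ln.end_b) for ln in ns.all_links()}
        assert pairs == {(-1, 2), (-2, 3)}

    def test_min_links_support_floor(self):
        g = _graph_with_lengths(2000, 2000)
        dg = _mldg_with(g, [((-1, 2, 10), 1), ((-1, 2, 12), 2)])  # only 2 supports
        lu = LinkageUntangler(dg)
        lu.select_by_size(0)
        assert lu.make_nextselected_linkage().all_links() == []

    def test_even_support_takes_lower_median(self):
        g = _graph_with_lengths(2000, 2000)
        dg = _mldg_with(g, [((-1, 2, 4), 1), ((-1, 2, 6), 2), ((-1, 2, 4), 3), ((-1, 2, 6), 4)])
        lu = LinkageUntangler(dg)
        lu.select_by_size(0)
        (ln,) = lu.make_nextselected_linkage().all_links()
        assert ln.distance == 4


class TestDeselectMulticonnected:
    def test_simple_chain_deselects_nothing(self):
        g = _graph_with_lengths(2000, 2000, 2000)
        dg = DistanceGraph(g, "ns")
        dg.add_link(-1, 2, 10)
        dg.add_link(-2, 3, 10)
        lu = LinkageUntangler(dg)
        lu.select_by_size(0)
        assert lu.deselect_multiconnected(dg) == 0
        assert lu.selected_nodes.selected_ids() == [1, 2, 3]

    def test_repeat_with_two_entries_is_deselected(self):
        g = _graph_with_lengths(2000, 2000, 500, 2000, 2000)
        dg = DistanceGraph(g, "ns")
        dg.add_link(-1, 3, 0)
        dg.add_link(-2, 3, 0)
        dg.add_link(-3, 4, 0)
        dg.add_link(-3, 5, 0)
        lu = LinkageUntangler(dg)
        lu.select_by_size(0)
        assert lu.deselect_multiconnected(dg) == 1
        assert 3 not in lu.selected_nodes.selected_ids()

    def test_empty_graph_deselects_nothing(self):
        g = _graph_with_lengths(2000)
        dg = DistanceGraph(g, "ns")
        lu = LinkageUntangler(dg)
        lu.select_by_size(0)
        assert lu.deselect_multiconnected(dg) == 0
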