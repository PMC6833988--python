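"""Graph data model: nodes, signed-end links, views, paths."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdgraph import (
    GraphError,
    SequenceDistanceGraph,
    SequenceDistanceGraphPath,
    enumerate_maximal_paths,
    reverse_complement,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


class TestNodes:
    def test_ids_are_sequential_from_one(self):
        g = SequenceDistanceGraph()
        assert [g.add_node("ACGT") for _ in range(5)] == [1, 2, 3, 4, 5]

    def test_sequences_are_uppercased_on_ingest(self):
        g = SequenceDistanceGraph()
        g.add_node("acgT")
        assert g.node_sequence(1) == "ACGT"

    @pytest.mark.parametrize("bad", ["", "ACGTN", "ACGU", "AC GT"])
    def test_invalid_sequences_rejected(self, bad):
        g = SequenceDistanceGraph()
        with pytest.raises(ValueError):
            g.add_node(bad)

    def test_illegal_character_error_names_position(self):
        g = SequenceDistanceGraph()
        with pytest.raises(ValueError, match="position 4"):
            g.add_node("ACGTN")

    def test_deletion_tombstones_without_renumbering(self):
        g = SequenceDistanceGraph()
        for _ in range(3):
            g.add_node("ACGTACGT")
        g.add_link(-1, 2, 0)
        g.remove_node(2)
        assert g.active_node_ids() == [1, 3]
        assert g.add_node("TTTT") == 4  # deleted id never reused
        with pytest.raises(GraphError):
            g.get_nodeview(2)
        assert g.get_nodeview(1).next() == []  # links of deleted node dropped


class TestLinks:
    def test_link_is_symmetric_and_idempotent(self, fig1):
        g = fig1.sdg
        # re-adding with swapped ends is the same link
        g.add_link(2, -1, -2)
        assert len(g.links_on_end(-1)) == 2  # (-1,2) and (-1,-3) only
        assert len(g.all_links()) == 5

    def test_unknown_node_rejected(self, fig1):
        with pytest.raises(GraphError, match="unknown"):
            fig1.sdg.add_link(-1, 9, 0)

    def test_overlap_longer_than_node_rejected(self):
        g = SequenceDistanceGraph()
        g.add_node("ACGTACGT")
        g.add_node("ACG")
        with pytest.raises(GraphError, match="overlap"):
            g.add_link(-1, 2, -3)

    def test_gap_link_between_tail_and_head(self):
        g = SequenceDistanceGraph()
        a, b = g.add_node("ACGTACGT"), g.add_node("TTGCATGC")
        g.add_link(-a, b, 10)
        (lv,) = g.get_nodeview(a).next()
        assert lv.distance() == 10 and lv.node().node_id() == b
        (lv,) = g.get_nodeview(b).prev()
        assert lv.distance() == 10 and lv.node().node_id() == a


class TestNodeViews:
    def test_fig1_next_prev_convention(self, fig1):
        nv = fig1.sdg.get_nodeview(1)
        nxt = nv.next()
        assert [(lv.distance(), lv.node().node_id()) for lv in nxt] == [(-3, -3), (-2, 2)]
        back = nxt[0].node()
        assert [(lv.distance(), lv.node().node_id()) for lv in back.prev()] == [(-3, 1)]
        assert back.sequence() == "GGACCGTATT"

    def test_dead_end_has_no_next(self, fig1):
        assert fig1.sdg.get_nodeview(5).next() == []

    def test_view_sequence_orientation(self, fig1):
        nv = fig1.sdg.get_nodeview(3)
        assert nv.rc().sequence() == reverse_complement(nv.sequence())

    def test_parallels_on_fig1(self, fig1):
        assert [v.node_id() for v in fig1.sdg.get_nodeview(2).parallels()] == [-3]

    def test_parallels_perfect_bubble(self):
        g = SequenceDistanceGraph()
        a = g.add_node("AAAAAAAA")
        b1 = g.add_node("CCCCCCCC")
        b2 = g.add_node("GGGGGGGG")
        c = g.add_node("TTTTTTTT")
        for side in (b1, b2):
            g.add_link(-a, side, 0)
            g.add_link(-side, c, 0)
        assert [v.node_id() for v in g.get_nodeview(b1).parallels()] == [b2]
        assert [v.node_id() for v in g.get_nodeview(b2).parallels()] == [b1]

    def test_isolated_node_has_no_parallels(self):
        g = SequenceDistanceGraph()
        g.add_node("ACGT")
        assert g.get_nodeview(1).parallels() == []


class TestPaths:
    def test_fig1_path_sequence(self, fig1):
        p = SequenceDistanceGraphPath(fig1.sdg, [1, -3, 4, 5])
        assert p.sequence() == "CTACGGACCGTATTACGAANNNNNNNNNNCTGATATGA"

    def test_alternative_fig1_path(self, fig1):
        p = SequenceDistanceGraphPath(fig1.sdg, [1, 2, 4, 5])
        assert p.sequence() == "CTACGGACCTTACGAANNNNNNNNNNCTGATATGA"

    def test_single_node_path(self, fig1):
        assert SequenceDistanceGraphPath(fig1.sdg, [-3]).sequence() == "GGACCGTATT"

    def test_missing_link_rejected(self, fig1):
        with pytest.raises(GraphError, match="no link"):
            SequenceDistanceGraphPath(fig1.sdg, [1, 5]).sequence()

    def test_overlap_mismatch_detected_and_optionally_ignored(self):
        g = SequenceDistanceGraph()
        g.add_node("ACGTTT")
        g.add_node("GGACGT")
        g.add_link(-1, 2, -2)  # claims TT == GG
        p = SequenceDistanceGraphPath(g, [1, 2])
        with pytest.raises(GraphError, match="mismatch"):
            p.sequence()
        assert p.sequence(check_overlaps=False) == "ACGTTTACGT"

    def test_reverse_gives_reverse_complement(self, fig1):
        p = SequenceDistanceGraphPath(fig1.sdg, [1, -3, 4, 5])
        fwd = p.sequence()
        assert p.reverse().nodes == [-5, -4, 3, -1]
        assert p.sequence() == reverse_complement(fwd)


def _random_graph(seed: int, n_nodes: int = 12, n_links: int = 14) -> SequenceDistanceGraph:
    rng = random.Random(seed)
    g = SequenceDistanceGraph()
    for _ in range(n_nodes):
        g.add_node("".join(rng.choice("ACGT") for _ in range(rng.randint(8, 40))))
    for _ in range(n_links):
        a = rng.choice([1, -1]) * rng.randint(1, n_nodes)
        b = rng.choice([1, -1]) * rng.randint(1, n_nodes)
        g.add_link(a, b, rng.randint(0, 25))
    return g


@pytest.mark.parametrize("seed", range(8))
def test_next_prev_duality_on_random_graphs(seed):
    """m in next(s) iff s in prev(m), with equal distances (brute force)."""
    g = _random_graph(seed)
    for nid in g.active_node_ids():
        for s in (nid, -nid):
            for lv in g.get_nodeview(s).next():
                m = lv.node().node_id()
                mirrored = [
                    (pv.distance(), pv.node().node_id())
                    for pv in g.get_nodeview(m).prev()
                ]
                assert (lv.distance(), s) in mirrored


@pytest.mark.parametrize("seed", range(5))
def test_path_reversal_orientation_on_random_graphs(seed):
    """path_sequence(reverse(p)) == rc(path_sequence(p)) on gap-linked walks."""
    rng = random.Random(seed)
    g = SequenceDistanceGraph()
    nodes = [g.add_node("".join(rng.choice("ACGT") for _ in range(rng.randint(5, 30))))
             for _ in range(6)]
    signed = [n if rng.random() < 0.5 else -n for n in nodes]
    for a, b in zip(signed, signed[1:]):
        g.add_link(-a, b, rng.randint(0, 15))
    p = SequenceDistanceGraphPath(g, signed)
    fwd = p.sequence()
    assert p.reverse().sequence() == reverse_complement(fwd)


class TestReverseComplement:
    def test_worked_example(self):
        assert reverse_complement("AATACGGTCC") == "GGACCGTATT"

    def test_empty(self):
        assert reverse_complement("") == ""

    @settings(deadline=None, max_examples=50)
    @given(dna)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq


class TestMaximalPaths:
    def test_fig1_has_two_maximal_paths(self, fig1):
        paths = enumerate_maximal_paths(fig1.sdg)
        assert sorted(p.nodes for p in paths) == [[1, -3, 4, 5], [1, 2, 4, 5]]

    def test_single_unlinked_node(self):
        g = SequenceDistanceGraph()
        g.add_node("ACGT")
        (p,) = enumerate_maximal_paths(g)
        assert [abs(n) for n in p.nodes] == [1]

    def test_simple_chain(self):
        g = SequenceDistanceGraph()
        for _ in range(3):
            g.add_node("ACGTACGT")
        g.add_link(-1, 2, 0)
        g.add_link(-2, 3, 0)
        (p,) = enumerate_maximal_paths(g)
        assert p.nodes in ([1, 2, 3], [-3, -2, -1])

    def test_limit_guard(self, fig1):
        with pytest.raises(GraphError, match="limit"):
            enumerate_maximal_paths(fig1.sdg, limit=2)
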