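"""Read-to-graph mapping: unique-anchor short reads, chained long reads."""

from __future__ import annotations

import numpy as np
import pytest

from sdgraph import GraphError, SequenceDistanceGraph, fixtures
from sdgraph._dna import canonical_kmer, reverse_complement
from sdgraph.datastores import build_long_datastore, build_paired_datastore, LongReadDatastore, PairedReadDatastore
from sdgraph.mappers import LongReadMapper, PairedReadMapper, UniqueKmerIndex


def _write_fastq(path, seqs):
    path.write_text("".join(f"@r{i}\n{s}\n+\n{'I'*len(s)}\n" for i, s in enumerate(seqs)))
    return path


def _paired_store(tmp_path, r1, r2, name="pe"):
    return PairedReadDatastore(
        build_paired_datastore(
            _write_fastq(tmp_path / f"{name}_1.fastq", r1),
            _write_fastq(tmp_path / f"{name}_2.fastq", r2),
            tmp_path / name,
        )
    )


def _long_store(tmp_path, reads, name="lo"):
    return LongReadDatastore(
        build_long_datastore(_write_fastq(tmp_path / f"{name}.fastq", reads), tmp_path / name)
    )


@pytest.fixture
def two_node_graph():
    rng = np.random.default_rng(42)
    g = SequenceDistanceGraph()
    g.add_node(fixtures.random_sequence(3000, rng))
    g.add_node(fixtures.random_sequence(3000, rng))
    return g


class TestUniqueIndex:
    def test_indexed_kmers_occur_exactly_once(self, two_node_graph):
        """Brute-force soundness: no indexed k-mer occurs twice in the graph."""
        k = 21
        idx = UniqueKmerIndex(two_node_graph, k)
        counts: dict[str, int] = {}
        for nid in two_node_graph.active_node_ids():
            seq = two_node_graph.node_sequence(nid)
            for i in range(len(seq) - k + 1):
                km = canonical_kmer(seq[i : i + k])
                counts[km] = counts.get(km, 0) + 1
        singletons = {km for km, n in counts.items() if n == 1}
        from sdgraph._kmers import decode_code

        indexed = {decode_code(c, k) for c in idx.codes.tolist()}
        assert indexed == singletons

    def test_repeated_sequence_drops_out(self):
        g = SequenceDistanceGraph()
        rng = np.random.default_rng(1)
        seq = fixtures.random_sequence(500, rng)
        g.add_node(seq)
        g.add_node(seq)  # every k-mer now occurs twice
        assert len(UniqueKmerIndex(g, 31)) == 0


class TestPairedMapper:
    def test_verbatim_read_maps_forward(self, two_node_graph, tmp_path):
        seq = two_node_graph.node_sequence(1)
        store = _paired_store(tmp_path, [seq[1000:1250]], [reverse_complement(seq[1400:1650])])
        mapper = PairedReadMapper(two_node_graph, store)
        m1, m2 = mapper.map_reads()
        assert m1.node == 1 and m1.read_id == 1
        assert m2.node == -1 and m2.read_id == 2  # second mate is reverse complemented

    def test_chimeric_read_is_unmapped(self, two_node_graph, tmp_path):
        a = two_node_graph.node_sequence(1)[:125]
        b = two_node_graph.node_sequence(2)[:125]
        store = _paired_store(tmp_path, [a + b], [reverse_complement(a + b)])
        mapper = PairedReadMapper(two_node_graph, store)
        assert mapper.map_reads() == []

    def test_strand_coherence(self, two_node_graph, tmp_path):
        seq = two_node_graph.node_sequence(2)
        read = seq[500:750]
        store = _paired_store(tmp_path, [read], [reverse_complement(read)])
        mapper = PairedReadMapper(two_node_graph, store)
        fwd, rev = mapper.map_reads()
        assert fwd.node == 2 and rev.node == -2
        assert fwd.hit_count == rev.hit_count
        assert rev.first_offset == len(read) - 31 - fwd.last_offset

    def test_origin_recovery_rate(self, tmp_path):
        """>= 99% of error-free reads from unique sequence map to their origin."""
        rng = np.random.default_rng(23)
        g = SequenceDistanceGraph()
        nodes = [g.add_node(fixtures.random_sequence(4000, rng)) for _ in range(4)]
        r1, r2, origins = [], [], []
        for i in range(400):
            nid = nodes[i % 4]
            seq = g.node_sequence(nid)
            start = int(rng.integers(0, len(seq) - 700))
            frag = seq[start : start + 700]
            r1.append(frag[:250])
            r2.append(reverse_complement(frag[-250:]))
            origins.extend([nid, nid])
        store = _paired_store(tmp_path, r1, r2)
        mapper = PairedReadMapper(g, store)
        mappings = {m.read_id: abs(m.node) for m in mapper.map_reads()}
        correct = sum(mappings.get(rid) == origins[rid - 1] for rid in range(1, 801))
        assert correct >= 0.99 * 800

    def test_reads_on_node(self, two_node_graph, tmp_path):
        seq = two_node_graph.node_sequence(1)
        store = _paired_store(tmp_path, [seq[:250]], [reverse_complement(seq[-250:])])
        mapper = PairedReadMapper(two_node_graph, store)
        mapper.map_reads()
        assert mapper.reads_on_node(1) == [1, 2]
        assert mapper.reads_on_node(2) == []
        two_node_graph.remove_node(2)
        with pytest.raises(GraphError):
            mapper.reads_on_node(2)


class TestLongReadMapper:
    def test_concatenated_nodes_give_ordered_mappings(self, two_node_graph, tmp_path):
        read = two_node_graph.node_sequence(1) + two_node_graph.node_sequence(2)
        store = _long_store(tmp_path, [read])
        mapper = LongReadMapper(two_node_graph, store)
        mappings = mapper.map_reads()
        assert len(mappings) >= 2
        by_start = sorted(mappings, key=lambda m: m.read_start)
        assert by_start[0].node == 1 and by_start[-1].node == 2
        assert by_start[0].read_start < by_start[-1].read_start

    def test_noisy_read_chain_covers_most_of_the_node(self, tmp_path):
        """At 10% errors a chain still covers >= 80% of the 5 kb read span."""
        rng = np.random.default_rng(31)
        g = SequenceDistanceGraph()
        g.add_node(fixtures.random_sequence(5000, rng))
        noisy = fixtures._apply_long_errors(g.node_sequence(1), 0.10, rng)
        store = _long_store(tmp_path, [noisy])
        mapper = LongReadMapper(g, store)
        mappings = mapper.map_reads()
        assert mappings
        best = max(mappings, key=lambda m: m.score)
        assert best.node == 1
        assert (best.read_end - best.read_start) >= 0.8 * len(noisy)

    def test_repeat_node_is_multimapped(self, tmp_path):
        rng = np.random.default_rng(37)
        repeat = fixtures.random_sequence(1200, rng)
        g = SequenceDistanceGraph()
        g.add_node(fixtures.random_sequence(2000, rng))
        g.add_node(repeat)
        g.add_node(fixtures.random_sequence(2000, rng))
        read1 = g.node_sequence(1) + repeat
        read2 = repeat + g.node_sequence(3)
        store = _long_store(tmp_path, [read1, read2])
        mapper = LongReadMapper(g, store)
        mapper.map_reads()
        assert mapper.reads_on_node(2) == [1, 2]  # both contexts hit the repeat

    def test_strand_coherence(self, two_node_graph, tmp_path):
        read = two_node_graph.node_sequence(1)[200:2800]
        store = _long_store(tmp_path, [read, reverse_complement(read)])
        mapper = LongReadMapper(two_node_graph, store)
        m_fwd, m_rev = mapper.map_reads()
        assert m_fwd.node == 1 and m_rev.node == -1
        assert m_fwd.score == m_rev.score
        assert m_fwd.read_start == m_rev.read_start  # mirrored coordinates
        node_len = two_node_graph.node_length(1)
        assert m_rev.node_start == node_len - m_fwd.node_end
        assert m_rev.node_end == node_len - m_fwd.node_start

    def test_rerun_is_deterministic_and_sorted(self, two_node_graph, tmp_path):
        rng = np.random.default_rng(41)
        reads = []
        for _ in range(10):
            nid = int(rng.integers(1, 3))
            seq = two_node_graph.node_sequence(nid)
            reads.append(fixtures._apply_long_errors(seq, 0.05, rng))
        store = _long_store(tmp_path, reads)
        mapper = LongReadMapper(two_node_graph, store)
        first = mapper.map_reads()
        second = mapper.map_reads()
        assert first == second
        keys = [(m.read_id, abs(m.node), m.node < 0, m.read_start) for m in first]
        assert keys == sorted(keys)

    def test_k_range_enforced(self, two_node_graph, tmp_path):
        store = _long_store(tmp_path, ["ACGT" * 100])
        mapper = LongReadMapper(two_node_graph, store)
        mapper.k = 17
        with pytest.raises(ValueError, match="7..15"):
            mapper.map_reads()
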