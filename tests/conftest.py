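"""Shared fixtures: the worked 5-node graph and two end-to-end simulations."""

from __future__ import annotations

import pytest

from sdgraph import WorkSpace, scaffold_with_long_reads
from sdgraph import datastores, dbg, fixtures

FIG1_SEQUENCES = ["CTACGGA", "GACCTTA", "AATACGGTCC", "TTACGAA", "CTGATATGA"]
FIG1_LINKS = [(-1, 2, -2), (-1, -3, -3), (-2, 4, -3), (3, 4, -2), (-4, 5, 10)]


def build_fig1_workspace() -> WorkSpace:
    """The five-node worked-example graph, built through the public API."""
    ws = WorkSpace()
    for seq in FIG1_SEQUENCES:
        ws.sdg.add_node(seq)
    for ea, eb, d in FIG1_LINKS:
        ws.sdg.add_link(ea, eb, d)
    return ws


@pytest.fixture
def fig1():
    return build_fig1_workspace()


# ---------------------------------------------------------------------------
# end-to-end simulations, shared across modules (expensive, session-scoped)
# ---------------------------------------------------------------------------

SCAFFOLD_SEED = 7
TRIO_SEED = 11


def run_scaffold_pipeline(workdir, seed: int = SCAFFOLD_SEED) -> dict:
    """Hybrid assembly on a 100 kb circular genome with 4 interspersed repeats.

    Two exact 1400 bp repeat families with two copies each; 40x error-free
    paired reads assemble the base graph at k=63, 30x long reads (5% errors)
    provide the scaffolding linkage.
    """
    genome = fixtures.make_genome(
        fixtures.GenomeSpec(
            100_000,
            (fixtures.RepeatSpec(1400, 2), fixtures.RepeatSpec(1400, 2)),
            circular=True,
            seed=seed,
        )
    )
    pe = fixtures.simulate_paired_reads(genome, coverage=40, error_rate=0.0, seed=seed)
    r1, r2 = pe.write(workdir / "pe")
    store_path = datastores.build_paired_datastore(r1, r2, workdir / "pe")
    store = datastores.PairedReadDatastore(store_path)
    ws = dbg.build_dbg(store, dbg.DbgParams(k=63, min_coverage=1))
    lr = fixtures.simulate_long_reads(
        genome, mean_len=6000, error_rate=0.05, coverage=30, seed=seed
    )
    lr_path = lr.write(workdir / "lr")
    lords = ws.add_long_reads_datastore(datastores.build_long_datastore(lr_path, workdir / "lr"))
    lords.mapper.map_reads()
    result = scaffold_with_long_reads(ws.sdg, lords.mapper, 1100, 1000, 10)
    # repeat nodes: unitig sequences occurring more than once along the genome
    doubled = genome.sequence + genome.sequence
    repeat_nodes = [
        nv.node_id()
        for nv in ws.sdg.get_all_nodeviews()
        if doubled.count(nv.sequence()) + doubled.count(
            fixtures.reverse_complement(nv.sequence())
        ) > 2  # a unique segment of a circular genome appears twice in doubled
    ]
    return {
        "genome": genome,
        "workspace": ws,
        "long_handle": lords,
        "result": result,
        "repeat_nodes": repeat_nodes,
        "workdir": workdir,
    }


def run_trio_pipeline(workdir, seed: int = TRIO_SEED) -> dict:
    """Diploid trio on a 50 kb template: 1% het, 2x250 bp, 70x, 0.1% errors.

    The child's reads are assembled at k=63 and the parents' reads are
    counted over the child graph's k=31 index.
    """
    import numpy as np

    template = fixtures.random_sequence(50_000, np.random.default_rng(seed))
    trio = fixtures.simulate_trio(fixtures.TrioSpec(templates=(template,), seed=seed))
    files = trio.write(workdir)
    r1, r2 = files["child"]
    store_path = datastores.build_paired_datastore(r1, r2, workdir / "child_pe")
    store = datastores.PairedReadDatastore(store_path)
    ws = dbg.build_dbg(store, dbg.DbgParams(k=63, min_coverage=2))
    counter = ws.get_kmer_counter("main")
    counter.add_count("p1", list(files["p1"]))
    counter.add_count("p2", list(files["p2"]))
    return {"trio": trio, "workspace": ws, "counter": counter, "workdir": workdir}


@pytest.fixture(scope="session")
def scaffold_run(tmp_path_factory):
    return run_scaffold_pipeline(tmp_path_factory.mktemp("scaffold"))


@pytest.fixture(scope="session")
def trio_run(tmp_path_factory):
    return run_trio_pipeline(tmp_path_factory.mktemp("trio"))
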