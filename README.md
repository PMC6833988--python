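# sdgraph

Genome assembly graphs that keep both overlaps and gaps, plus everything
needed to project raw sequencing data onto them.

Assembly pipelines usually flatten graphs into linear sequences between
steps, losing the ambiguity information that downstream stages need.
`sdgraph` is a workbench for doing the opposite: it holds a **sequence
distance graph** — nodes carrying DNA sequences, links joining *node ends*
with a signed distance in bp (negative = the sequences overlap by that many
bases, positive = a gap of unknown sequence) — together with the raw reads,
their mappings, and k-mer counts, in one persistent workspace. It is aimed at
people building or dissecting assemblies interactively or in scripts:
scaffolding a short-read graph with long reads, walking haplotypes of a
diploid graph using parental k-mer coverage, or just navigating a GFA with a
sane orientation model.

Every node `n` has a `+n` end (the head of its stored sequence) and a `-n`
end (the tail). A link between ends `(-a, b)` reads "a forward, then b
forward"; traversal, paths, and reverse complements all fall out of this one
convention. A `WorkSpace` binds one base `SequenceDistanceGraph`, any number
of alternative `DistanceGraph` link sets (e.g. long-range scaffolding
linkage), on-disk random-access read datastores with per-datastore mappers,
and `KmerCounter` indexes with named count vectors.

## A worked example

```python
>>> import sdgraph as SDG
>>> ws = SDG.WorkSpace()
>>> [ws.sdg.add_node(s) for s in
...  ["CTACGGA", "GACCTTA", "AATACGGTCC", "TTACGAA", "CTGATATGA"]]
[1, 2, 3, 4, 5]
>>> ws.sdg.add_link(-1, 2, -2)    # node 1 then node 2, overlapping 2 bp
>>> ws.sdg.add_link(-1, -3, -3)   # node 1 then reverse of node 3, 3 bp overlap
>>> ws.sdg.add_link(-2, 4, -3)
>>> ws.sdg.add_link(3, 4, -2)
>>> ws.sdg.add_link(-4, 5, 10)    # a 10 bp gap
>>> nv = ws.sdg.get_nodeview(1)
>>> print(nv.next())
[<LinkView: -3bp to Node -3>, <LinkView: -2bp to Node 2>]
>>> nv = nv.next()[0].node()
>>> print(nv.prev())
[<LinkView: -3bp to Node 1>]
>>> nv.sequence()
'GGACCGTATT'
>>> SDG.SequenceDistanceGraphPath(ws.sdg, [1, -3, 4, 5]).sequence()
'CTACGGACCGTATTACGAANNNNNNNNNNCTGATATGA'
```

The path sequence splices overlaps (checking the overlapping bases match)
and fills the 10 bp gap with `N`s. Bubble sides are found with
`nv.parallels()`, and `SDG.enumerate_maximal_paths(ws.sdg)` reports the two
maximal walks of this little graph, `[1, 2, 4, 5]` and `[1, -3, 4, 5]`.

Larger workflows follow the same shape. A hybrid assembly:

```python
from sdgraph import scaffold_with_long_reads
from sdgraph.datastores import PairedReadDatastore
from sdgraph.dbg import build_dbg, DbgParams

ws = build_dbg(PairedReadDatastore("pe.prseq"), DbgParams(k=63, min_coverage=2))
lords = ws.add_long_reads_datastore("pb.loseq")
lords.mapper.map_reads()
result = scaffold_with_long_reads(ws.sdg, lords.mapper,
                                  min_node_bp=1100, min_map_span_bp=1000, min_pct=10)
result.final.write_to_gfa1("scaffolded.gfa")
ws.save("checkpoint.sdgws")   # graph + mappings + counters, reloadable anywhere
```

On the packaged synthetic benchmark (a 100 kb circular genome with four
interspersed exact 1.4 kb repeats, 40x paired reads, 30x long reads at 5%
error) this leaves the four unique nodes joined in a single cycle in their
genomic order and both repeat nodes disconnected from any linkage. For trio
analysis, `largest_bubble(ws.sdg)` plus per-parent k-mer counts on the
child's graph identify haplotype nodes, and
`extend_parent_covered_path(ws.sdg, node, "main", "p1")` grows a
haplotype-pure path in both directions.

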