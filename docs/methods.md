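# Methods

## The graph model

A sequence distance graph stores each DNA sequence once, in an arbitrary
orientation, and expresses all adjacency through links between *node ends*.
Node `n` exposes end `+n` (the head of the stored sequence) and end `-n`
(the tail). A link `(end_a, end_b, d)` is symmetric — the same object is
discoverable from both ends — and `d` unifies overlap and gap: `d < 0` means
the adjacent sequences share `|d|` bases, `d > 0` means `d` unknown bases
separate them, `d = 0` means they abut.

Traversal is defined once and reused everywhere: for a signed view `s`, the
*next* neighbours are the links incident to end `-s`, and the neighbour's
view id is the link's other end verbatim; the *previous* neighbours are the
links on end `s`, with the other end negated. Consequently `add_link(-a, b,
d)` reads "a forward, then b forward". Link lists are returned sorted by
(distance, |neighbour|, sign) so output is deterministic.

Paths are lists of signed nodes; each consecutive pair `(s_i, s_{i+1})` must
be joined by a link between ends `(-s_i, s_{i+1})`. Path sequences splice
negative distances by consuming bases — by default the overlapping substrings
must match exactly, and a mismatch raises (silent mismatches usually mean
graph corruption; `sequence(check_overlaps=False)` opts out) — and render
`d >= 0` as `d` `N` characters. Node deletion tombstones the id and drops its
links; ids are never renumbered, because mappings and links reference them.

`parallels()` returns the other oriented nodes whose previous-end set and
next-end set both equal the view's own (both non-empty): the two sides of a
simple bubble. Self-links are stored but excluded from bubble detection and
from maximal-path enumeration, which is a guarded exhaustive search intended
for small graphs.

## GFA dialects

GFA2 round-trips exactly: overlaps become E-lines, gaps become G-lines with
the distance. GFA1 has no native gap encoding, so gap links are written as
`0M` overlaps with a `gp:i:<bp>` tag; a foreign reader sees a zero-overlap
adjacency, which is the least-wrong lossy reading, and the dialect is noted
in a header comment. Only single-run `NM` CIGARs are accepted on read —
the model has no alignment detail to store, so anything else is an error
rather than a silent approximation. Orientation maps as: `+` on the
from-segment means from-end `-n`, `-` means `+n`; on the to-segment `+`
means to-end `+m`. All-digit segment names keep their ids; other names get
fresh sequential ids with the mapping preserved on the returned graph.

## Datastores

Read datastores pack sequences at 2 bits/base into a single container file
with a trailing offset index (layout documented in `datastores.py`), so any
read is one seek away and nothing is held in memory. Qualities are dropped:
no algorithm here uses them, and it halves the size. Non-ACGT characters are
stored as `A` and their positions recorded in an exceptions table;
`get_read_masked` restores them as `N`, which makes every k-mer consumer skip
windows touching them. Building a store from identical inputs is
byte-identical, which makes checkpoints diffable.

## k-mers

Canonical k-mers (the lexicographic minimum of a k-mer and its reverse
complement) are encoded base-4 big-endian so numeric order equals string
order: one 64-bit word for k <= 31, a (hi, lo) pair for 31 < k <= 63. k must
be odd so no k-mer is its own reverse complement. All bulk operations are
vectorised with numpy over batches of reads joined by `N` separators (the
separator invalidates straddling windows).

A `KmerCounter` indexes exactly the canonical k-mers of the active node
sequences (k <= 31) and keeps named count vectors over that index; the
graph's own occurrence count always exists under the reserved name `"sdg"`.
Counting reads ignores k-mers absent from the index — only graph-projected
analyses are supported — and saturates at 2^32-1 rather than overflowing.
Coverage projection over an oriented sequence reports, per position, the
stored count of the canonical k-mer starting there; by canonical symmetry the
reverse view's vector is exactly the reversed vector.

## de Bruijn graph construction

Canonical k-mers (default k=63, two-word encoding) are counted across a
paired datastore; k-mers below `min_coverage` (default 2) are dropped;
survivors are compacted into unitigs — maximal walks whose internal junctions
are 1-in/1-out on both sides — by deterministic extension from each canonical
k-mer in sorted order. Unitig sequences are stored as min(seq, revcomp).
Links between unitigs carry the dBG overlap `-(k-1)`; an isolated cycle (a
circular genome) becomes one unitig with a self-link. No tip clipping or
bubble popping is done: heterozygous bubbles are the signal for trio
analyses, and error tips are cheap to ignore downstream. The defaults (k=63,
min_coverage=2) suit the "long-k dBG then scaffold" workflow; both are CLI
flags. The builder wraps the graph in a workspace and pre-adds a k=31 counter
("main") with the graph count and the reads' count ("PE").

## Mappers

Short reads map through a *unique* k-mer index (default k=31): only k-mers
occurring exactly once across all node sequences anchor reads. A read maps
only when all its anchors agree on one node (majority vote on strand);
anchors spanning two or more nodes leave the read unmapped, which keeps
placements unambiguous at the price of recall near junctions.

Long reads map through a short non-unique index (default k=15, 7..15
allowed). Every anchor hit is kept; hits are grouped per oriented node and
per diagonal (read offset minus oriented node offset, tolerance 500 bp), then
chained greedily in read order: a hit joins the chain if its node coordinate
is monotone, the read gap to the previous anchor is <= 500 bp and the read
and node coordinate deltas agree within 20% (minimum 10 bp slack); chains
with >= 5 anchors are reported. Mapping coordinates are given in the
*oriented* node so `node_start < node_end` always holds. All chains are
reported — filtering belongs to the consumer (the linkage maker applies span
and identity thresholds). Mappings are stored in the workspace, not the
datastore, so one datastore can serve several workspaces; output is sorted
by (read, node, start) and is independent of processing order.

## Linkage

`LinkageMaker.make_longreads_multilinkage(mapper, min_span, min_pct)` keeps,
per read, the mappings on selected nodes spanning at least `min_span` bp of
the node with a matched-k-mer percentage (anchors / k-mer positions in the
mapped span) of at least `min_pct`, orders them by read coordinate, and adds
one link per *ordered pair* of survivors between the facing ends, distance =
read gap minus the unmapped node tails (possibly negative), tagged with the
read id. All pairs — not only consecutive survivors — are linked: when a
repeat node is later deselected, the direct pair links across it are what let
the collapse reconnect its flanks; with consecutive-only links the final
graph could never bridge a deselected node. Parallel links between the same
ends are preserved, one per supporting read.

`LinkageUntangler.make_nextselected_linkage()` collapses that evidence: for
each end of each selected node, parallel links to the same neighbouring end
are aggregated (distance = lower median — the smaller central value for even
counts — support = link count); neighbours with fewer than `min_links`
(default 3, rejecting singleton chimeras) are ignored, and the closest
surviving neighbour by aggregated distance wins, ties broken by higher
support then lower node id. `deselect_multiconnected` then drops every node
with more than one link on either side (repeats belong in more than one
place), and a second collapse yields the clean scaffold graph.

## Workspace persistence

A workspace serialises to one container file (magic, version, journal, base
graph with tombstones, distance graphs, datastore registrations with their
mappers' full mapping tables, counter references). Reads and k-mer counts
stay in their own files, referenced by paths relative to the workspace file,
so a checkpoint directory is portable and several workspaces can share one
dataset. Loading with a referenced file missing succeeds with that handle
*detached*: graph-only analyses keep working, data queries on the detached
handle raise. A journal of operations is kept and printed by the CLI tools.
Everything here is single-threaded; results trivially do not depend on any
worker count.

## Synthetic data

The fixtures module generates every dataset used in tests, as pure functions
of (spec, seed):

* **Genomes** — uniform random sequence with exact repeat families overwritten
  at evenly spread, non-overlapping placements (or explicit ones); the truth
  table lists each copy's interval. This emulates interspersed exact repeats
  only: no tandem arrays, no diverged copies, no compositional bias.
* **Paired reads** — fragments dropped uniformly (normal length, sd = 10% of
  the mean), mates from the fragment ends with the second mate reverse
  complemented, substitution errors only. Defaults mirror the trio study
  conditions: 700 bp fragments, 2x250 bp, 70x, 0.1% error.
* **Long reads** — lognormal lengths (sigma 0.3 around the requested mean),
  substitution/insertion/deletion errors at 0.6/0.2/0.2 of the error rate;
  circular genomes wrap. No chimeras and no length-quality correlation.
* **Trio** — each parent is the template with heterozygous substitutions at
  ~1% of sites (the alt allele assigned to a random haplotype); each parent's
  pair is crossed over (one uniform crossover by default, configurable) and
  the child inherits one recombinant product per parent at random; reads are
  simulated per individual at the requested total coverage, split across the
  two haplotypes.

Because repeats are exact and errors are memoryless, passing the end-to-end
tests shows the machinery composes correctly, not that the parameters are
tuned for real instruments; on real data the mapper bands and the `min_pct`
filter are the knobs to revisit.

## Benchmark problem sizes

The end-to-end suites run a 100 kb circular genome with two exact 1.4 kb
repeat families (two copies each, all four loci shorter than the 6 kb mean
long-read length) at 40x paired / 30x long coverage for scaffolding, and a
50 kb diploid trio at 1% heterozygosity, 2x250 bp, 70x, 0.1% error for the
haplotype analysis. These sizes keep every structural feature of the larger
worked analyses (collapsed repeats, parental bubbles) while staying
comfortable for routine runs; all seeds are fixed in the tests.

The exact node and base-pair tallies of a haplotype extension depend on the
topology of each haplotype's subgraph and on the simulator's random draws, so
the suite checks structural properties (coverage complementarity, path
purity, cycle recovery) rather than any particular node count.

## Known limitations

* Linked-read (10x) datastores are accepted by the CLI only to report that
  they are not implemented; BAM/CRAM input is out of scope.
* GFA P/W/C/F lines are rejected, not skipped.
* The long-read mapper produces k-mer chains, not base-level alignments; there
  are no CIGARs or mapping qualities, and paired-end mapping does no mate
  rescue.
* The dBG builder performs no error correction; it relies on the coverage
  filter, so very low-coverage datasets need `--min-cov 1` and clean reads.
* `enumerate_maximal_paths` is exponential in the worst case and guarded by a
  node-count limit; it is a worked-example and debugging tool, not an
  assembly algorithm.
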