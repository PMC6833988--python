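"""Seeded synthetic data generators.

Everything the test suite and the worked examples consume is generated here:
repeat-bearing genomes with a truth table of repeat placements, paired-end
and long reads with configurable error models, and a diploid parent-offspring
trio with recombination.  All generators are pure functions of their
parameters and seed: rerunning with the same inputs is byte-identical.

Short reads carry substitution errors only; long reads carry substitutions,
insertions and deletions, emulating the respective technologies.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ._dna import reverse_complement
from ._kmers import canonical_codes

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_LIST = "ACGT"


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode("ascii")


def _substitute(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in _BASE_LIST if b != base]
    return choices[rng.integers(0, 3)]


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatSpec:
    """One exact repeat family: a unit of ``unit_length`` placed ``copies`` times."""

    unit_length: int
    copies: int
    placements: Optional[tuple[int, ...]] = None  # start positions; auto if None


@dataclass(frozen=True)
class GenomeSpec:
    length: int
    repeats: tuple[RepeatSpec, ...] = ()
    circular: bool = False
    seed: int = 1


@dataclass
class Genome:
    sequence: str
    circular: bool
    # truth table: (repeat family index, copy index, start, end) per placement
    repeat_truth: list[tuple[int, int, int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)


def make_genome(spec: GenomeSpec) -> Genome:
    """A random genome with exact interspersed repeats and a truth table.

    Without explicit placements, repeat copies are interleaved round-robin
    across families and spread evenly along the genome, so consecutive copies
    of the same family are separated by unique sequence.  Overlapping
    placements are rejected.
    """
    rng = _rng(spec.seed)
    seq = list(random_sequence(spec.length, rng))
    units = [random_sequence(r.unit_length, rng) for r in spec.repeats]

    placements: list[tuple[int, int, int]] = []  # (family, copy, start)
    slots: list[tuple[int, int]] = []
    for fam, r in enumerate(spec.repeats):
        for copy in range(r.copies):
            slots.append((fam, copy))
    if slots:
        explicit = all(r.placements is not None for r in spec.repeats)
        if explicit:
            for fam, r in enumerate(spec.repeats):
                if len(r.placements) != r.copies:
                    raise ValueError(f"repeat family {fam}: {r.copies} copies but "
                                     f"{len(r.placements)} placements")
                for copy, start in enumerate(r.placements):
                    placements.append((fam, copy, start))
        else:
            # round-robin interleave: families alternate along the genome
            order = sorted(slots, key=lambda s: (s[1], s[0]))
            n = len(order)
            for i, (fam, copy) in enumerate(order):
                centre = int(round(spec.length * (i + 1) / (n + 1)))
                placements.append((fam, copy, centre - spec.repeats[fam].unit_length // 2))
    placements.sort(key=lambda p: p[2])
    truth = []
    prev_end = 0
    for fam, copy, start in placements:
        end = start + spec.repeats[fam].unit_length
        if start < prev_end or end > spec.length:
            raise ValueError("repeat placements overlap or fall off the genome")
        seq[start:end] = units[fam]
        truth.append((fam, copy, start, end))
        prev_end = end
    return Genome("".join(seq), spec.circular, truth)


# ---------------------------------------------------------------------------
# paired-end reads
# ---------------------------------------------------------------------------

@dataclass
class PairedReadSim:
    r1: list[str]
    r2: list[str]
    # truth per fragment: (fragment start, fragment length, source index)
    truth: list[tuple[int, int, int]]
    read_len: int

    def write(self, prefix) -> tuple[Path, Path]:
        """Write <prefix>_R1.fastq.gz / <prefix>_R2.fastq.gz."""
        p1 = Path(f"{prefix}_R1.fastq.gz")
        p2 = Path(f"{prefix}_R2.fastq.gz")
        _write_fastq_gz(p1, (f"fr{i}/1" for i in range(len(self.r1))), self.r1)
        _write_fastq_gz(p2, (f"fr{i}/2" for i in range(len(self.r2))), self.r2)
        return p1, p2


def _write_fastq_gz(path: Path, names, seqs) -> None:
    # mtime pinned to zero so identical simulations give identical bytes
    with open(path, "wb") as raw:
        with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as fh:
            for name, seq in zip(names, seqs):
                fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n".encode("ascii"))


def simulate_paired_reads(
    genome: str | Genome | Sequence[str],
    frag_mean: int = 700,
    read_len: int = 250,
    coverage: float = 70,
    error_rate: float = 0.001,
    seed: int = 1,
    frag_sd: Optional[float] = None,
) -> PairedReadSim:
    """Paired-end reads from fragments dropped uniformly along the genome.

    ``genome`` may be a sequence string, a :class:`Genome` (circular genomes
    wrap) or a list of sequences (e.g. the haplotypes of a diploid; coverage
    is then split across them).  Mates come from the fragment ends, the
    second mate reverse complemented; substitution errors are applied at
    ``error_rate`` per base.
    """
    if read_len > frag_mean:
        raise ValueError("read_len must not exceed frag_mean")
    circular = isinstance(genome, Genome) and genome.circular
    if isinstance(genome, Genome):
        sources = [genome.sequence]
    elif isinstance(genome, str):
        sources = [genome]
    else:
        sources = list(genome)
    rng = _rng(seed)
    sd = frag_sd if frag_sd is not None else 0.1 * frag_mean
    r1, r2, truth = [], [], []
    total_len = sum(len(s) for s in sources)
    for src_idx, src in enumerate(sources):
        n_frags = int(round(coverage * len(src) / (2 * read_len)))
        lens = np.maximum(
            read_len, np.round(rng.normal(frag_mean, sd, n_frags)).astype(int)
        )
        if circular:
            starts = rng.integers(0, len(src), n_frags)
            doubled = src + src
        else:
            lens = np.minimum(lens, len(src))
            starts = rng.integers(0, len(src) - lens + 1)
            doubled = src
        n_err1 = rng.binomial(read_len, error_rate, n_frags)
        n_err2 = rng.binomial(read_len, error_rate, n_frags)
        for i in range(n_frags):
            frag = doubled[starts[i] : starts[i] + lens[i]]
            a = frag[:read_len]
            b = reverse_complement(frag[-read_len:])
            if n_err1[i]:
                a = _apply_substitutions(a, n_err1[i], rng)
            if n_err2[i]:
                b = _apply_substitutions(b, n_err2[i], rng)
            r1.append(a)
            r2.append(b)
            truth.append((int(starts[i]), int(lens[i]), src_idx))
    return PairedReadSim(r1, r2, truth, read_len)


def _apply_substitutions(seq: str, n: int, rng: np.random.Generator) -> str:
    chars = list(seq)
    for pos in rng.choice(len(chars), size=min(n, len(chars)), replace=False):
        chars[pos] = _substitute(chars[pos], rng)
    return "".join(chars)


# ---------------------------------------------------------------------------
# long reads
# ---------------------------------------------------------------------------

@dataclass
class LongReadSim:
    reads: list[str]
    # truth per read: (genomic start, genomic end (may wrap), strand +1/-1)
    truth: list[tuple[int, int, int]]

    def write(self, prefix) -> Path:
        path = Path(f"{prefix}.fastq.gz")
        _write_fastq_gz(path, (f"lr{i}" for i in range(len(self.reads))), self.reads)
        return path


def simulate_long_reads(
    genome: str | Genome,
    mean_len: int = 6000,
    error_rate: float = 0.05,
    coverage: float = 30,
    seed: int = 1,
    sigma: float = 0.3,
) -> LongReadSim:
    """Long reads with lognormal lengths and substitution+indel errors.

    Lengths follow exp(N(ln(mean) - sigma^2/2, sigma)), so the expectation is
    ``mean_len``.  Errors occur per base at ``error_rate``; an error is a
    substitution with probability 0.6, an insertion or a deletion with 0.2
    each.  Circular genomes wrap; half the reads come from each strand.
    """
    circular = isinstance(genome, Genome) and genome.circular
    seq = genome.sequence if isinstance(genome, Genome) else genome
    L = len(seq)
    rng = _rng(seed)
    mu = np.log(mean_len) - sigma**2 / 2
    doubled = seq + seq if circular else seq
    reads, truth = [], []
    total = 0
    target = coverage * L
    while total < target:
        rlen = int(np.clip(np.round(np.exp(rng.normal(mu, sigma))), 300, 5 * mean_len))
        if not circular:
            rlen = min(rlen, L)
            start = int(rng.integers(0, L - rlen + 1))
        else:
            start = int(rng.integers(0, L))
        fragment = doubled[start : start + rlen]
        strand = 1 if rng.random() < 0.5 else -1
        if strand < 0:
            fragment = reverse_complement(fragment)
        reads.append(_apply_long_errors(fragment, error_rate, rng))
        truth.append((start, start + rlen, strand))
        total += rlen
    return LongReadSim(reads, truth)


def _apply_long_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    n = rng.binomial(len(seq), error_rate)
    if n == 0:
        return seq
    positions = np.sort(rng.choice(len(seq), size=n, replace=False))
    kinds = rng.choice(3, size=n, p=[0.6, 0.2, 0.2])  # sub, ins, del
    out = []
    prev = 0
    for pos, kind in zip(positions.tolist(), kinds.tolist()):
        out.append(seq[prev:pos])
        if kind == 0:
            out.append(_substitute(seq[pos], rng))
            prev = pos + 1
        elif kind == 1:
            out.append(_BASE_LIST[rng.integers(0, 4)])
            prev = pos  # insertion before pos
        else:
            prev = pos + 1  # deletion
    out.append(seq[prev:])
    return "".join(out)


# ---------------------------------------------------------------------------
# trio simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrioSpec:
    """A diploid parent-offspring trio over one or more template chromosomes."""

    templates: tuple[str, ...]
    heterozygosity: float = 0.01
    frag_mean: int = 700
    read_len: int = 250
    coverage: float = 70  # per individual, across both haplotypes
    error_rate: float = 0.001
    crossovers: int = 1
    seed: int = 1


@dataclass
class Individual:
    name: str
    haplotypes: list[str]  # one per template chromosome, times two
    reads: PairedReadSim


@dataclass
class TrioSim:
    p1: Individual
    p2: Individual
    child: Individual
    # per parent, per chromosome: sorted het site positions
    het_positions: dict[str, list[np.ndarray]]
    # per parent, per chromosome: crossover position used for the child
    crossovers: dict[str, list[int]]
    # child haplotypes by origin: child_from[parent][chrom] is the inherited sequence
    child_from: dict[str, list[str]]

    def write(self, outdir) -> dict[str, tuple[Path, Path]]:
        """Write six FASTQ files: <who>-pe-reads_R{1,2}.fastq.gz per individual."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        out = {}
        for ind in (self.p1, self.p2, self.child):
            out[ind.name] = ind.reads.write(outdir / f"{ind.name}-pe-reads")
        return out


def _make_diploid(template: str, het: float, rng: np.random.Generator):
    """Two haplotypes differing at ~het fraction of sites, plus the site list."""
    L = len(template)
    sites = np.flatnonzero(rng.random(L) < het)
    hap_a = list(template)
    hap_b = list(template)
    for pos in sites.tolist():
        alt = _substitute(template[pos], rng)
        if rng.random() < 0.5:
            hap_a[pos] = alt
        else:
            hap_b[pos] = alt
    return "".join(hap_a), "".join(hap_b), sites


def _recombine(hap_a: str, hap_b: str, n_crossovers: int, rng: np.random.Generator):
    """Cross the pair over and return one inherited product plus the points."""
    L = len(hap_a)
    points = sorted(int(rng.integers(1, L)) for _ in range(n_crossovers))
    first, second = (hap_a, hap_b) if rng.random() < 0.5 else (hap_b, hap_a)
    out = []
    cur, other = first, second
    prev = 0
    for x in points:
        out.append(cur[prev:x])
        cur, other = other, cur
        prev = x
    out.append(cur[prev:])
    return "".join(out), points


def simulate_trio(spec: TrioSpec) -> TrioSim:
    """Simulate the trio: diploid parents, recombined inheritance, reads.

    Each parent is the template with heterozygous substitutions at ~1% of
    sites (by default).  For every chromosome each parent's pair is crossed
    over and the child inherits one recombinant product from each parent at
    random.  Paired reads are simulated for all three individuals at the
    requested per-individual coverage.
    """
    if any(len(t) < 1000 for t in spec.templates):
        raise ValueError("template chromosomes must be at least 1 kb")
    rng = _rng(spec.seed)
    het_positions: dict[str, list[np.ndarray]] = {"p1": [], "p2": []}
    crossovers: dict[str, list[int]] = {"p1": [], "p2": []}
    child_from: dict[str, list[str]] = {"p1": [], "p2": []}
    parent_haps: dict[str, list[str]] = {"p1": [], "p2": []}
    for template in spec.templates:
        for parent in ("p1", "p2"):
            hap_a, hap_b, sites = _make_diploid(template, spec.heterozygosity, rng)
            parent_haps[parent].extend([hap_a, hap_b])
            het_positions[parent].append(sites)
            inherited, points = _recombine(hap_a, hap_b, spec.crossovers, rng)
            child_from[parent].append(inherited)
            crossovers[parent].extend(points)

    child_haps = [*child_from["p1"], *child_from["p2"]]

    def reads_for(haps: list[str], seed: int) -> PairedReadSim:
        return simulate_paired_reads(
            haps,
            frag_mean=spec.frag_mean,
            read_len=spec.read_len,
            coverage=spec.coverage / 2,  # per haplotype: total is per individual
            error_rate=spec.error_rate,
            seed=seed,
        )

    base = spec.seed * 4
    p1 = Individual("p1", parent_haps["p1"], reads_for(parent_haps["p1"], base + 1))
    p2 = Individual("p2", parent_haps["p2"], reads_for(parent_haps["p2"], base + 2))
    child = Individual("child", child_haps, reads_for(child_haps, base + 3))
    return TrioSim(p1, p2, child, het_positions, crossovers, child_from)


def genome_kmer_codes(sequences: Sequence[str], k: int) -> np.ndarray:
    """Sorted unique canonical k-mer codes of a set of sequences (k <= 31)."""
    parts = []
    for seq in sequences:
        canon, _, valid = canonical_codes(seq, k)
        parts.append(canon[valid])
    if not parts:
        return np.empty(0, dtype=np.uint64)
    return np.unique(np.concatenate(parts))


def parent_private_kmers(trio: TrioSim, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical k-mer codes private to each parent's genome (p1-only, p2-only)."""
    k1 = genome_kmer_codes(trio.p1.haplotypes, k)
    k2 = genome_kmer_codes(trio.p2.haplotypes, k)
    return np.setdiff1d(k1, k2), np.setdiff1d(k2, k1)
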