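"""GFA1 / GFA2 import and export.

Negative link distances map to overlap CIGARs (``|d|M`` in GFA1, E-lines in
GFA2).  GFA1 has no native encoding for a positive (gap) distance, so gap
links are written as ``0M`` overlaps carrying the distance in a custom
``gp:i:<bp>`` tag; foreign readers see a zero-overlap adjacency.  GFA2 gap
links use proper G-lines and round-trip exactly.

Segment names are written as the integer node ids.  On read, all-digit names
keep their id; arbitrary names are assigned fresh sequential ids and the
mapping is preserved on the returned graph as ``gfa_names``.
"""

from __future__ import annotations

import gzip
import re
from typing import IO, Iterator

from .graph_core import SequenceDistanceGraph, _LinkHolder

GAP_TAG = "gp"

_CIGAR_RE = re.compile(r"^(\d+)M$")


class GfaError(ValueError):
    """Malformed or unsupported GFA content."""


def _open_text(path, mode: str) -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def _link_to_gfa_ends(ea: int, eb: int) -> tuple[int, str, int, str]:
    """Map a link's signed ends to GFA from/to segments with orientations.

    A link between ends (-a, b) means "a forward then b forward", i.e.
    ``a + b +`` in GFA terms.
    """
    from_seg, from_or = abs(ea), ("+" if ea < 0 else "-")
    to_seg, to_or = abs(eb), ("+" if eb > 0 else "-")
    return from_seg, from_or, to_seg, to_or


def _gfa_ends_to_link(from_seg: int, from_or: str, to_seg: int, to_or: str) -> tuple[int, int]:
    ea = -from_seg if from_or == "+" else from_seg
    eb = to_seg if to_or == "+" else -to_seg
    return ea, eb


# ---------------------------------------------------------------------------
# GFA1
# ---------------------------------------------------------------------------

def write_gfa1(graph: _LinkHolder, destination) -> None:
    """Write a graph (sequence or distance graph) as GFA1."""
    with _open_text(destination, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        fh.write(f"# gap links are encoded as 0M overlaps with a {GAP_TAG}:i:<bp> tag\n")
        for nid in graph.active_node_ids():
            fh.write(f"S\t{nid}\t{graph.node_sequence(nid)}\n")
        for ln in graph.all_links():
            fs, fo, ts, to = _link_to_gfa_ends(ln.end_a, ln.end_b)
            if ln.distance < 0:
                cigar, tag = f"{-ln.distance}M", ""
            else:
                cigar, tag = "0M", f"\t{GAP_TAG}:i:{ln.distance}"
            fh.write(f"L\t{fs}\t{fo}\t{ts}\t{to}\t{cigar}{tag}\n")


def read_gfa1(source) -> SequenceDistanceGraph:
    """Read a GFA1 file into a new sequence distance graph."""
    graph = SequenceDistanceGraph()
    names: dict[str, int] = {}
    pending_links: list[tuple[int, str, int, int, int]] = []

    def seg_id(name: str, lineno: int) -> int:
        if name in names:
            return names[name]
        raise GfaError(f"line {lineno}: L-line references unknown segment {name!r}")

    with _open_text(source, "r") as fh:
        for lineno, line in enumerate(_records(fh), start=1):
            if line is None:
                continue
            fields = line.split("\t")
            kind = fields[0]
            if kind == "H":
                _check_version(fields, "1.0", lineno)
            elif kind == "S":
                if len(fields) < 3 or fields[2] in ("*", ""):
                    raise GfaError(f"line {lineno}: S-line without an inline sequence")
                names[fields[1]] = _add_segment(graph, fields[1], fields[2], lineno)
            elif kind == "L":
                if len(fields) < 6:
                    raise GfaError(f"line {lineno}: malformed L-line")
                a = seg_id(fields[1], lineno)
                b = seg_id(fields[3], lineno)
                d = _parse_overlap(fields[5], lineno)
                gap = _find_gap_tag(fields[6:])
                if gap is not None:
                    if d != 0:
                        raise GfaError(f"line {lineno}: {GAP_TAG} tag on a non-0M link")
                    d = gap
                ea, eb = _gfa_ends_to_link(a, fields[2], b, fields[4])
                graph.add_link(ea, eb, d)
            else:
                raise GfaError(f"line {lineno}: unsupported record type {kind!r}")
    graph.gfa_names = names
    return graph


def _parse_overlap(cigar: str, lineno: int) -> int:
    m = _CIGAR_RE.match(cigar)
    if not m:
        raise GfaError(
            f"line {lineno}: only single-run match CIGARs (NM) are supported, got {cigar!r}"
        )
    return -int(m.group(1))


def _find_gap_tag(tags: list[str]) -> int | None:
    for tag in tags:
        parts = tag.split(":")
        if len(parts) == 3 and parts[0] == GAP_TAG and parts[1] == "i":
            return int(parts[2])
    return None


# ---------------------------------------------------------------------------
# GFA2
# ---------------------------------------------------------------------------

def write_gfa2(graph: _LinkHolder, destination) -> None:
    """Write a graph as GFA2: overlaps as E-lines, gaps as G-lines."""
    with _open_text(destination, "w") as fh:
        fh.write("H\tVN:Z:2.0\n")
        for nid in graph.active_node_ids():
            seq = graph.node_sequence(nid)
            fh.write(f"S\t{nid}\t{len(seq)}\t{seq}\n")
        for ln in graph.all_links():
            fs, fo, ts, to = _link_to_gfa_ends(ln.end_a, ln.end_b)
            if ln.distance < 0:
                o = -ln.distance
                len1 = graph.node_length(fs)
                len2 = graph.node_length(ts)
                if fo == "+":
                    beg1, end1 = str(len1 - o), f"{len1}$"
                else:
                    beg1, end1 = "0", str(o)
                if to == "+":
                    beg2, end2 = "0", str(o)
                else:
                    beg2, end2 = str(len2 - o), f"{len2}$"
                fh.write(
                    f"E\t*\t{fs}{fo}\t{ts}{to}\t{beg1}\t{end1}\t{beg2}\t{end2}\t{o}M\n"
                )
            else:
                fh.write(f"G\t*\t{fs}{fo}\t{ts}{to}\t{ln.distance}\t*\n")


def read_gfa2(source) -> SequenceDistanceGraph:
    """Read a GFA2 file into a new sequence distance graph."""
    graph = SequenceDistanceGraph()
    names: dict[str, int] = {}

    def ref(field: str, lineno: int) -> tuple[int, str]:
        name, orient = field[:-1], field[-1]
        if orient not in "+-":
            raise GfaError(f"line {lineno}: malformed oriented reference {field!r}")
        if name not in names:
            raise GfaError(f"line {lineno}: reference to unknown segment {name!r}")
        return names[name], orient

    with _open_text(source, "r") as fh:
        for lineno, line in enumerate(_records(fh), start=1):
            if line is None:
                continue
            fields = line.split("\t")
            kind = fields[0]
            if kind == "H":
                _check_version(fields, "2.0", lineno)
            elif kind == "S":
                if len(fields) < 4 or fields[3] in ("*", ""):
                    raise GfaError(f"line {lineno}: S-line without an inline sequence")
                names[fields[1]] = _add_segment(graph, fields[1], fields[3], lineno)
            elif kind == "E":
                if len(fields) < 9:
                    raise GfaError(f"line {lineno}: malformed E-line")
                a, ao = ref(fields[2], lineno)
                b, bo = ref(fields[3], lineno)
                beg1 = int(fields[4].rstrip("$"))
                end1 = int(fields[5].rstrip("$"))
                d = -(end1 - beg1)
                if d >= 0:
                    raise GfaError(f"line {lineno}: E-line with empty overlap interval")
                ea, eb = _gfa_ends_to_link(a, ao, b, bo)
                graph.add_link(ea, eb, d)
            elif kind == "G":
                if len(fields) < 5:
                    raise GfaError(f"line {lineno}: malformed G-line")
                a, ao = ref(fields[2], lineno)
                b, bo = ref(fields[3], lineno)
                ea, eb = _gfa_ends_to_link(a, ao, b, bo)
                graph.add_link(ea, eb, int(fields[4]))
            else:
                raise GfaError(f"line {lineno}: unsupported record type {kind!r}")
    graph.gfa_names = names
    return graph


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _records(fh) -> Iterator[str | None]:
    for raw in fh:
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            yield None
        else:
            yield line


def _check_version(fields: list[str], expected: str, lineno: int) -> None:
    for tag in fields[1:]:
        if tag.startswith("VN:Z:") and tag[5:] != expected:
            raise GfaError(f"line {lineno}: GFA version {tag[5:]} where {expected} expected")


def _add_segment(graph: SequenceDistanceGraph, name: str, seq: str, lineno: int) -> int:
    try:
        if name.isdigit() and int(name) >= 1:
            return graph._add_node_with_id(int(name), seq)
        return graph.add_node(seq)
    except ValueError as exc:
        raise GfaError(f"line {lineno}: {exc}") from exc
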