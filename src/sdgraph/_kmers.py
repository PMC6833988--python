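"""Vectorised canonical k-mer machinery.

k-mers are encoded base-4 big-endian (A=0, C=1, G=2, T=3) so that numeric
order on codes equals lexicographic order on the strings.  k <= 31 fits one
64-bit word; 31 < k <= 63 is held in a (hi, lo) pair where ``hi`` encodes the
first k-31 bases and ``lo`` the last 31, compared lexicographically.

The canonical form of a k-mer is the smaller of the k-mer and its reverse
complement; with odd k no k-mer equals its own reverse complement.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np

_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _LUT[_b] = _i

_BASES = b"ACGT"

U2 = np.uint64(2)


def encode(seq: str | bytes) -> np.ndarray:
    """Map a sequence to per-base codes 0..3; non-ACGT becomes 255."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _LUT[np.frombuffer(seq, dtype=np.uint8)]


def _window_codes(vals: np.ndarray, k: int) -> np.ndarray:
    """Base-4 codes of every length-k window of a clamped uint64 value array."""
    m = len(vals) - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64)
    codes = vals[0:m].copy()
    for j in range(1, k):
        codes = (codes << U2) | vals[j : j + m]
    return codes


def _prepare(vals: np.ndarray, k: int):
    """Clamped forward/reverse value arrays plus the window validity mask."""
    bad = vals > 3
    clamped = np.where(bad, 0, vals).astype(np.uint64)
    m = len(vals) - k + 1
    if m <= 0:
        return clamped, None, np.empty(0, dtype=bool)
    cs = np.concatenate([[0], np.cumsum(bad)])
    valid = (cs[k:] - cs[:-k]) == 0
    rclamped = (np.uint64(3) - clamped)[::-1]
    return clamped, rclamped, valid


def canonical_codes(seq: str | bytes | np.ndarray, k: int):
    """Canonical codes of all k-mers of a sequence (k <= 31).

    Returns ``(canon, fwd_is_canon, valid)`` arrays of length len(seq)-k+1.
    ``valid`` is False for windows touching a non-ACGT character.
    """
    if k > 31:
        raise ValueError(f"k={k} exceeds the single-word limit of 31")
    vals = seq if isinstance(seq, np.ndarray) else encode(seq)
    clamped, rclamped, valid = _prepare(vals, k)
    if rclamped is None:
        e = np.empty(0, dtype=np.uint64)
        return e, np.empty(0, dtype=bool), valid
    fwd = _window_codes(clamped, k)
    rc = _window_codes(rclamped, k)[::-1]
    fwd_is_canon = fwd <= rc
    canon = np.where(fwd_is_canon, fwd, rc)
    return canon, fwd_is_canon, valid


def canonical_codes_2word(seq: str | bytes | np.ndarray, k: int):
    """Canonical (hi, lo) codes for 31 < k <= 63; returns (hi, lo, valid)."""
    if not 31 < k <= 63:
        raise ValueError(f"k={k} out of the two-word range (32..63)")
    h = k - 31
    vals = seq if isinstance(seq, np.ndarray) else encode(seq)
    clamped, rclamped, valid = _prepare(vals, k)
    if rclamped is None:
        e = np.empty(0, dtype=np.uint64)
        return e, e.copy(), valid
    m = len(vals) - k + 1
    fhi = _window_codes(clamped, h)[:m]
    flo = _window_codes(clamped[h:], 31)[:m]
    # window i of the forward sequence is window m-1-i of the reverse complement
    rhi = _window_codes(rclamped, h)[:m][::-1].copy()
    rlo = _window_codes(rclamped[h:], 31)[:m][::-1].copy()
    fwd_le = (fhi < rhi) | ((fhi == rhi) & (flo <= rlo))
    hi = np.where(fwd_le, fhi, rhi)
    lo = np.where(fwd_le, flo, rlo)
    return hi, lo, valid


def decode_code(code: int, k: int) -> str:
    out = bytearray(k)
    c = int(code)
    for i in range(k - 1, -1, -1):
        out[i] = _BASES[c & 3]
        c >>= 2
    return out.decode("ascii")


def decode_2word(hi: int, lo: int, k: int) -> str:
    return decode_code(hi, k - 31) + decode_code(lo, 31)


def decode_many_2word(hi: np.ndarray, lo: np.ndarray, k: int) -> list[str]:
    """Decode arrays of two-word codes to strings in one vectorised pass."""
    n = len(hi)
    h = k - 31
    chars = np.empty((n, k), dtype=np.uint8)
    basemap = np.frombuffer(_BASES, dtype=np.uint8)
    for i in range(h):
        chars[:, i] = basemap[((hi >> np.uint64(2 * (h - 1 - i))) & np.uint64(3)).astype(np.intp)]
    for i in range(31):
        chars[:, h + i] = basemap[((lo >> np.uint64(2 * (30 - i))) & np.uint64(3)).astype(np.intp)]
    buf = chars.tobytes()
    return [buf[i * k : (i + 1) * k].decode("ascii") for i in range(n)]


def iter_canonical_batches(
    sequences: Iterable[str], k: int, batch_bases: int = 1_000_000
) -> Iterator[np.ndarray]:
    """Yield canonical code arrays (k <= 31) over batches of sequences.

    Sequences are joined with an ``N`` separator so no window spans two reads;
    invalid windows are dropped.
    """
    buf: list[str] = []
    size = 0
    for seq in sequences:
        buf.append(seq)
        size += len(seq) + 1
        if size >= batch_bases:
            yield _batch_canon(buf, k)
            buf, size = [], 0
    if buf:
        yield _batch_canon(buf, k)


def _batch_canon(seqs: list[str], k: int) -> np.ndarray:
    canon, _, valid = canonical_codes("N".join(seqs), k)
    return canon[valid]


def iter_canonical_batches_2word(
    sequences: Iterable[str], k: int, batch_bases: int = 1_000_000
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Two-word analogue of :func:`iter_canonical_batches` (31 < k <= 63)."""
    buf: list[str] = []
    size = 0
    for seq in sequences:
        buf.append(seq)
        size += len(seq) + 1
        if size >= batch_bases:
            yield _batch_canon_2word(buf, k)
            buf, size = [], 0
    if buf:
        yield _batch_canon_2word(buf, k)


def _batch_canon_2word(seqs: list[str], k: int) -> tuple[np.ndarray, np.ndarray]:
    hi, lo, valid = canonical_codes_2word("N".join(seqs), k)
    return hi[valid], lo[valid]
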