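"""Small DNA sequence helpers shared across the package."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_VALID = frozenset("ACGT")
_VALID_WITH_N = frozenset("ACGTN")


def reverse_complement(sequence: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}.

    ``N`` maps to ``N``; the empty string maps to itself.
    """
    return sequence.translate(_COMPLEMENT)[::-1]


def normalize_node_sequence(sequence: str) -> str:
    """Upper-case and validate a node sequence (strict {A,C,G,T} alphabet).

    Raises ``ValueError`` naming the first offending position.
    """
    if not sequence:
        raise ValueError("node sequence must be non-empty")
    seq = sequence.upper()
    for i, base in enumerate(seq):
        if base not in _VALID:
            raise ValueError(
                f"illegal character {base!r} at position {i} "
                "(node sequences are restricted to A, C, G, T)"
            )
    return seq


def canonical_kmer(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc
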