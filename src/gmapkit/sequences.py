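"""Small sequence helpers shared across modules.

Sequences are plain uppercase ``str`` over {A,C,G,T} throughout the package;
lowercase input is accepted and upcased, ``U`` is rejected (DNA only).
Coordinates are 0-based, half-open.
"""

from __future__ import annotations

from .errors import SequenceError

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCATGCA")

DNA_ALPHABET = frozenset("ACGT")


def clean_sequence(seq: str, *, what: str = "sequence", min_length: int = 1) -> str:
    """Upcase and validate a DNA string; reject non-ACGT naming the position."""
    if not isinstance(seq, str):
        raise SequenceError(f"{what} must be a string, got {type(seq).__name__}")
    s = seq.upper()
    if len(s) < min_length:
        raise SequenceError(
            f"{what} too short: length {len(s)} < required {min_length}"
        )
    for i, ch in enumerate(s):
        if ch not in DNA_ALPHABET:
            raise SequenceError(
                f"{what} contains non-ACGT character {ch!r} at position {i}"
            )
    return s


def revcomp(seq: str) -> str:
    """Reverse complement, 5'->3'."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def least_rotation(s: str) -> int:
    """Index of the lexicographically least rotation (Booth's algorithm)."""
    t = s + s
    n = len(t)
    f = [-1] * n
    k = 0
    for j in range(1, n):
        sj = t[j]
        i = f[j - k - 1]
        while i != -1 and sj != t[k + i + 1]:
            if sj < t[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != t[k + i + 1]:
            if sj < t[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


def canonical_circular(seq: str) -> str:
    """Canonical form of a circular duplex: the lexicographically smaller of
    the least rotations of the two strands.  Used to deduplicate assembly
    products up to rotation and reverse complement."""
    if not seq:
        return seq
    rc = revcomp(seq)
    a = seq[least_rotation(seq):] + seq[:least_rotation(seq)]
    b = rc[least_rotation(rc):] + rc[:least_rotation(rc)]
    return min(a, b)


def rotations_equal(a: str, b: str) -> bool:
    """True if circular sequences a and b are the same duplex molecule."""
    return len(a) == len(b) and canonical_circular(a) == canonical_circular(b)
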