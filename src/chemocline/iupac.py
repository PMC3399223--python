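"""IUPAC nucleotide codes and degenerate matching.

Degenerate codes are compared as base sets: two codes are compatible when
their base sets intersect.  This permissive rule is the convention of
in-silico digest tools, where an ``N`` in a sequencing read should not hide
a restriction site.
"""

from __future__ import annotations

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "U": "A", "G": "C", "C": "G",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def validate(seq: str, what: str = "sequence") -> str:
    """Upper-case *seq* and check every character is an IUPAC code."""
    s = str(seq).upper()
    for ch in s:
        if ch not in IUPAC_SETS:
            raise ValueError(f"{what} contains non-IUPAC character {ch!r}")
    return s


def codes_compatible(a: str, b: str) -> bool:
    """True when the base sets of two IUPAC codes intersect."""
    return bool(IUPAC_SETS[a] & IUPAC_SETS[b])


def matches_at(seq: str, motif: str, pos: int) -> bool:
    """True when *motif* is compatible with *seq* starting at *pos*."""
    if pos < 0 or pos + len(motif) > len(seq):
        return False
    return all(codes_compatible(seq[pos + i], motif[i]) for i in range(len(motif)))


def find_matches(seq: str, motif: str) -> list[int]:
    """All 0-based start positions where *motif* matches *seq*."""
    return [i for i in range(len(seq) - len(motif) + 1) if matches_at(seq, motif, i)]


def mismatch_count(seq: str, primer: str, pos: int) -> int:
    """Number of incompatible positions of *primer* aligned at *pos*."""
    return sum(
        not codes_compatible(seq[pos + i], primer[i]) for i in range(len(primer))
    )


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[ch] for ch in reversed(seq.upper()))
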