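"""In-silico prediction of labeled terminal restriction fragment lengths.

In TRFLP the 5' end of the forward primer carries a fluorophore, so only
the fragment between that labeled base and the first downstream cut on the
top strand is detected.  Given an amplicon (or a clone sequence that begins
at the priming site), a restriction enzyme, and the primer pair, the
predicted fragment length is::

    first top-strand cut position at/after the labeled 5' end
    - labeled 5' end position

counting from the first base of the forward primer inclusive.  When the
enzyme has no recognition site before the reverse-primer site the fragment
is ``uncut`` (the whole amplicon is detected).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from . import iupac

UNCUT = "uncut"


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme as seen by the labeled (top) strand.

    ``cut_offset_top`` is the distance in bp from the first base of the
    recognition motif to the cut on the top strand; it may exceed the motif
    length for downstream cutters such as MnlI.
    """

    name: str
    recognition: str
    cut_offset_top: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "recognition", iupac.validate(self.recognition, "recognition motif"))
        if self.cut_offset_top < 0:
            raise ValueError("cut_offset_top must be non-negative")


@dataclass(frozen=True)
class PrimerPair:
    """Forward (5'-labeled) and reverse primers bounding the amplicon."""

    forward: str
    reverse: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.forward or not self.reverse:
            raise ValueError("primer sequences must be non-empty")
        object.__setattr__(self, "forward", iupac.validate(self.forward, "forward primer"))
        object.__setattr__(self, "reverse", iupac.validate(self.reverse, "reverse primer"))


#: Standard recognition/cut data for the enzymes used in bacterial and
#: Planctomycetes fingerprinting.  User-overridable: pass your own Enzyme
#: objects anywhere an enzyme is accepted.
ENZYMES: dict[str, Enzyme] = {
    "HaeIII": Enzyme("HaeIII", "GGCC", 2),        # GG^CC
    "MspI": Enzyme("MspI", "CCGG", 1),            # C^CGG
    "MnlI": Enzyme("MnlI", "CCTC", 4 + 7),        # CCTC(7/6), top-strand cut 7 nt past motif
    "Hpy188I": Enzyme("Hpy188I", "TCNGA", 3),     # TCN^GA
}

#: The universal bacterial forward primer; the reverse bound is supplied by
#: the user (sequence not standardized here).
DEFAULT_FORWARD_27F = "AGAGTTTGATCMTGGCTCAG"


@dataclass(frozen=True)
class DigestPrediction:
    phylotype: str
    accession: str
    enzyme: str
    fragment_bp: float | None  # None encodes "uncut"
    primer_set: str = ""

    @property
    def is_cut(self) -> bool:
        return self.fragment_bp is not None

    def __post_init__(self) -> None:
        if self.fragment_bp is not None and self.fragment_bp <= 0:
            raise ValueError("fragment_bp must be positive when cut")


def find_primer_site(sequence: str, primer: str, max_mismatches: int = 0):
    """Locate the 5'-most forward-strand primer match.

    Returns ``(start, '+')`` for the left-most alignment with at most
    ``max_mismatches`` incompatible positions (IUPAC codes compared as
    sets), or ``None`` when the primer is absent.
    """
    if not primer:
        raise ValueError("primer must be non-empty")
    seq = iupac.validate(sequence)
    primer = iupac.validate(primer, "primer")
    for pos in range(len(seq) - len(primer) + 1):
        if iupac.mismatch_count(seq, primer, pos) <= max_mismatches:
            return pos, "+"
    return None


def _reverse_primer_bound(seq: str, primers: PrimerPair | None, start: int) -> int:
    """End of the amplicon: position just past the reverse-primer site, or len(seq)."""
    if primers is None:
        return len(seq)
    rc = iupac.reverse_complement(primers.reverse)
    for pos in range(start, len(seq) - len(rc) + 1):
        if iupac.mismatch_count(seq, rc, pos) == 0:
            return pos + len(rc)
    return len(seq)


def predict_trf(
    sequence: str,
    enzyme: Enzyme,
    primers: PrimerPair | None = None,
    anchor: Literal["primer", "sequence_start"] = "sequence_start",
    max_mismatches: int = 0,
) -> float | None:
    """Predicted labeled-fragment length in bp, or ``None`` for uncut.

    ``anchor="primer"`` anchors the labeled 5' end at the forward-primer
    start (requires the primer to be found); ``anchor="sequence_start"``
    anchors at position 0, appropriate for clone sequences that begin at
    the priming site.
    """
    seq = iupac.validate(sequence)
    if anchor == "primer":
        if primers is None:
            raise ValueError("anchor='primer' requires a PrimerPair")
        site = find_primer_site(seq, primers.forward, max_mismatches)
        if site is None:
            raise ValueError("forward primer not found in sequence")
        label_start = site[0]
    elif anchor == "sequence_start":
        label_start = 0
    else:
        raise ValueError(f"unknown anchor {anchor!r}")

    amplicon_end = _reverse_primer_bound(seq, primers, label_start)
    motif = enzyme.recognition
    for pos in range(label_start, amplicon_end - len(motif) + 1):
        if iupac.matches_at(seq, motif, pos):
            cut = pos + enzyme.cut_offset_top
            if cut <= amplicon_end:
                return float(cut - label_start)
            # cut site falls past the amplicon; fragment runs off the end
    return None


def digest_table(
    fasta,
    enzymes: Iterable[Enzyme] | None = None,
    primers: PrimerPair | None = None,
    anchor: Literal["primer", "sequence_start"] = "sequence_start",
    primer_set: str = "",
    accessions: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One :class:`DigestPrediction` row per sequence x enzyme.

    ``fasta`` may be a path or an iterable of Bio.SeqRecord objects.
    Columns: phylotype, accession, enzyme, fragment_bp ("uncut" when no
    site), primer_set.
    """
    if enzymes is None:
        enzymes = list(ENZYMES.values())
    if isinstance(fasta, (str, Path)):
        records: Sequence[SeqRecord] = list(SeqIO.parse(str(fasta), "fasta"))
    else:
        records = list(fasta)
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sequence ids: {dupes}")

    rows = []
    for rec in records:
        acc = (accessions or {}).get(rec.id, rec.id)
        for enz in enzymes:
            frag = predict_trf(str(rec.seq), enz, primers=primers, anchor=anchor)
            rows.append(
                {
                    "phylotype": rec.id,
                    "accession": acc,
                    "enzyme": enz.name,
                    "fragment_bp": UNCUT if frag is None else frag,
                    "primer_set": primer_set,
                }
            )
    return pd.DataFrame(rows, columns=["phylotype", "accession", "enzyme", "fragment_bp", "primer_set"])
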