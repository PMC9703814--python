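"""Promoter extraction and cis-regulatory element counting.

Promoters are the 2000 bp upstream of the annotated gene start (strand
aware, truncated at chromosome ends).  Elements are short IUPAC motifs
counted on both strands with overlaps allowed; a palindromic motif's
forward and reverse hits at one position count once.  The built-in library
covers the stress/hormone-responsive elements commonly scanned in plant
promoter surveys (ABA, MeJA, drought, low temperature, wounding); it is a
small documented set loaded from TSV, with no claim of equivalence to any
external prediction service.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .sequence_io import GeneRecord, reverse_complement

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

_RC = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def motif_reverse_complement(motif: str) -> str:
    return motif.translate(_RC)[::-1]


@dataclass(frozen=True)
class CisElement:
    name: str
    motif: str  # IUPAC nucleotide string
    category: str  # ABA | MeJA | drought | low-temperature | wound | other

    def __post_init__(self) -> None:
        if len(self.motif) < 4:
            raise ValueError(f"{self.name}: motif shorter than 4 bp")
        bad = set(self.motif.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.name}: invalid IUPAC codes {sorted(bad)}")


#: Default element library: canonical core motifs of widely used
#: stress/hormone-responsive plant cis-elements.
DEFAULT_ELEMENTS: tuple[CisElement, ...] = (
    CisElement("ABRE", "ACGTG", "ABA"),
    CisElement("ABRE-core", "CACGTG", "ABA"),
    CisElement("TGACG-motif", "TGACG", "MeJA"),
    CisElement("CGTCA-motif", "CGTCA", "MeJA"),
    CisElement("MBS", "CAACTG", "drought"),
    CisElement("LTR", "CCGAAA", "low-temperature"),
    CisElement("WUN-motif", "AAATTTCCT", "wound"),
)


def load_elements(path: str | Path) -> tuple[CisElement, ...]:
    """Load an element library from TSV columns name, motif, category."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return tuple(
        CisElement(row["name"], row.motif.upper(), row.category)
        for row in df.itertuples()
    )


def extract_promoters(
    genes: Sequence[GeneRecord],
    genome: Mapping[str, str],
    length: int = 2000,
) -> list[tuple[str, str]]:
    """Strand-aware upstream windows as (gene_id, sequence) records.

    Plus-strand genes take [start-length, start-1]; minus-strand genes take
    [end+1, end+length] reverse-complemented.  Windows are truncated at
    chromosome ends (never padded); a truncation is recorded in the returned
    sequence's length.
    """
    out = []
    for g in genes:
        if g.chromosome not in genome:
            raise ValueError(f"{g.gene_id}: chromosome {g.chromosome!r} not in genome")
        chrom = genome[g.chromosome]
        if g.strand == "-":
            lo = g.end  # 0-based slice start == 1-based end+1 - 1
            hi = min(g.end + length, len(chrom))
            seq = reverse_complement(chrom[lo:hi])
        else:
            lo = max(0, g.start - 1 - length)
            hi = g.start - 1
            seq = chrom[lo:hi]
        out.append((g.gene_id, seq))
    return out


def count_motif(seq: str, motif: str) -> int:
    """Occurrences of an IUPAC motif on both strands of *seq*.

    Overlapping hits count; at a position where both the motif and its
    reverse complement match (a palindrome), the hit counts once.
    """
    seq = seq.upper()
    motif = motif.upper()
    rc = motif_reverse_complement(motif)
    palindromic = rc == motif
    m = len(motif)
    count = 0
    for i in range(len(seq) - m + 1):
        window = seq[i : i + m]
        if all(b in IUPAC[p] for b, p in zip(window, motif)):
            count += 1
        if not palindromic and all(b in IUPAC[p] for b, p in zip(window, rc)):
            count += 1
    return count


def scan_elements(
    promoters: Sequence[tuple[str, str]],
    library: Sequence[CisElement] = DEFAULT_ELEMENTS,
) -> pd.DataFrame:
    """Hit-count table: genes as rows, element names as columns."""
    names = [e.name for e in library]
    rows = {}
    for gid, seq in promoters:
        rows[gid] = [count_motif(seq, e.motif) for e in library]
    return pd.DataFrame.from_dict(rows, orient="index", columns=names)


def category_summary(
    table: pd.DataFrame, library: Sequence[CisElement] = DEFAULT_ELEMENTS
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Per-gene per-category totals plus the argmax gene(s) per category.

    Categories with zero hits everywhere report an empty argmax list.
    """
    cats = sorted({e.category for e in library})
    by_cat = pd.DataFrame(0, index=table.index, columns=cats)
    for e in library:
        if e.name in table.columns:
            by_cat[e.category] = by_cat[e.category] + table[e.name]
    argmax: dict[str, list[str]] = {}
    for cat in cats:
        col = by_cat[cat]
        top = col.max() if len(col) else 0
        argmax[cat] = sorted(col.index[col == top]) if top > 0 else []
    return by_cat, argmax
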