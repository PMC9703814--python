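"""Reading, writing and normalising the sequence and gene-coordinate inputs.

Everything downstream operates on :class:`GeneRecord` objects: a gene
identifier tied to a protein sequence, optionally a CDS, and 1-based
inclusive genomic coordinates (GFF3 convention).  Intron counts and phases
are derived from the ordered CDS exon intervals of the primary transcript.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Data.CodonTable import standard_dna_table

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(cds: str) -> str:
    """Translate a CDS with the standard code; codons containing N give 'X'."""
    table = standard_dna_table.forward_table
    stops = set(standard_dna_table.stop_codons)
    aas = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        if codon in stops:
            aas.append("*")
        elif "N" in codon:
            aas.append("X")
        else:
            aas.append(table[codon])
    return "".join(aas)


@dataclass(frozen=True)
class GeneRecord:
    """One gene: sequences plus genomic location.

    Coordinates are 1-based inclusive on both ends.  ``exons`` holds CDS
    intervals in transcription order (descending genomic coordinates on the
    minus strand), each again 1-based inclusive.
    """

    gene_id: str
    protein_seq: str | None = None
    cds_seq: str | None = None
    chromosome: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None
    exons: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.start is not None and self.end is not None and self.start > self.end:
            raise ValueError(
                f"{self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand is not None and self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.cds_seq is not None and self.protein_seq is not None:
            self._check_cds_matches_protein()

    def _check_cds_matches_protein(self) -> None:
        cds = self.cds_seq
        if len(cds) % 3:
            raise ValueError(f"{self.gene_id}: CDS length {len(cds)} not divisible by 3")
        aa = translate_cds(cds)
        if aa.endswith("*"):
            aa = aa[:-1]
        if "*" in aa:
            raise ValueError(f"{self.gene_id}: internal stop codon in CDS")
        prot = self.protein_seq
        if len(aa) != len(prot):
            raise ValueError(
                f"{self.gene_id}: CDS translates to {len(aa)} aa, protein has {len(prot)}"
            )
        for i, (x, y) in enumerate(zip(aa, prot)):
            if x != y and x != "X" and y != "X":
                raise ValueError(
                    f"{self.gene_id}: CDS translation mismatch at residue {i + 1}"
                )

    @property
    def coding_cds(self) -> str:
        """CDS with any terminal stop codon trimmed."""
        cds = self.cds_seq
        if cds is None:
            raise ValueError(f"{self.gene_id}: no CDS")
        if len(cds) % 3 == 0 and cds[-3:] in standard_dna_table.stop_codons:
            return cds[:-3]
        return cds

    def with_coordinates(self, other: "GeneRecord") -> "GeneRecord":
        return replace(
            self,
            chromosome=other.chromosome,
            start=other.start,
            end=other.end,
            strand=other.strand,
            exons=other.exons,
        )


@dataclass(frozen=True)
class GeneModel:
    """Intron count and phases of one gene model."""

    gene_id: str
    intron_count: int
    intron_phases: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.intron_phases) != self.intron_count:
            raise ValueError("phase list length must equal intron count")
        if any(p not in (0, 1, 2) for p in self.intron_phases):
            raise ValueError("intron phases must be in {0,1,2}")


def read_fasta(path: str | Path, alphabet: str = "protein") -> list[tuple[str, str]]:
    """Parse a FASTA file into ``(id, sequence)`` pairs in file order.

    The record id is the first whitespace-delimited token of the header;
    sequences are uppercased and validated against *alphabet*
    (``protein`` or ``nucleotide``).
    """
    allowed = PROTEIN_ALPHABET if alphabet == "protein" else NUCLEOTIDE_ALPHABET
    if alphabet not in ("protein", "nucleotide"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    text = Path(path).read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty FASTA file")
    records: list[tuple[str, str]] = []
    name: str | None = None
    chunks: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                records.append((name, "".join(chunks)))
            name = line[1:].split()[0] if line[1:].split() else ""
            chunks = []
        else:
            if name is None:
                raise ValueError(f"{path}: sequence data before first header")
            chunks.append(line.upper())
    if name is not None:
        records.append((name, "".join(chunks)))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    for rid, seq in records:
        for pos, ch in enumerate(seq, start=1):
            if ch not in allowed:
                raise ValueError(
                    f"{path}: record {rid!r}: illegal {alphabet} character "
                    f"{ch!r} at position {pos}"
                )
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_GFF_ATTR_ID = re.compile(r"(?:^|;)\s*ID=([^;]+)")


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read gene coordinates from GFF3 or a 5-column TSV.

    The TSV dialect has columns gene_id, chrom, start, end, strand (header
    optional).  Both dialects yield 1-based inclusive coordinates.  When the
    GFF3 carries CDS features tied to a gene via ID/Parent attributes, the
    exon intervals are attached in transcription order.  Records are sorted
    by (chromosome, start); duplicate gene ids are an error.
    """
    path = Path(path)
    lines = [
        ln for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("#")
    ]
    is_gff = any(len(ln.split("\t")) >= 8 and ln.split("\t")[3].isdigit() for ln in lines[:5])
    records: dict[str, dict] = {}
    if is_gff:
        cds_by_parent: dict[str, list[tuple[int, int]]] = {}
        parent_of: dict[str, str] = {}
        for ln in lines:
            cols = ln.split("\t")
            if len(cols) < 9:
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = cols[:9]
            start_i, end_i = int(start), int(end)
            if ftype == "gene":
                m = _GFF_ATTR_ID.search(attrs)
                if not m:
                    raise ValueError(f"{path}: gene feature without ID attribute")
                gid = m.group(1)
                if gid in records:
                    raise ValueError(f"{path}: duplicate gene_id {gid!r}")
                if start_i > end_i:
                    raise ValueError(f"{path}: {gid}: start > end")
                records[gid] = dict(
                    chromosome=chrom, start=start_i, end=end_i, strand=strand
                )
            elif ftype == "mRNA":
                m = _GFF_ATTR_ID.search(attrs)
                pm = re.search(r"(?:^|;)\s*Parent=([^;]+)", attrs)
                if m and pm:
                    parent_of[m.group(1)] = pm.group(1)
            elif ftype == "CDS":
                pm = re.search(r"(?:^|;)\s*Parent=([^;]+)", attrs)
                if pm:
                    cds_by_parent.setdefault(pm.group(1), []).append((start_i, end_i))
        for parent, ivals in cds_by_parent.items():
            gid = parent_of.get(parent, parent)
            if gid in records:
                rec = records[gid]
                ivals = sorted(ivals)
                if rec["strand"] == "-":
                    ivals = ivals[::-1]
                rec["exons"] = tuple(ivals)
    else:
        header_skipped = False
        for ln in lines:
            cols = ln.split("\t")
            if len(cols) < 5:
                raise ValueError(f"{path}: expected 5 TSV columns, got {len(cols)}")
            if not header_skipped and not cols[2].lstrip("-").isdigit():
                header_skipped = True
                continue
            gid, chrom, start, end, strand = cols[:5]
            if gid in records:
                raise ValueError(f"{path}: duplicate gene_id {gid!r}")
            start_i, end_i = int(start), int(end)
            if start_i > end_i:
                raise ValueError(f"{path}: {gid}: start > end")
            records[gid] = dict(chromosome=chrom, start=start_i, end=end_i, strand=strand)
    out = [GeneRecord(gene_id=gid, **fields) for gid, fields in records.items()]
    out.sort(key=lambda r: (r.chromosome, r.start))
    return out


def gene_model_from_exons(record: GeneRecord) -> GeneModel:
    """Derive intron count and phases from the ordered CDS exon intervals.

    The phase of intron *i* is the cumulative coding length of the exons
    upstream of it modulo 3, a transcript-level quantity: exon order follows
    transcription, so minus-strand genes list exons by descending genomic
    coordinate.
    """
    if not record.exons:
        raise ValueError(f"{record.gene_id}: no exons recorded")
    lengths = [e - s + 1 for s, e in record.exons]
    phases = []
    cum = 0
    for length in lengths[:-1]:
        cum += length
        phases.append(cum % 3)
    return GeneModel(
        gene_id=record.gene_id,
        intron_count=len(lengths) - 1,
        intron_phases=tuple(phases),
    )


def build_records(
    proteins: Sequence[tuple[str, str]],
    cds: Sequence[tuple[str, str]] | None = None,
    gene_table: Sequence[GeneRecord] | None = None,
) -> list[GeneRecord]:
    """Join protein FASTA, CDS FASTA and coordinate table on gene id."""
    cds_map = dict(cds) if cds else {}
    coord_map = {r.gene_id: r for r in gene_table} if gene_table else {}
    out = []
    for gid, prot in proteins:
        coord = coord_map.get(gid)
        out.append(
            GeneRecord(
                gene_id=gid,
                protein_seq=prot,
                cds_seq=cds_map.get(gid),
                chromosome=coord.chromosome if coord else None,
                start=coord.start if coord else None,
                end=coord.end if coord else None,
                strand=coord.strand if coord else None,
                exons=coord.exons if coord else None,
            )
        )
    return out
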