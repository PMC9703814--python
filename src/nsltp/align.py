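"""Global protein alignment and codon back-threading.

Duplicate and ortholog detection both rest on exact Needleman–Wunsch global
alignment (BLOSUM62, affine gaps: open 10, extend 0.5) rather than a
heuristic seeded search — family members are short and homologous, and an
exact optimum makes every downstream call deterministic.  Identity is
computed over the aligned (both-non-gap) columns; coverage is the aligned
column count as a fraction of the longer input.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .sequence_io import translate_cds


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    identity_pct: float
    coverage_pct: float
    score: float

    def aligned_columns(self) -> int:
        return sum(
            1 for x, y in zip(self.aligned_a, self.aligned_b) if x != "-" and y != "-"
        )


def _make_aligner(open_penalty: float, extend_penalty: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    matrix = substitution_matrices.load("BLOSUM62")
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -open_penalty
    aligner.extend_gap_score = -extend_penalty
    return aligner


_DEFAULT_ALIGNER = _make_aligner(10.0, 0.5)


def global_align(
    a: str,
    b: str,
    open_penalty: float = 10.0,
    extend_penalty: float = 0.5,
) -> AlignmentResult:
    """Optimal global alignment of two protein sequences.

    Columns containing 'X' on either side count as mismatches for identity.
    Raises on empty input.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if open_penalty == 10.0 and extend_penalty == 0.5:
        aligner = _DEFAULT_ALIGNER
    else:
        aligner = _make_aligner(open_penalty, extend_penalty)
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    aligned = matches = 0
    for x, y in zip(sa, sb):
        if x != "-" and y != "-":
            aligned += 1
            if x == y and x != "X":
                matches += 1
    identity = 100.0 * matches / aligned if aligned else 0.0
    coverage = 100.0 * aligned / max(len(a), len(b))
    return AlignmentResult(
        aligned_a=sa,
        aligned_b=sb,
        identity_pct=identity,
        coverage_pct=coverage,
        score=float(aln.score),
    )


def thread_codons(
    aln: AlignmentResult, cds_a: str, cds_b: str
) -> tuple[list[tuple[str, str]], int]:
    """Back-thread two CDSs through a protein alignment.

    Returns one codon pair per both-non-gap protein column, in order, plus
    the count of pairs dropped because a codon contained N or was a stop.
    The CDSs must translate to the unaligned proteins (terminal stop codons
    may be present and are ignored).
    """
    a = aln.aligned_a.replace("-", "")
    b = aln.aligned_b.replace("-", "")
    for label, prot, cds in (("a", a, cds_a), ("b", b, cds_b)):
        aa = translate_cds(cds)
        if aa.endswith("*"):
            aa = aa[:-1]
        if len(aa) != len(prot) or any(
            x != y and x != "X" and y != "X" for x, y in zip(aa, prot)
        ):
            raise ValueError(f"CDS for sequence {label} does not translate to its protein")
    stops = {"TAA", "TAG", "TGA"}
    pairs: list[tuple[str, str]] = []
    dropped = 0
    ia = ib = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        ca = cds_a[3 * ia : 3 * ia + 3] if x != "-" else None
        cb = cds_b[3 * ib : 3 * ib + 3] if y != "-" else None
        if x != "-":
            ia += 1
        if y != "-":
            ib += 1
        if ca is None or cb is None:
            continue
        if "N" in ca or "N" in cb or ca in stops or cb in stops:
            dropped += 1
            continue
        pairs.append((ca, cb))
    return pairs, dropped
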