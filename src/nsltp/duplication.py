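"""Duplicate-pair calling and tandem/segmental classification.

A pair of family members is called duplicated when a global protein
alignment strictly exceeds 80% identity over the aligned region and the
aligned region covers strictly more than 80% of the longer sequence.  A
called pair is *tandem* when the two genes sit on the same chromosome and
are tightly linked — separated by at most ``tandem_max_separation`` bp of
intergenic span or by at most ``tandem_max_intervening`` annotated genes —
and *segmental* otherwise.  Within a tandem array only consecutive
neighbours are counted, so an array of k genes contributes k-1 duplication
events.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .align import global_align
from .sequence_io import GeneRecord

DEFAULT_MIN_IDENTITY = 80.0
DEFAULT_MIN_COVERAGE = 80.0
DEFAULT_TANDEM_MAX_SEPARATION = 100_000
DEFAULT_TANDEM_MAX_INTERVENING = 5


@dataclass(frozen=True)
class DuplicatePair:
    gene_a: str  # lexicographically smaller id
    gene_b: str
    identity_pct: float
    coverage_pct: float
    mode: str | None = None  # tandem | segmental
    type_label: str | None = None  # shared subfamily type or "mixed"

    def __post_init__(self) -> None:
        if self.gene_a >= self.gene_b:
            raise ValueError("gene_a must sort before gene_b")


def call_duplicates(
    records: Sequence[GeneRecord],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> list[DuplicatePair]:
    """All unordered pairs strictly exceeding both thresholds.

    Pairs are returned sorted by (gene_a, gene_b); modes are unset.
    """
    recs = [r for r in records if r.protein_seq]
    if len(recs) < 2:
        raise ValueError("need at least two records with protein sequences")
    pairs: list[DuplicatePair] = []
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            a, b = recs[i], recs[j]
            aln = global_align(a.protein_seq, b.protein_seq)
            if aln.identity_pct > min_identity and aln.coverage_pct > min_coverage:
                ga, gb = sorted((a.gene_id, b.gene_id))
                pairs.append(
                    DuplicatePair(
                        gene_a=ga,
                        gene_b=gb,
                        identity_pct=aln.identity_pct,
                        coverage_pct=aln.coverage_pct,
                    )
                )
    pairs.sort(key=lambda p: (p.gene_a, p.gene_b))
    return pairs


def _span_gap(a: GeneRecord, b: GeneRecord) -> int:
    """Intergenic distance between two gene spans (0 if they touch/overlap)."""
    left, right = (a, b) if a.start <= b.start else (b, a)
    return max(0, right.start - left.end - 1)


def _intervening_genes(
    a: GeneRecord, b: GeneRecord, all_genes: Sequence[GeneRecord]
) -> int:
    lo = min(a.end, b.end)
    hi = max(a.start, b.start)
    count = 0
    for g in all_genes:
        if g.gene_id in (a.gene_id, b.gene_id) or g.chromosome != a.chromosome:
            continue
        if g.start > lo and g.end < hi:
            count += 1
    return count


def classify_mode(
    pair: DuplicatePair,
    records: Mapping[str, GeneRecord],
    all_genes: Sequence[GeneRecord] | None = None,
    tandem_max_separation: int = DEFAULT_TANDEM_MAX_SEPARATION,
    tandem_max_intervening: int = DEFAULT_TANDEM_MAX_INTERVENING,
) -> DuplicatePair:
    """Set the pair's mode to tandem or segmental from genomic coordinates.

    *all_genes* is the full gene annotation used to count intervening genes;
    when omitted only the separation rule applies.
    """
    try:
        a = records[pair.gene_a]
        b = records[pair.gene_b]
    except KeyError as exc:
        raise ValueError(f"missing coordinates for gene {exc.args[0]!r}") from exc
    if a.chromosome is None or b.chromosome is None or a.start is None or b.start is None:
        raise ValueError(f"missing coordinates for pair {pair.gene_a}/{pair.gene_b}")
    tandem = False
    if a.chromosome == b.chromosome:
        if _span_gap(a, b) <= tandem_max_separation:
            tandem = True
        elif all_genes is not None and (
            _intervening_genes(a, b, all_genes) <= tandem_max_intervening
        ):
            tandem = True
    return replace(pair, mode="tandem" if tandem else "segmental")


def collapse_tandem_arrays(
    pairs: Sequence[DuplicatePair],
    records: Mapping[str, GeneRecord] | None = None,
) -> list[DuplicatePair]:
    """Reduce each tandem array to consecutive-neighbour events.

    Tandem pairs are grouped into connected components; a component of k
    genes is reported as the k-1 pairs of genomically consecutive members
    (one duplication event per neighbour step).  A consecutive pair absent
    from the input inherits the component's weakest identity/coverage as a
    conservative stand-in.  Segmental pairs pass through untouched.
    """
    tandem = [p for p in pairs if p.mode == "tandem"]
    out = [p for p in pairs if p.mode != "tandem"]

    # union-find over genes in tandem pairs
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for p in tandem:
        parent.setdefault(p.gene_a, p.gene_a)
        parent.setdefault(p.gene_b, p.gene_b)
        parent[find(p.gene_a)] = find(p.gene_b)

    components: dict[str, list[str]] = {}
    for g in parent:
        components.setdefault(find(g), []).append(g)

    stats = {(p.gene_a, p.gene_b): p for p in tandem}
    for members in components.values():
        if records is not None and all(
            g in records and records[g].start is not None for g in members
        ):
            members.sort(key=lambda g: records[g].start)
        else:
            members.sort()
        floor = min(
            (p for p in tandem if p.gene_a in members),
            key=lambda p: (p.identity_pct, p.coverage_pct),
        )
        for x, y in zip(members, members[1:]):
            key = tuple(sorted((x, y)))
            if key in stats:
                out.append(stats[key])
            else:
                out.append(
                    DuplicatePair(
                        gene_a=key[0],
                        gene_b=key[1],
                        identity_pct=floor.identity_pct,
                        coverage_pct=floor.coverage_pct,
                        mode="tandem",
                        type_label=floor.type_label,
                    )
                )
    out.sort(key=lambda p: (p.gene_a, p.gene_b))
    return out


def shared_type_label(
    pair: DuplicatePair, assignments: Mapping[str, str]
) -> DuplicatePair:
    """Annotate the pair with its subfamily type, or "mixed" when they differ."""
    ta = assignments.get(pair.gene_a, "unclassified")
    tb = assignments.get(pair.gene_b, "unclassified")
    return replace(pair, type_label=ta if ta == tb else "mixed")
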