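"""Reciprocal-best-hit (RBH) orthology between two species' families.

Each gene's best hit in the other species is the maximum global-alignment
score (ties resolved to the lexicographically smallest id); a pair is kept
only when the choice is reciprocal, giving at most one partner per gene.
A minimum-score floor discards spurious best hits between unrelated sets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .align import global_align
from .kaks import ClockConfig, KaKsResult, kaks_report
from .sequence_io import GeneRecord


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str  # species A
    gene_b: str  # species B
    score: float
    type_label: str | None = None
    kaks: KaKsResult | None = None


def reciprocal_best_hits(
    set_a: Sequence[GeneRecord],
    set_b: Sequence[GeneRecord],
    min_score: float = 0.0,
) -> list[OrthologPair]:
    """One-to-one ortholog pairs by reciprocal best alignment score."""
    if not set_a or not set_b:
        raise ValueError("both gene sets must be non-empty")
    scores: dict[tuple[str, str], float] = {}
    for a in set_a:
        for b in set_b:
            scores[(a.gene_id, b.gene_id)] = global_align(
                a.protein_seq, b.protein_seq
            ).score

    def best(gid: str, others: Sequence[GeneRecord], forward: bool) -> str | None:
        get = (lambda o: scores[(gid, o.gene_id)]) if forward else (
            lambda o: scores[(o.gene_id, gid)]
        )
        candidates = [(o.gene_id, get(o)) for o in others]
        top = max(s for _, s in candidates)
        if top < min_score:
            return None
        return min(g for g, s in candidates if s == top)

    best_in_b = {a.gene_id: best(a.gene_id, set_b, True) for a in set_a}
    best_in_a = {b.gene_id: best(b.gene_id, set_a, False) for b in set_b}
    pairs = [
        OrthologPair(
            gene_a=ga, gene_b=gb, score=scores[(ga, gb)]
        )
        for ga, gb in best_in_b.items()
        if gb is not None and best_in_a.get(gb) == ga
    ]
    pairs.sort(key=lambda p: p.gene_a)
    return pairs


def annotate_types(
    pairs: Sequence[OrthologPair],
    types_a: Mapping[str, str],
    types_b: Mapping[str, str],
) -> list[OrthologPair]:
    out = []
    for p in pairs:
        ta = types_a.get(p.gene_a, "unclassified")
        tb = types_b.get(p.gene_b, "unclassified")
        out.append(replace(p, type_label=ta if ta == tb else "mixed"))
    return out


def ortholog_kaks(
    pairs: Sequence[OrthologPair],
    records_a: Mapping[str, GeneRecord],
    records_b: Mapping[str, GeneRecord],
    clock: ClockConfig = ClockConfig(),
) -> tuple[list[OrthologPair], dict[str, int]]:
    """Attach a Ka/Ks report to each pair and tally the selection summary.

    Returns the annotated pairs plus counts of pairs under ratio < 1,
    ratio >= 1, and with undefined ratio (Ks == 0).
    """
    annotated: list[OrthologPair] = []
    summary = {"purifying": 0, "non_purifying": 0, "undefined": 0}
    for p in pairs:
        ra, rb = records_a[p.gene_a], records_b[p.gene_b]
        result = kaks_report(
            ra.protein_seq, rb.protein_seq, ra.coding_cds, rb.coding_cds, clock
        )
        annotated.append(replace(p, kaks=result))
        if result.ratio is None:
            summary["undefined"] += 1
        elif result.ratio < 1.0:
            summary["purifying"] += 1
        else:
            summary["non_purifying"] += 1
    return annotated, summary
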