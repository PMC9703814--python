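"""Spacing-grammar classification of nsLTPs into subfamily types.

The Boutrot-style types are distinguished by the admissible spacer lengths
of the 8CM.  The built-in grammar transcribes the spacing patterns observed
in the foxtail-millet family (Types I, II, IV, V and VI); additional type
slots (III, VII, VIII, IX occur in other species) can be loaded from a TSV
config.  A match classifies as a type only when every variable gap lies in
that type's allowed set (score 0) unless ``max_score`` is raised.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .motif import VARIABLE_GAPS, EightCMMatch

HYDROPHILIC_X = frozenset("RGENSTK")
HYDROPHOBIC_X = frozenset("LIFVM")


@dataclass(frozen=True)
class SpacingPattern:
    """Allowed integer spacer sets for one subfamily type."""

    type_label: str
    allowed: Mapping[str, frozenset[int]]

    def __post_init__(self) -> None:
        for name in VARIABLE_GAPS:
            if name not in self.allowed or not self.allowed[name]:
                raise ValueError(f"{self.type_label}: empty allowed set for {name}")


def _sets(**kw: Iterable[int]) -> dict[str, frozenset[int]]:
    return {k: frozenset(v) for k, v in kw.items()}


#: Spacing grammar of the five subfamilies present in foxtail millet.
TABLE1_PATTERNS: tuple[SpacingPattern, ...] = (
    SpacingPattern("I", _sets(
        n0={2, 3, 8}, g1={9}, g2={13, 14, 15}, g4={19},
        g6=set(range(21, 26)), g7={13}, n8={4, 7},
    )),
    SpacingPattern("II", _sets(
        n0={2, 3, 7, 8, 9}, g1={7}, g2={12, 13}, g4={8, 9, 10},
        g6={23, 24}, g7={6}, n8={0},
    )),
    SpacingPattern("IV", _sets(
        n0={1, 5}, g1={9}, g2={16, 17}, g4={9},
        g6={21, 24, 26}, g7={7, 8}, n8={0, 1, 3},
    )),
    SpacingPattern("V", _sets(
        n0={3, 5, 9}, g1={14}, g2={14}, g4={11, 12, 13},
        g6={24}, g7={10}, n8={6, 10},
    )),
    SpacingPattern("VI", _sets(
        n0={1, 3, 7, 10, 16}, g1={10}, g2={16, 17, 18}, g4={9, 10, 11},
        g6={20, 22, 23}, g7={7, 9}, n8={5, 6, 7, 8, 11, 16, 19},
    )),
)


def parse_allowed(text: str) -> frozenset[int]:
    """Parse an allowed-set string: comma lists ('2,3,8') and ranges ('13-15')."""
    out: set[int] = set()
    for part in text.split(","):
        part = part.strip()
        if "-" in part[1:]:
            lo, hi = part.split("-")
            out.update(range(int(lo), int(hi) + 1))
        elif part:
            out.add(int(part))
    return frozenset(out)


def load_patterns(path: str | Path) -> tuple[SpacingPattern, ...]:
    """Load a pattern grammar from TSV columns type_label, gap_name, allowed."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    patterns = []
    for label, grp in df.groupby("type_label", sort=False):
        allowed = {
            row.gap_name: parse_allowed(row.allowed) for row in grp.itertuples()
        }
        patterns.append(SpacingPattern(str(label), allowed))
    return tuple(patterns)


@dataclass(frozen=True)
class TypeAssignment:
    gene_id: str
    type_label: str  # a type label or "unclassified"
    score: int
    x_residue_class: str  # hydrophilic | hydrophobic | other
    x_residue: str = ""


def score_pattern(match: EightCMMatch, pattern: SpacingPattern) -> int:
    """Total distance of a match's spacing from a pattern.

    Sums, over the seven variable gaps, the distance from the observed gap
    to the nearest value in the pattern's allowed set; 0 means every gap is
    admissible.
    """
    total = 0
    for name, value in zip(VARIABLE_GAPS, match.variable_spacing()):
        allowed = pattern.allowed[name]
        total += min(abs(value - a) for a in allowed)
    return total


def classify_x_residue(x: str) -> str:
    if x in HYDROPHILIC_X:
        return "hydrophilic"
    if x in HYDROPHOBIC_X:
        return "hydrophobic"
    return "other"


def assign_type(
    match: EightCMMatch,
    gene_id: str = "",
    patterns: Sequence[SpacingPattern] = TABLE1_PATTERNS,
    max_score: int = 0,
) -> TypeAssignment:
    """Assign the minimum-score pattern, or "unclassified".

    A match is unclassified when its best score exceeds *max_score* or when
    two different type labels tie at the best score.
    """
    if not patterns:
        raise ValueError("no spacing patterns supplied")
    scores = [(score_pattern(match, p), p.type_label) for p in patterns]
    best = min(s for s, _ in scores)
    best_labels = sorted({lab for s, lab in scores if s == best})
    if best > max_score or len(best_labels) > 1:
        label = "unclassified"
    else:
        label = best_labels[0]
    return TypeAssignment(
        gene_id=gene_id,
        type_label=label,
        score=best,
        x_residue_class=classify_x_residue(match.x_residue),
        x_residue=match.x_residue,
    )


def family_summary(assignments: Sequence[TypeAssignment]) -> pd.DataFrame:
    """Per-type composition of the family.

    Returns a DataFrame indexed by type label with columns ``count`` and
    ``percent`` (rounded to the nearest integer percent of all genes,
    unclassified included in the denominator).
    """
    if not assignments:
        raise ValueError("no assignments to summarise")
    counts = Counter(a.type_label for a in assignments)
    total = sum(counts.values())
    rows = {
        label: (n, round(100 * n / total))
        for label, n in sorted(counts.items())
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=["count", "percent"])


def hydrophobic_x_frequencies(assignments: Sequence[TypeAssignment]) -> pd.DataFrame:
    """Residue frequencies among hydrophobic CXC-core X positions.

    Reports, for each hydrophobic residue observed between Cys5 and Cys6,
    its count and percentage of all hydrophobic X positions (the statistic
    behind the family-wide Leu dominance).
    """
    hydro = [a.x_residue for a in assignments if a.x_residue_class == "hydrophobic"]
    counts = Counter(hydro)
    total = sum(counts.values())
    rows = {
        res: (n, 100 * n / total)
        for res, n in counts.most_common()
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=["count", "percent"])
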