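"""Eight-cysteine-motif (8CM) detection.

Plant nsLTPs carry a conserved backbone of eight cysteines,
C-Xn-C-Xn-CC-CXC-Xn-C-Xn-C: Cys3/Cys4 are adjacent (the CC doublet) and
Cys5/Cys6 flank exactly one residue (the CXC core).  The remaining spacers
vary by subfamily; the scanner enumerates every assignment of eight
cysteine positions that satisfies the structural constraints and a set of
per-gap bounds, by depth-first search with per-gap pruning.
"""

from __future__ import annotations

from dataclasses import dataclass

from .sequence_io import PROTEIN_ALPHABET

#: The nine spacer slots of a motif occurrence, in N->C order: residues
#: before Cys1 (n0), the seven inter-cysteine gaps g1..g7, residues after
#: Cys8 (n8).  g3 (the CC doublet) is always 0 and g5 (CXC) always 1.
GAP_NAMES = ("n0", "g1", "g2", "g3", "g4", "g5", "g6", "g7", "n8")

#: The gaps that vary between subfamilies (g3 and g5 are structural).
VARIABLE_GAPS = ("n0", "g1", "g2", "g4", "g6", "g7", "n8")


@dataclass(frozen=True)
class EightCMMatch:
    """One placement of the 8CM on a mature peptide.

    ``cys_positions`` are 0-based indices of the eight cysteines, ascending.
    ``spacing`` is the 9-vector (n0, g1..g7, n8); inter-cysteine gaps are
    position differences minus one.  ``x_residue`` is the single residue of
    the CXC core, whose hydrophobicity separates subfamilies.
    """

    cys_positions: tuple[int, ...]
    spacing: tuple[int, ...]
    x_residue: str

    def variable_spacing(self) -> tuple[int, ...]:
        """The 7 subfamily-diagnostic gaps (n0, g1, g2, g4, g6, g7, n8)."""
        s = self.spacing
        return (s[0], s[1], s[2], s[4], s[6], s[7], s[8])


@dataclass(frozen=True)
class ScanBounds:
    """Inclusive (min, max) bounds for each variable gap.

    Defaults are the element-wise union of the five subfamily spacing
    patterns observed in the foxtail-millet family, so the default scan
    admits any sequence matching at least one subfamily pattern.
    """

    n0: tuple[int, int] = (1, 16)
    g1: tuple[int, int] = (7, 14)
    g2: tuple[int, int] = (12, 18)
    g4: tuple[int, int] = (8, 19)
    g6: tuple[int, int] = (20, 26)
    g7: tuple[int, int] = (6, 13)
    n8: tuple[int, int] = (0, 19)

    def __post_init__(self) -> None:
        for name in VARIABLE_GAPS:
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"bound {name}: min {lo} > max {hi}")

    def widened(self, slack: int) -> "ScanBounds":
        """Every bound widened by ±slack (lower bounds floored at 0)."""
        kw = {}
        for name in VARIABLE_GAPS:
            lo, hi = getattr(self, name)
            kw[name] = (max(0, lo - slack), hi + slack)
        return ScanBounds(**kw)


def _spacing_from_positions(seq_len: int, pos: tuple[int, ...]) -> tuple[int, ...]:
    gaps = tuple(pos[i + 1] - pos[i] - 1 for i in range(7))
    return (pos[0],) + gaps + (seq_len - 1 - pos[7],)


def scan_8cm(mature_seq: str, bounds: ScanBounds | None = None) -> list[EightCMMatch]:
    """Find every 8CM placement in *mature_seq* satisfying *bounds*.

    Returns matches sorted lexicographically by cysteine positions; an empty
    list when no valid assignment exists.  Overlapping/alternative
    placements are all reported — use :func:`best_match` to disambiguate.
    """
    if bounds is None:
        bounds = ScanBounds()
    seq = mature_seq.upper()
    bad = set(seq) - PROTEIN_ALPHABET
    if bad:
        raise ValueError(f"non-amino-acid characters in sequence: {sorted(bad)}")
    cys = [i for i, ch in enumerate(seq) if ch == "C"]
    n = len(seq)
    if n < 8 or len(cys) < 8:
        return []

    # gap constraint between consecutive chosen cysteines, indexed 1..7
    gap_bounds = {
        1: bounds.g1,
        2: bounds.g2,
        3: (0, 0),
        4: bounds.g4,
        5: (1, 1),
        6: bounds.g6,
        7: bounds.g7,
    }
    n0_lo, n0_hi = bounds.n0
    n8_lo, n8_hi = bounds.n8

    matches: list[EightCMMatch] = []
    chosen: list[int] = []

    def extend(next_idx: int) -> None:
        depth = len(chosen)
        if depth == 8:
            tail = n - 1 - chosen[-1]
            if n8_lo <= tail <= n8_hi:
                pos = tuple(chosen)
                matches.append(
                    EightCMMatch(
                        cys_positions=pos,
                        spacing=_spacing_from_positions(n, pos),
                        x_residue=seq[pos[4] + 1],
                    )
                )
            return
        for k in range(next_idx, len(cys)):
            p = cys[k]
            if depth == 0:
                if p < n0_lo:
                    continue
                if p > n0_hi:
                    break
            else:
                gap = p - chosen[-1] - 1
                lo, hi = gap_bounds[depth]
                if gap < lo:
                    continue
                if gap > hi:
                    break
            chosen.append(p)
            extend(k + 1)
            chosen.pop()

    extend(0)
    matches.sort(key=lambda m: m.cys_positions)
    return matches


def best_match(
    matches: list[EightCMMatch], patterns=None
) -> EightCMMatch | None:
    """Pick the match closest to a known subfamily spacing pattern.

    Minimises the best pattern score (see :func:`nsltp.classify.score_pattern`);
    ties break on lexicographically smallest cysteine positions.  Returns
    ``None`` for an empty list.
    """
    if not matches:
        return None
    from .classify import TABLE1_PATTERNS, score_pattern

    if patterns is None:
        patterns = TABLE1_PATTERNS
    return min(
        matches,
        key=lambda m: (min(score_pattern(m, p) for p in patterns), m.cys_positions),
    )
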