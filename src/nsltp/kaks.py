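"""Nei–Gojobori (1986) Ka/Ks estimation and molecular-clock dating.

The method counts, for each codon, the fraction of single-nucleotide
changes that are synonymous (the codon's synonymous *sites*, with changes
to stop codons excluded from the denominator), averages site totals over
the two sequences, counts pathway-averaged synonymous/nonsynonymous
*differences* per codon pair, converts the proportions ps = Sd/S and
pn = Nd/N to distances with the Jukes–Cantor correction

    K = -(3/4) * ln(1 - (4/3) p),

and dates a duplication with the synonymous clock t = Ks / (2 r), where r
is the neutral substitution rate per synonymous site per year.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

from Bio.Data.CodonTable import standard_dna_table

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_STOPS = frozenset(standard_dna_table.stop_codons)
_CODE = dict(standard_dna_table.forward_table)

#: Default neutral substitution rate (substitutions per synonymous site per
#: year) used for grass nuclear genes.
DEFAULT_CLOCK_RATE = 6.5e-9


@dataclass(frozen=True)
class ClockConfig:
    """Molecular-clock rate r, substitutions per synonymous site per year."""

    r: float = DEFAULT_CLOCK_RATE

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("clock rate r must be positive")


@dataclass(frozen=True)
class KaKsResult:
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    Ks: float
    Ka: float
    ratio: float | None  # None when Ks == 0 (ratio undefined)
    purifying: bool | None
    n_codon_pairs: int
    dropped_pairs: int = 0
    age_mya: float | None = None


def _amino(codon: str) -> str:
    return _CODE[codon]


def _check_codon(codon: str) -> None:
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"ambiguous or malformed codon {codon!r}")
    if codon in _STOPS:
        raise ValueError(f"stop codon {codon!r} has no defined site counts")


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts (s, n) of one sense codon.

    At each of the three positions the fraction of single-base changes that
    preserve the amino acid is counted; mutations creating a stop codon are
    excluded from that position's denominator.  s + n == 3 exactly.
    """
    _check_codon(codon)
    aa = _amino(codon)
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in _STOPS:
                continue
            valid += 1
            if _amino(mut) == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


@lru_cache(maxsize=None)
def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous differences (sd, nd).

    For codons differing at k positions, every order of introducing the k
    changes is a mutational pathway; each single-base step is classified as
    synonymous or nonsynonymous and the per-step counts are averaged over
    pathways.  Pathways passing through a stop codon are excluded and the
    average renormalised over the rest; if every pathway hits a stop the
    unnormalised average over all pathways is used (with a warning), so a
    difference count is always returned.
    """
    _check_codon(codon_a)
    _check_codon(codon_b)
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    k = len(diff_positions)
    if k == 0:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    all_paths: list[tuple[int, int]] = []
    for order in itertools.permutations(diff_positions):
        current = codon_a
        sd = nd = 0
        hit_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in _STOPS or current in _STOPS:
                # steps into or out of a stop are nonsynonymous by definition
                hit_stop = hit_stop or nxt in _STOPS
                nd += 1
            elif _amino(current) == _amino(nxt):
                sd += 1
            else:
                nd += 1
            current = nxt
        all_paths.append((sd, nd))
        if not hit_stop:
            valid.append((sd, nd))
    paths = valid
    if not paths:
        logger.warning(
            "all mutational pathways between %s and %s pass through stop codons; "
            "averaging over all pathways unnormalised",
            codon_a,
            codon_b,
        )
        paths = all_paths
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor multiple-hit correction of a proportion of differences."""
    if p >= 0.75:
        raise ValueError(
            f"Jukes-Cantor correction undefined (saturation): p = {p:.4f} >= 0.75"
        )
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ratio_from_rates(ka: float, ks: float) -> float | None:
    """The Ka/Ks selection ratio; ``None`` (undefined) when Ks == 0."""
    if ks == 0:
        return None
    return ka / ks


def ng86(pairs: Sequence[tuple[str, str]], dropped: int = 0) -> KaKsResult:
    """NG86 estimate over a list of aligned codon pairs.

    Site totals are the average of the two sequences' per-codon sums;
    proportions ps, pn convert to Ks, Ka via Jukes–Cantor.  The ratio is
    flagged undefined (``None``) when Ks == 0.
    """
    if not pairs:
        raise ValueError("no codon pairs to analyse")
    Sa = Na = Sb = Nb = 0.0
    Sd = Nd = 0.0
    for ca, cb in pairs:
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        Sa += sa
        Na += na
        Sb += sb
        Nb += nb
        sd, nd = pathway_differences(ca, cb)
        Sd += sd
        Nd += nd
    S = (Sa + Sb) / 2.0
    N = (Na + Nb) / 2.0
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    Ks = jukes_cantor(ps)
    Ka = jukes_cantor(pn)
    ratio = ratio_from_rates(Ka, Ks)
    purifying = ratio < 1.0 if ratio is not None else None
    return KaKsResult(
        S_sites=S,
        N_sites=N,
        Sd=Sd,
        Nd=Nd,
        ps=ps,
        pn=pn,
        Ks=Ks,
        Ka=Ka,
        ratio=ratio,
        purifying=purifying,
        n_codon_pairs=len(pairs),
        dropped_pairs=dropped,
    )


def divergence_age(Ks: float, clock: ClockConfig = ClockConfig()) -> float:
    """Age of a duplication in million years: t = Ks / (2 r) / 1e6."""
    if Ks < 0:
        raise ValueError("Ks must be non-negative")
    return Ks / (2.0 * clock.r) / 1e6


def kaks_report(
    protein_a: str,
    protein_b: str,
    cds_a: str,
    cds_b: str,
    clock: ClockConfig = ClockConfig(),
) -> KaKsResult:
    """Full per-pair pipeline: align proteins, thread codons, NG86, date.

    Terminal stop codons on the CDSs are trimmed before threading.
    """
    from .align import global_align, thread_codons

    aln = global_align(protein_a, protein_b)
    cds_a = _trim_stop(cds_a)
    cds_b = _trim_stop(cds_b)
    pairs, dropped = thread_codons(aln, cds_a, cds_b)
    result = ng86(pairs, dropped=dropped)
    age = divergence_age(result.Ks, clock)
    return KaKsResult(**{**result.__dict__, "age_mya": age})


def _trim_stop(cds: str) -> str:
    if len(cds) % 3 == 0 and cds[-3:] in _STOPS:
        return cds[:-3]
    return cds
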