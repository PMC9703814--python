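"""Labelled synthetic fixtures for every pipeline stage.

Each generator emits data with the statistical structure its consumer
assumes, together with a machine-readable truth table, so recovery can be
asserted without any external downloads.  All generators are deterministic
for a fixed seed.

What is emulated (and what is not): protein families obeying the subfamily
spacing grammar with optional +-1 spacer noise; codon pairs with controlled
synonymous/nonsynonymous divergence on the NG86 scale; genome layouts with
tandem arrays and segmental duplicate pairs among unrelated filler genes;
promoters with planted cis-elements on a motif-free background; and
tissue-blocked FPKM matrices with lognormal noise.  Real genome base
composition, codon usage and chromosome sizes are not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import HYDROPHILIC_X, TABLE1_PATTERNS, SpacingPattern
from .expression import ExpressionMatrix, QpcrMeasurement
from .kaks import codon_sites
from .motif import VARIABLE_GAPS
from .promoter import DEFAULT_ELEMENTS, CisElement, count_motif, motif_reverse_complement
from .sequence_io import GeneRecord, reverse_complement, translate_cds

_NON_CYS = "ADEFGHIKLMNPQRSTVWY"  # 19 standard residues minus C
_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
)

# hydrophobic CXC-core residues, Leu weighted highest as in real families
_HYDROPHOBIC_WEIGHTS = (("L", 0.60), ("I", 0.12), ("F", 0.12), ("V", 0.10), ("M", 0.06))


@dataclass(frozen=True)
class FamilySpec:
    """Composition of a synthetic nsLTP family.

    Default counts mirror a realistic five-subfamily family (14 Type I,
    9 Type II, 6 Type IV, 5 Type V, 8 Type VI).
    """

    type_counts: Mapping[str, int] = field(
        default_factory=lambda: {"I": 14, "II": 9, "IV": 6, "V": 5, "VI": 8}
    )
    spacing_noise: float = 0.0  # probability a gap is perturbed +-1 off-pattern
    residue_divergence: float = 0.10  # per-residue substitution rate within a type
    decoy_count: int = 0
    seed: int = 0


def _pattern_by_label(label: str) -> SpacingPattern:
    for p in TABLE1_PATTERNS:
        if p.type_label == label:
            return p
    raise ValueError(f"no built-in spacing pattern for type {label!r}")


def _draw_x_residue(label: str, rng: np.random.Generator) -> str:
    if label == "I":
        return str(rng.choice(sorted(HYDROPHILIC_X)))
    residues, weights = zip(*_HYDROPHOBIC_WEIGHTS)
    return str(rng.choice(residues, p=weights))


def _type_prototype(pattern: SpacingPattern, rng: np.random.Generator) -> dict[str, str]:
    """Per-gap prototype spacer residues, one stream per variable gap.

    Family members of a type share these residues (up to per-member
    substitutions), giving the within-type sequence similarity real
    subfamilies show.
    """
    return {
        gap: "".join(rng.choice(list(_NON_CYS), size=max(pattern.allowed[gap]) + 2))
        for gap in VARIABLE_GAPS
    }


def _sequence_from_spacing(
    spacing7: Sequence[int],
    x_residue: str,
    rng: np.random.Generator,
    prototype: Mapping[str, str] | None = None,
    divergence: float = 0.0,
) -> str:
    """Assemble a protein from the 7 variable gaps and the CXC-core residue."""
    values = dict(zip(VARIABLE_GAPS, spacing7))

    def fill(gap: str) -> str:
        k = values[gap]
        if not k:
            return ""
        if prototype is None:
            return "".join(rng.choice(list(_NON_CYS), size=k))
        base = list(prototype[gap][:k])
        while len(base) < k:  # noise pushed a gap beyond the prototype
            base.append(str(rng.choice(list(_NON_CYS))))
        for i in range(k):
            if divergence and rng.random() < divergence:
                base[i] = str(rng.choice([c for c in _NON_CYS if c != base[i]]))
        return "".join(base)

    return (
        fill("n0") + "C" + fill("g1") + "C" + fill("g2") + "CC" + fill("g4")
        + "C" + x_residue + "C" + fill("g6") + "C" + fill("g7") + "C" + fill("n8")
    )


def gen_family(spec: FamilySpec) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate a type-labelled protein family plus decoys.

    Returns FASTA-style records and a truth table with columns gene_id,
    true_type, the seven variable gaps, and x_residue.  Decoys are random
    proteins with fewer than eight cysteines (hence no motif).
    """
    rng = np.random.default_rng(spec.seed)
    records: list[tuple[str, str]] = []
    rows = []
    idx = 0
    for label in sorted(spec.type_counts):
        pattern = _pattern_by_label(label)
        prototype = _type_prototype(pattern, rng)
        for _ in range(spec.type_counts[label]):
            idx += 1
            gid = f"LTP{idx:03d}"
            spacing = []
            for gap in VARIABLE_GAPS:
                value = int(rng.choice(sorted(pattern.allowed[gap])))
                if spec.spacing_noise and rng.random() < spec.spacing_noise:
                    step = int(rng.choice([-1, 1]))
                    value = max(0, value + step)
                spacing.append(value)
            x = _draw_x_residue(label, rng)
            seq = _sequence_from_spacing(
                spacing, x, rng, prototype, spec.residue_divergence
            )
            records.append((gid, seq))
            rows.append(
                dict(
                    gene_id=gid,
                    true_type=label,
                    **dict(zip(VARIABLE_GAPS, spacing)),
                    x_residue=x,
                )
            )
    for _ in range(spec.decoy_count):
        idx += 1
        gid = f"DEC{idx:03d}"
        length = int(rng.integers(70, 130))
        n_cys = int(rng.integers(0, 8))  # strictly fewer than 8 cysteines
        seq = list(rng.choice(list(_NON_CYS), size=length))
        for pos in rng.choice(length, size=n_cys, replace=False):
            seq[pos] = "C"
        records.append((gid, "".join(seq)))
        rows.append(
            dict(
                gene_id=gid,
                true_type="decoy",
                **{g: -1 for g in VARIABLE_GAPS},
                x_residue="",
            )
        )
    return records, pd.DataFrame(rows)


@dataclass(frozen=True)
class DivergenceSpec:
    """Target NG86-scale divergence of one codon pair."""

    n_codons: int
    ka: float
    ks: float
    seed: int = 0


def _p_from_k(k: float) -> float:
    """Invert the Jukes-Cantor correction: expected difference proportion."""
    return 0.75 * (1.0 - math.exp(-4.0 * k / 3.0))


@lru_cache(maxsize=None)
def _syn_mutants(codon: str) -> tuple[str, ...]:
    aa = translate_cds(codon)
    out = []
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut not in _STOPS and translate_cds(mut) == aa:
                out.append(mut)
    return tuple(out)


@lru_cache(maxsize=None)
def _nonsyn_mutants(codon: str) -> tuple[str, ...]:
    aa = translate_cds(codon)
    out = []
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut not in _STOPS and translate_cds(mut) != aa:
                out.append(mut)
    return tuple(out)


def gen_codon_pair(spec: DivergenceSpec) -> tuple[str, str, dict[str, float]]:
    """A stop-free CDS pair with planted synonymous/nonsynonymous divergence.

    A random ancestral CDS receives Poisson-distributed numbers of
    synonymous and nonsynonymous single-base edits (expected counts ps*S
    and pn*N with ps, pn the Jukes-Cantor inverses of the targets), at most
    one edit per codon and never creating a stop, so NG86 pathway counting
    classifies every planted difference exactly.  Returns (cds_a, cds_b,
    realized) where realized records the planted difference counts and site
    totals of the ancestral sequence.
    """
    ps = _p_from_k(spec.ks)
    pn = _p_from_k(spec.ka)
    if ps >= 0.7 or pn >= 0.7:
        raise ValueError("requested divergence is saturated (p >= 0.7)")
    rng = np.random.default_rng(spec.seed)
    codons = [str(rng.choice(_SENSE_CODONS)) for _ in range(spec.n_codons)]
    S = sum(codon_sites(c)[0] for c in codons)
    N = sum(codon_sites(c)[1] for c in codons)
    n_syn = int(rng.poisson(ps * S))
    n_nonsyn = int(rng.poisson(pn * N))
    syn_eligible = [i for i, c in enumerate(codons) if _syn_mutants(c)]
    if n_syn > len(syn_eligible) or n_syn + n_nonsyn > spec.n_codons:
        raise ValueError("requested divergence too high for sequence length")
    mutated = list(codons)
    syn_sites = rng.choice(len(syn_eligible), size=n_syn, replace=False)
    edited = {syn_eligible[i] for i in syn_sites}
    for i in sorted(edited):
        mutated[i] = str(rng.choice(_syn_mutants(codons[i])))
    remaining = [i for i in range(spec.n_codons) if i not in edited]
    nonsyn_sites = rng.choice(len(remaining), size=n_nonsyn, replace=False)
    for i in sorted(remaining[j] for j in nonsyn_sites):
        mutated[i] = str(rng.choice(_nonsyn_mutants(codons[i])))
    realized = {
        "Sd": float(n_syn),
        "Nd": float(n_nonsyn),
        "S_sites_ancestral": float(S),
        "N_sites_ancestral": float(N),
    }
    return "".join(codons), "".join(mutated), realized


@dataclass(frozen=True)
class GenomeLayoutSpec:
    """Planted duplication structure of a synthetic genome."""

    chromosome_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 1_200_000, "chr2": 1_200_000, "chr3": 1_200_000}
    )
    tandem_arrays: tuple[tuple[str, int, int], ...] = ()  # (chrom, size, spacing bp)
    segmental_pairs: tuple[tuple[str, str], ...] = ()  # (chrom_a, chrom_b)
    filler_gene_count: int = 0
    gene_codons: int = 200
    duplicate_ks: float = 0.20
    duplicate_ka: float = 0.02
    seed: int = 0


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_SENSE_CODONS) for _ in range(n_codons))


def _apply_divergence(cds: str, ka: float, ks: float, rng: np.random.Generator) -> str:
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    ps, pn = _p_from_k(ks), _p_from_k(ka)
    S = sum(codon_sites(c)[0] for c in codons)
    N = sum(codon_sites(c)[1] for c in codons)
    n_syn = int(rng.poisson(ps * S))
    n_nonsyn = int(rng.poisson(pn * N))
    syn_eligible = [i for i, c in enumerate(codons) if _syn_mutants(c)]
    n_syn = min(n_syn, len(syn_eligible))
    mutated = list(codons)
    picks = rng.choice(len(syn_eligible), size=n_syn, replace=False)
    edited = {syn_eligible[i] for i in picks}
    for i in edited:
        mutated[i] = str(rng.choice(_syn_mutants(codons[i])))
    remaining = [i for i in range(len(codons)) if i not in edited]
    n_nonsyn = min(n_nonsyn, len(remaining))
    picks = rng.choice(len(remaining), size=n_nonsyn, replace=False)
    for j in picks:
        i = remaining[j]
        mutated[i] = str(rng.choice(_nonsyn_mutants(codons[i])))
    return "".join(mutated)


def gen_genome_layout(
    spec: GenomeLayoutSpec,
) -> tuple[list[GeneRecord], dict[str, str], pd.DataFrame]:
    """Genome layout with planted tandem arrays and segmental pairs.

    Returns (gene records, genome sequences, truth table of planted
    duplicate pairs with modes).  Tandem array members sit consecutively on
    one chromosome separated by the spec's spacing; segmental partners sit
    on distinct chromosomes.  Filler genes are mutually unrelated random
    CDSs scattered over the chromosomes.
    """
    rng = np.random.default_rng(spec.seed)
    genome = {
        chrom: "".join(rng.choice(list(_BASES), size=length))
        for chrom, length in spec.chromosome_lengths.items()
    }
    cursor = {chrom: 10_000 for chrom in genome}
    records: list[GeneRecord] = []
    truth_rows = []
    gene_n = 0

    def place(chrom: str, cds: str, gap: int) -> GeneRecord:
        nonlocal gene_n
        gene_n += 1
        gid = f"G{gene_n:03d}"
        start = cursor[chrom] + gap
        end = start + len(cds) - 1
        if end > spec.chromosome_lengths[chrom]:
            raise ValueError(f"features do not fit chromosome {chrom}")
        cursor[chrom] = end + 1
        prot = translate_cds(cds)
        rec = GeneRecord(
            gene_id=gid, protein_seq=prot, cds_seq=cds,
            chromosome=chrom, start=start, end=end, strand="+",
        )
        records.append(rec)
        return rec

    for chrom, size, spacing in spec.tandem_arrays:
        ancestor = _random_cds(spec.gene_codons, rng)
        members = []
        for k in range(size):
            cds = ancestor if k == 0 else _apply_divergence(
                ancestor, spec.duplicate_ka, spec.duplicate_ks, rng
            )
            members.append(place(chrom, cds, spacing if k else 50_000))
        for a, b in zip(members, members[1:]):
            ga, gb = sorted((a.gene_id, b.gene_id))
            truth_rows.append(dict(gene_a=ga, gene_b=gb, mode="tandem"))

    for chrom_a, chrom_b in spec.segmental_pairs:
        ancestor = _random_cds(spec.gene_codons, rng)
        a = place(chrom_a, ancestor, 60_000)
        b = place(
            chrom_b,
            _apply_divergence(ancestor, spec.duplicate_ka, spec.duplicate_ks, rng),
            60_000,
        )
        ga, gb = sorted((a.gene_id, b.gene_id))
        truth_rows.append(dict(gene_a=ga, gene_b=gb, mode="segmental"))

    chroms = sorted(genome)
    for _ in range(spec.filler_gene_count):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        place(chrom, _random_cds(spec.gene_codons, rng), 40_000)

    records.sort(key=lambda r: (r.chromosome, r.start))
    truth = pd.DataFrame(truth_rows, columns=["gene_a", "gene_b", "mode"])
    return records, genome, truth


def gen_promoters(
    genes: Sequence[GeneRecord],
    genome: Mapping[str, str],
    planted: Mapping[str, Mapping[str, int]],
    library: Sequence[CisElement] = DEFAULT_ELEMENTS,
    length: int = 2000,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Plant exact element copies into promoter windows of a genome.

    *planted* maps gene_id -> {element name -> copies}.  The promoter
    window of every listed gene is first scrubbed of accidental matches to
    any library motif, then the requested copies are inserted at
    non-overlapping random positions on random strands.  Returns the edited
    genome and a truth table of per-gene per-element counts.
    """
    rng = np.random.default_rng(seed)
    genome = {k: list(v) for k, v in genome.items()}
    by_name = {e.name: e for e in library}
    truth_rows = []
    for g in genes:
        if g.gene_id not in planted:
            continue
        if g.strand == "-":
            lo, hi = g.end, min(g.end + length, len(genome[g.chromosome]))
        else:
            lo, hi = max(0, g.start - 1 - length), g.start - 1
        window = "".join(genome[g.chromosome][lo:hi])
        if g.strand == "-":
            window = reverse_complement(window)
        window = _scrub_motifs(window, library, rng)
        window = _plant_motifs(
            window, {by_name[n]: c for n, c in planted[g.gene_id].items()},
            library, rng,
        )
        if g.strand == "-":
            window = reverse_complement(window)
        genome[g.chromosome][lo:hi] = list(window)
        row = dict(gene_id=g.gene_id)
        row.update(planted[g.gene_id])
        truth_rows.append(row)
    out = {k: "".join(v) for k, v in genome.items()}
    truth = pd.DataFrame(truth_rows).fillna(0)
    return out, truth


def _scrub_motifs(
    window: str, library: Sequence[CisElement], rng: np.random.Generator, max_iter: int = 200
) -> str:
    seq = list(window)
    for _ in range(max_iter):
        dirty = False
        for e in library:
            for pat in {e.motif, motif_reverse_complement(e.motif)}:
                m = len(pat)
                for i in range(len(seq) - m + 1):
                    from .promoter import IUPAC

                    if all(b in IUPAC[p] for b, p in zip(seq[i : i + m], pat)):
                        j = i + int(rng.integers(0, m))
                        current = seq[j]
                        seq[j] = str(rng.choice([b for b in _BASES if b != current]))
                        dirty = True
        if not dirty:
            return "".join(seq)
    raise RuntimeError("could not scrub background motifs")


def _plant_motifs(
    window: str,
    counts: Mapping[CisElement, int],
    library: Sequence[CisElement],
    rng: np.random.Generator,
    max_attempts: int = 100,
) -> str:
    from .promoter import count_motif as _count

    for _ in range(max_attempts):
        seq = list(window)
        occupied: list[tuple[int, int]] = []
        ok = True
        for element, copies in counts.items():
            m = len(element.motif)
            for _ in range(copies):
                for _try in range(200):
                    pos = int(rng.integers(0, len(seq) - m + 1))
                    if all(pos + m <= s or pos >= e for s, e in occupied):
                        break
                else:
                    ok = False
                    break
                motif = element.motif
                if rng.random() < 0.5:
                    motif = motif_reverse_complement(motif)
                # degenerate positions get a concrete base
                from .promoter import IUPAC

                concrete = "".join(
                    b if b in _BASES else str(rng.choice(list(IUPAC[b]))) for b in motif
                )
                seq[pos : pos + m] = list(concrete)
                occupied.append((pos, pos + m))
            if not ok:
                break
        if not ok:
            continue
        # planting must not create hits of any other library element either
        # (junction artifacts), so the whole library is re-verified; elements
        # sequence-coupled to a planted one (reverse-complement twins like
        # TGACG/CGTCA, or nested motifs like ACGTG inside CACGTG) cannot be
        # held at zero and are left unchecked
        planted_seq = "".join(seq)
        if all(
            _count(planted_seq, e.motif) == expected
            for e in library
            if (expected := _expected_count(e, counts)) is not None
        ):
            return planted_seq
    raise RuntimeError("could not plant motifs without collisions")


def motifs_coupled(a: str, b: str) -> bool:
    """Whether two IUPAC motifs cannot be counted independently."""
    rc_b = motif_reverse_complement(b)
    return a in b or b in a or a in rc_b or rc_b in a


def _expected_count(
    e: CisElement, counts: Mapping[CisElement, int]
) -> int | None:
    """Scan count the planter must verify for element *e*, or None to skip.

    A planted site of a motif is also a site of its exact reverse-complement
    twin (both strands are scanned), so twins accumulate each other's
    requests.  Any other coupling (nested motifs) is not independently
    countable and goes unchecked.
    """
    twins = 0
    for p, k in counts.items():
        if p is e:
            continue
        if p.motif == motif_reverse_complement(e.motif):
            twins += k
        elif motifs_coupled(e.motif, p.motif):
            return None
    if e in counts:
        return counts[e] + twins
    return twins if twins else 0


# expression fixtures -------------------------------------------------------

#: Tissue panel used by the tissue-specific fixture.
TISSUES = ("root", "stem", "leaf", "panicle", "seed", "sheath", "crown")

#: Which tissues each subfamily type is highly expressed in.
TYPE_TISSUE_BLOCKS = {
    "I": ("stem", "leaf"),
    "II": ("leaf",),
    "IV": ("root", "stem"),
    "V": ("root", "stem"),
    "VI": ("panicle",),
}


def gen_expression(
    gene_types: Mapping[str, str],
    tissues: Sequence[str] = TISSUES,
    n_replicates: int = 3,
    high_fpkm: float = 60.0,
    low_fpkm: float = 2.0,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Tissue-blocked FPKM matrix with lognormal replicate noise.

    Genes of each subfamily type are highly expressed in that type's tissue
    block and lowly expressed elsewhere; noise_sd is the standard deviation
    on the natural-log scale.  Returns the raw matrix plus a truth table of
    per-gene high-expression tissues.
    """
    rng = np.random.default_rng(seed)
    samples = []
    groups = {}
    for t in tissues:
        for r in range(1, n_replicates + 1):
            name = f"{t}_rep{r}"
            samples.append(name)
            groups[name] = t
    data = {}
    truth_rows = []
    for gid, label in gene_types.items():
        block = TYPE_TISSUE_BLOCKS.get(label, ())
        row = []
        for s in samples:
            mean = high_fpkm if groups[s] in block else low_fpkm
            row.append(float(np.exp(np.log(mean) + rng.normal(0.0, noise_sd))))
        data[gid] = row
        truth_rows.append(dict(gene_id=gid, high_tissues=",".join(block)))
    values = pd.DataFrame.from_dict(data, orient="index", columns=samples)
    return (
        ExpressionMatrix(values=values, replicate_groups=groups, state="raw"),
        pd.DataFrame(truth_rows),
    )


#: The abiotic-stress design: 3 treatments x 2 timepoints + control.
STRESS_CONDITIONS = (
    "control",
    "salt_6h", "salt_24h",
    "dehydration_6h", "dehydration_24h",
    "cold_6h", "cold_24h",
)


def gen_qpcr(
    fold_truths: Mapping[tuple[str, str], float],
    control_condition: str = "control",
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    ct_reference: float = 20.0,
    seed: int = 0,
) -> list[QpcrMeasurement]:
    """Back-compute Ct tables from known fold changes.

    For each (gene, condition) the target Ct is set so that the replicate
    mean dCt differs from the control's by -log2(fold), plus Gaussian noise
    of sd *noise_sd* per replicate.  The control condition is emitted for
    every gene automatically.
    """
    rng = np.random.default_rng(seed)
    genes = sorted({g for g, _ in fold_truths})
    out: list[QpcrMeasurement] = []
    base_dct = {g: 5.0 + float(rng.normal(0, 0.5)) for g in genes}
    conditions = {g: {control_condition} for g in genes}
    for (g, cond) in fold_truths:
        conditions[g].add(cond)
    for g in genes:
        for cond in sorted(conditions[g]):
            fold = 1.0 if cond == control_condition else fold_truths[(g, cond)]
            target_dct = base_dct[g] - math.log2(fold)
            for rep in range(1, n_replicates + 1):
                noise = float(rng.normal(0.0, noise_sd)) if noise_sd else 0.0
                out.append(
                    QpcrMeasurement(
                        gene=g,
                        condition=cond,
                        replicate=rep,
                        ct_target=ct_reference + target_dct + noise,
                        ct_reference=ct_reference,
                    )
                )
    return out
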