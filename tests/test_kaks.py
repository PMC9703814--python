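import itertools
import math

import numpy as np
import pytest

from nsltp.kaks import (
    ClockConfig,
    codon_sites,
    divergence_age,
    jukes_cantor,
    kaks_report,
    ng86,
    pathway_differences,
)
from nsltp.synthetic import DivergenceSpec, gen_codon_pair

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}
SENSE = [a + b + c for a in BASES for b in BASES for c in BASES
         if a + b + c not in STOPS]

CODE = {}
_T = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for i, (b1, b2, b3) in enumerate(itertools.product("TCAG", repeat=3)):
    CODE[b1 + b2 + b3] = _T[i]


def oracle_sites(codon):
    """Independent enumeration of synonymous site fractions."""
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if mut in STOPS:
                continue
            valid += 1
            syn += CODE[mut] == CODE[codon]
        if valid:
            s += syn / valid
    return s, 3.0 - s


def oracle_pathways(ca, cb):
    """Independent pathway enumeration with stop exclusion."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0
    kept = []
    everything = []
    for order in itertools.permutations(diff):
        cur, sd, nd, stopped = ca, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if nxt in STOPS or cur in STOPS:
                stopped = stopped or nxt in STOPS
                nd += 1
            elif CODE[cur] == CODE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        everything.append((sd, nd))
        if not stopped:
            kept.append((sd, nd))
    use = kept or everything
    return (sum(x for x, _ in use) / len(use), sum(y for _, y in use) / len(use))


class TestCodonSites:
    @pytest.mark.parametrize("codon,s", [
        ("TTT", 1 / 3),  # Phe: only 3rd-position TTC is synonymous
        ("ATG", 0.0),    # Met: no synonymous single-base mutants
        ("GGG", 1.0),    # Gly: fully degenerate third position
    ])
    def test_known_codons(self, codon, s):
        got_s, got_n = codon_sites(codon)
        assert got_s == pytest.approx(s)
        assert got_s + got_n == pytest.approx(3.0)

    def test_all_sense_codons_match_enumeration(self):
        for codon in SENSE:
            assert codon_sites(codon) == pytest.approx(oracle_sites(codon))

    def test_stop_codon_errors(self):
        with pytest.raises(ValueError):
            codon_sites("TAA")

    def test_ambiguous_base_errors(self):
        with pytest.raises(ValueError):
            codon_sites("ATN")


class TestPathwayDifferences:
    def test_identical(self):
        assert pathway_differences("TTT", "TTT") == (0.0, 0.0)

    def test_single_synonymous(self):
        assert pathway_differences("TTT", "TTC") == (1.0, 0.0)

    def test_two_difference_enumeration(self):
        assert pathway_differences("TTT", "GTA") == pytest.approx(
            oracle_pathways("TTT", "GTA")
        )

    def test_all_pairs_match_enumeration(self):
        for ca in SENSE:
            for cb in SENSE:
                got = pathway_differences(ca, cb)
                exp = oracle_pathways(ca, cb)
                assert got == pytest.approx(exp), (ca, cb)

    def test_difference_count_conserved(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            ca, cb = rng.choice(SENSE, size=2)
            k = sum(x != y for x, y in zip(ca, cb))
            sd, nd = pathway_differences(ca, cb)
            assert sd + nd == pytest.approx(k)


class TestNg86:
    def test_identical_pair(self):
        pairs = [("ATG", "ATG"), ("AAA", "AAA")]
        res = ng86(pairs)
        assert res.Ka == 0.0 and res.Ks == 0.0
        assert res.ratio is None and res.purifying is None

    def test_site_conservation(self):
        rng = np.random.default_rng(2)
        pairs = [tuple(rng.choice(SENSE, size=2)) for _ in range(50)]
        res = ng86(pairs)
        assert res.S_sites + res.N_sites == pytest.approx(3 * len(pairs))

    def test_symmetry(self):
        a, b, _ = gen_codon_pair(DivergenceSpec(n_codons=300, ka=0.1, ks=0.3, seed=4))
        pairs = [(a[i:i + 3], b[i:i + 3]) for i in range(0, len(a), 3)]
        fwd = ng86(pairs)
        rev = ng86([(b, a) for a, b in pairs])
        assert fwd.Ks == pytest.approx(rev.Ks)
        assert fwd.Ka == pytest.approx(rev.Ka)

    def test_neutral_simulation_ratio_near_one(self):
        a, b, _ = gen_codon_pair(DivergenceSpec(n_codons=10_000, ka=0.1, ks=0.1, seed=9))
        pairs = [(a[i:i + 3], b[i:i + 3]) for i in range(0, len(a), 3)]
        res = ng86(pairs)
        assert res.ratio == pytest.approx(1.0, abs=0.1)

    def test_purifying_simulation(self):
        a, b, _ = gen_codon_pair(DivergenceSpec(n_codons=2_000, ka=0.0, ks=0.4, seed=9))
        pairs = [(a[i:i + 3], b[i:i + 3]) for i in range(0, len(a), 3)]
        res = ng86(pairs)
        assert res.Ka == 0.0
        assert res.purifying is True
        assert res.Ks == pytest.approx(0.4, abs=0.05)

    def test_synonymous_changes_do_not_increase_ka(self):
        base = [("ATG", "ATG"), ("AAA", "AAA"), ("GGT", "GGT")] * 4
        with_syn = base + [("TTT", "TTC"), ("GGA", "GGG")]
        assert ng86(with_syn).Ka <= ng86(base).Ka

    def test_saturation_errors(self):
        # 75% of synonymous sites differing is beyond the JC domain
        with pytest.raises(ValueError, match="saturation"):
            jukes_cantor(0.75)


class TestPathwaySymmetryProperty:
    from hypothesis import HealthCheck, given, settings
    from hypothesis import strategies as st

    @given(ca=st.sampled_from(SENSE), cb=st.sampled_from(SENSE))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_pathway_counts_symmetric(self, ca, cb):
        sd, nd = pathway_differences(ca, cb)
        assert (sd, nd) == pytest.approx(pathway_differences(cb, ca))
        k = sum(x != y for x, y in zip(ca, cb))
        assert sd + nd == pytest.approx(k)


class TestDivergenceAge:
    @pytest.mark.parametrize("ks,age", [
        (0.4681, 36.0085),
        (0.3932, 30.2491),
        (0.0356, 2.7374),
        (0.0167, 1.2867),
        (0.0, 0.0),
    ])
    def test_printed_ages_from_printed_ks(self, ks, age):
        # printed Ks values are rounded, so agreement is to ~0.5%
        assert divergence_age(ks) == pytest.approx(age, rel=5e-3)

    def test_linear_in_ks_inverse_in_r(self):
        assert divergence_age(0.2) == pytest.approx(2 * divergence_age(0.1))
        fast = ClockConfig(r=1.3e-8)
        assert divergence_age(0.2, fast) == pytest.approx(divergence_age(0.1))

    def test_negative_ks_errors(self):
        with pytest.raises(ValueError):
            divergence_age(-0.1)


class TestKaksReport:
    @pytest.mark.parametrize("ka,ks,ratio", [
        (0.0150, 0.4681, 0.0321),
        (0.0413, 0.3932, 0.1051),
        (0.0207, 0.0356, 0.5803),
    ])
    def test_ratio_arithmetic_from_printed_inputs(self, ka, ks, ratio):
        assert ka / ks == pytest.approx(ratio, rel=0.01)

    def test_parameter_recovery(self):
        from nsltp.sequence_io import translate_cds

        a, b, _ = gen_codon_pair(DivergenceSpec(n_codons=500, ka=0.06, ks=0.3, seed=21))
        res = kaks_report(translate_cds(a), translate_cds(b), a, b)
        assert res.ratio == pytest.approx(0.2, abs=0.05)
        assert res.age_mya == pytest.approx(divergence_age(res.Ks))

    def test_ks_recovery_grid(self):
        # median |relative error| of recovered Ks over a planted grid
        errors = []
        for i, ks in enumerate((0.1, 0.2, 0.3, 0.4, 0.5)):
            a, b, _ = gen_codon_pair(
                DivergenceSpec(n_codons=1_000, ka=0.05, ks=ks, seed=100 + i)
            )
            pairs = [(a[j:j + 3], b[j:j + 3]) for j in range(0, len(a), 3)]
            errors.append(abs(ng86(pairs).Ks - ks) / ks)
        assert float(np.median(errors)) <= 0.10
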