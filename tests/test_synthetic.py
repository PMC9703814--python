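import numpy as np
import pandas as pd
import pytest

from nsltp.classify import assign_type
from nsltp.expression import collapse_replicates, ddct, hierarchical_cluster, log2p1
from nsltp.kaks import ng86
from nsltp.motif import best_match, scan_8cm
from nsltp.synthetic import (
    STRESS_CONDITIONS,
    DivergenceSpec,
    FamilySpec,
    GenomeLayoutSpec,
    gen_codon_pair,
    gen_expression,
    gen_family,
    gen_genome_layout,
    gen_qpcr,
)


def codon_pairs(a, b):
    return [(a[i:i + 3], b[i:i + 3]) for i in range(0, len(a), 3)]


class TestGenFamily:
    def test_counts_and_determinism(self):
        spec = FamilySpec(seed=7, decoy_count=5)
        r1, t1 = gen_family(spec)
        r2, t2 = gen_family(spec)
        assert r1 == r2
        pd.testing.assert_frame_equal(t1, t2)
        assert len(r1) == 42 + 5
        assert (t1.true_type == "decoy").sum() == 5

    def test_noiseless_labels_recovered(self, family_fixture):
        records, truth = family_fixture
        types = dict(zip(truth.gene_id, truth.true_type))
        for gid, seq in records:
            m = best_match(scan_8cm(seq))
            if types[gid] == "decoy":
                assert m is None
            else:
                assert assign_type(m, gid).type_label == types[gid]

    def test_decoys_never_match(self):
        records, truth = gen_family(
            FamilySpec(type_counts={}, decoy_count=20, seed=3)
        )
        for _, seq in records:
            assert scan_8cm(seq) == []

    def test_spacing_noise_produces_off_pattern(self):
        records, truth = gen_family(
            FamilySpec(type_counts={"I": 30}, spacing_noise=0.5, seed=5)
        )
        scores = []
        for gid, seq in records:
            m = best_match(scan_8cm(seq))
            if m is not None:
                scores.append(assign_type(m, gid).score)
        assert any(s > 0 for s in scores)

    def test_x_residue_hydropathy_per_type(self, family_fixture):
        _, truth = family_fixture
        from nsltp.classify import HYDROPHILIC_X, HYDROPHOBIC_X

        for row in truth.itertuples():
            if row.true_type == "I":
                assert row.x_residue in HYDROPHILIC_X
            elif row.true_type != "decoy":
                assert row.x_residue in HYDROPHOBIC_X


class TestGenCodonPair:
    def test_zero_divergence_identical(self):
        a, b, real = gen_codon_pair(DivergenceSpec(100, 0.0, 0.0, seed=1))
        assert a == b
        assert real["Sd"] == real["Nd"] == 0

    def test_synonymous_only_gives_exact_zero_ka(self):
        a, b, real = gen_codon_pair(DivergenceSpec(2_000, 0.0, 0.4, seed=2))
        res = ng86(codon_pairs(a, b))
        assert res.Ka == 0.0
        assert res.Ks == pytest.approx(0.4, abs=0.05)
        assert res.Sd == real["Sd"]

    def test_neutral_recovery(self):
        a, b, _ = gen_codon_pair(DivergenceSpec(10_000, 0.1, 0.1, seed=3))
        assert ng86(codon_pairs(a, b)).ratio == pytest.approx(1.0, abs=0.1)

    def test_no_stops_planted(self):
        a, b, _ = gen_codon_pair(DivergenceSpec(500, 0.1, 0.3, seed=4))
        stops = {"TAA", "TAG", "TGA"}
        for seq in (a, b):
            assert not any(seq[i:i + 3] in stops for i in range(0, len(seq), 3))

    def test_saturation_request_errors(self):
        with pytest.raises(ValueError, match="saturat"):
            gen_codon_pair(DivergenceSpec(100, 0.0, 5.0, seed=5))

    def test_determinism(self):
        s = DivergenceSpec(300, 0.05, 0.2, seed=6)
        assert gen_codon_pair(s) == gen_codon_pair(s)


class TestGenGenomeLayout:
    def test_truth_shape(self, genome_fixture):
        records, genome, truth = genome_fixture
        assert set(truth["mode"]) == {"tandem", "segmental"}
        assert (truth["mode"] == "tandem").sum() == 2  # 3-gene array -> 2 events
        assert (truth["mode"] == "segmental").sum() == 2

    def test_planted_separations_below_threshold(self, genome_fixture):
        records, _, truth = genome_fixture
        lookup = {r.gene_id: r for r in records}
        for row in truth.itertuples():
            a, b = lookup[row.gene_a], lookup[row.gene_b]
            if row.mode == "tandem":
                assert a.chromosome == b.chromosome
                gap = max(a.start, b.start) - min(a.end, b.end) - 1
                assert gap <= 100_000

    def test_empty_spec(self):
        records, genome, truth = gen_genome_layout(GenomeLayoutSpec(seed=1))
        assert records == [] and truth.empty

    def test_determinism(self):
        spec = GenomeLayoutSpec(
            tandem_arrays=(("chr1", 2, 5_000),), filler_gene_count=2, seed=9
        )
        r1, g1, t1 = gen_genome_layout(spec)
        r2, g2, t2 = gen_genome_layout(spec)
        assert r1 == r2 and g1 == g2
        pd.testing.assert_frame_equal(t1, t2)

    def test_cds_translates_to_protein(self, genome_fixture):
        records, _, _ = genome_fixture
        from nsltp.sequence_io import translate_cds

        for r in records:
            assert translate_cds(r.cds_seq) == r.protein_seq


class TestGenExpression:
    def test_blocks_recovered_by_clustering(self):
        types = {f"r{i}": "IV" for i in range(4)}
        types.update({f"p{i}": "VI" for i in range(4)})
        m, truth = gen_expression(types, noise_sd=0.1, seed=2)
        collapsed = collapse_replicates(log2p1(m))
        _, order = hierarchical_cluster(collapsed, metric="correlation")
        top = set(order[:4]), set(order[4:])
        root_block = {g for g, t in types.items() if t == "IV"}
        assert root_block in top

    def test_high_tissues_have_higher_medians(self):
        types = {"a": "VI", "b": "IV"}
        m, truth = gen_expression(types, noise_sd=0.1, seed=3)
        collapsed = collapse_replicates(m)
        assert collapsed.values.loc["a", "panicle"] > collapsed.values.loc["a", "root"]
        assert collapsed.values.loc["b", "root"] > collapsed.values.loc["b", "panicle"]

    def test_determinism(self):
        types = {"a": "I", "b": "II"}
        m1, _ = gen_expression(types, seed=4)
        m2, _ = gen_expression(types, seed=4)
        pd.testing.assert_frame_equal(m1.values, m2.values)


class TestGenQpcr:
    def test_zero_noise_exact_folds(self):
        folds = {("g1", "salt_6h"): 2.0, ("g1", "cold_6h"): 0.25,
                 ("g2", "salt_6h"): 1.0}
        q = gen_qpcr(folds, noise_sd=0.0, seed=1)
        out = ddct(q, "control").set_index(["gene", "condition"])
        for (g, cond), fold in folds.items():
            assert out.loc[(g, cond), "fold"] == pytest.approx(fold)
        assert out.loc[("g1", "control"), "fold"] == 1.0

    def test_stress_design_conditions_available(self):
        folds = {("g", c): 2.0 for c in STRESS_CONDITIONS if c != "control"}
        q = gen_qpcr(folds, noise_sd=0.0, seed=2)
        conds = {m.condition for m in q}
        assert conds == set(STRESS_CONDITIONS)
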