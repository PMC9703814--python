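import itertools

import numpy as np
import pytest

from nsltp.sequence_io import GeneRecord
from nsltp.synthetic import FamilySpec, GenomeLayoutSpec, gen_family, gen_genome_layout


@pytest.fixture(scope="session")
def family_fixture():
    """A noiseless 42-gene five-subfamily family plus 5 decoys."""
    records, truth = gen_family(FamilySpec(seed=7, decoy_count=5))
    return records, truth


@pytest.fixture(scope="session")
def genome_fixture():
    """Synthetic genome: one 3-gene tandem array, two segmental pairs, fillers."""
    spec = GenomeLayoutSpec(
        tandem_arrays=(("chr1", 3, 8_000),),
        segmental_pairs=(("chr2", "chr3"), ("chr1", "chr2")),
        filler_gene_count=6,
        seed=11,
    )
    return gen_genome_layout(spec)


def brute_force_8cm(seq, bounds):
    """Independent 8CM oracle: filter all 8-subsets of cysteine positions."""
    from nsltp.motif import EightCMMatch, _spacing_from_positions

    cys = [i for i, ch in enumerate(seq) if ch == "C"]
    out = []
    limits = dict(
        n0=bounds.n0, g1=bounds.g1, g2=bounds.g2, g3=(0, 0), g4=bounds.g4,
        g5=(1, 1), g6=bounds.g6, g7=bounds.g7, n8=bounds.n8,
    )
    names = ("n0", "g1", "g2", "g3", "g4", "g5", "g6", "g7", "n8")
    for subset in itertools.combinations(cys, 8):
        spacing = _spacing_from_positions(len(seq), subset)
        if all(
            limits[n][0] <= v <= limits[n][1] for n, v in zip(names, spacing)
        ):
            out.append(
                EightCMMatch(
                    cys_positions=subset,
                    spacing=spacing,
                    x_residue=seq[subset[4] + 1],
                )
            )
    out.sort(key=lambda m: m.cys_positions)
    return out


def random_cys_protein(rng, max_cys=12):
    """Random protein with at most max_cys cysteines, LTP-like length."""
    length = int(rng.integers(60, 130))
    n_cys = int(rng.integers(0, max_cys + 1))
    body = list(rng.choice(list("ADEFGHIKLMNPQRSTVWY"), size=length))
    for pos in rng.choice(length, size=min(n_cys, length), replace=False):
        body[pos] = "C"
    return "".join(body)


def random_additive_tree(rng, n_leaves):
    """Random binary tree with positive branch lengths and its leaf distances.

    Returns (newick string, labels, distance matrix) where the matrix is
    exactly additive on the tree.
    """
    labels = [f"T{i}" for i in range(n_leaves)]
    # start with star of leaves, join randomly; track paths via distance map
    nodes = {lab: {lab: 0.0} for lab in labels}  # node -> leaf distances below
    edge = {}
    alive = list(labels)
    newick = {lab: lab for lab in labels}
    while len(alive) > 2:
        i, j = sorted(rng.choice(len(alive), size=2, replace=False))
        a, b = alive[i], alive[j]
        la = float(rng.integers(1, 10))
        lb = float(rng.integers(1, 10))
        new = f"({newick[a]}:{la},{newick[b]}:{lb})"
        merged = {}
        for leaf, d in nodes[a].items():
            merged[leaf] = d + la
        for leaf, d in nodes[b].items():
            merged[leaf] = d + lb
        key = f"N{len(nodes)}"
        nodes[key] = merged
        newick[key] = new
        alive = [x for x in alive if x not in (a, b)] + [key]
    a, b = alive
    lab_final = float(rng.integers(1, 10))
    nwk = f"({newick[a]},{newick[b]}:{lab_final});"
    dists_a, dists_b = nodes[a], nodes[b]
    n = len(labels)
    d = np.zeros((n, n))
    for x in range(n):
        for y in range(n):
            if x == y:
                continue
            lx, ly = labels[x], labels[y]
            if lx in dists_a and ly in dists_a:
                # both below a: need within-subtree distance; recompute via
                # lowest merged ancestor — walk merged maps
                d[x, y] = _within(nodes, lx, ly)
            elif lx in dists_b and ly in dists_b:
                d[x, y] = _within(nodes, lx, ly)
            else:
                da = dists_a.get(lx, dists_b.get(lx))
                db = dists_a.get(ly, dists_b.get(ly))
                d[x, y] = da + db + lab_final
    return nwk, labels, d


def _within(nodes, lx, ly):
    best = None
    for merged in nodes.values():
        if lx in merged and ly in merged:
            total = merged[lx] + merged[ly]
            if best is None or total < best:
                best = total
    return best
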