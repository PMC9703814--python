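"""Neighbor-joining trees from pairwise alignment distances.

Distances are p-distances (1 - identity fraction over both-non-gap columns
of a global pairwise alignment), so no multiple-sequence alignment is
required.  Joining follows Saitou & Nei's Q-criterion with deterministic
tie-breaking on the smallest (i, j) index pair; negative branch lengths are
clamped to zero with the deficit moved to the sister branch, preserving the
joined pair's distance.  Trees are dendropy objects and serialise to newick.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .align import global_align
from .sequence_io import GeneRecord


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match label count")


def pdistance_matrix(records: Sequence[GeneRecord]) -> DistanceMatrix:
    """Pairwise p-distance matrix: d = 1 - identity_pct/100."""
    if len(records) < 3:
        raise ValueError("need at least 3 records for a distance matrix")
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(records[i].protein_seq, records[j].protein_seq)
            d[i, j] = d[j, i] = 1.0 - aln.identity_pct / 100.0
    return DistanceMatrix(labels=[r.gene_id for r in records], d=d)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining on a symmetric distance matrix."""
    if not np.allclose(dm.d, dm.d.T):
        raise ValueError("distance matrix is not symmetric")
    if len(dm.labels) < 3:
        raise ValueError("need at least 3 taxa")

    tns = dendropy.TaxonNamespace(dm.labels)
    nodes: list[dendropy.Node] = []
    for lab in dm.labels:
        node = dendropy.Node(taxon=tns.get_taxon(lab))
        nodes.append(node)
    D = dm.d.astype(float).copy()
    active = list(range(len(dm.labels)))  # indices into D rows
    # D stays full-size; rows/cols of joined nodes are retired from `active`
    # and new nodes appended.
    node_of = {i: nodes[i] for i in active}
    next_row = len(dm.labels)
    # grow D lazily by padding
    while len(active) > 2:
        n = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        best_q = None
        for ai in range(n):
            for aj in range(ai + 1, n):
                i, j = active[ai], active[aj]
                q = (n - 2) * D[i, j] - r[i] - r[j]
                if best_q is None or q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = D[i, j] - li
        # clamp negatives, moving the deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new_node = dendropy.Node()
        node_of[i].edge.length = li
        node_of[j].edge.length = lj
        new_node.add_child(node_of[i])
        new_node.add_child(node_of[j])
        # distances from the new node to every other active node
        pad = np.zeros((1, D.shape[1]))
        D = np.vstack([D, pad])
        D = np.hstack([D, np.zeros((D.shape[0], 1))])
        u = next_row
        next_row += 1
        for k in active:
            if k in (i, j):
                continue
            D[u, k] = D[k, u] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        node_of[u] = new_node
        active = [k for k in active if k not in (i, j)] + [u]
    i, j = active
    # seed the tree at an internal node when possible
    if node_of[i].is_leaf() and not node_of[j].is_leaf():
        i, j = j, i
    node_of[j].edge.length = max(D[i, j], 0.0)
    node_of[i].add_child(node_of[j])
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=node_of[i])
    tree.is_rooted = False
    return tree


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def _leafsets(tree: dendropy.Tree) -> list[frozenset[str]]:
    """Leaf-label set under every node (one side of each bipartition)."""
    sets = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._leafset = frozenset([node.taxon.label])
        else:
            s: frozenset[str] = frozenset()
            for ch in node.child_nodes():
                s |= ch._leafset
            node._leafset = s
        sets.append(node._leafset)
    return sets


def is_monophyletic(tree: dendropy.Tree, labels: set[str]) -> bool:
    """Whether *labels* forms one side of some bipartition of the tree."""
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    target = frozenset(labels)
    if not target <= all_leaves:
        raise ValueError("labels not all present in tree")
    if len(target) <= 1 or target == all_leaves:
        return True
    complement = all_leaves - target
    return any(s in (target, complement) for s in _leafsets(tree))


def clade_purity(
    tree: dendropy.Tree, assignments: Mapping[str, str]
) -> dict[str, bool]:
    """Per-type monophyly on the tree, ignoring unclassified leaves.

    Unclassified leaves are pruned before testing, so a type counts as
    monophyletic when its members form a connected subtree among the
    classified leaves.
    """
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = leaves - set(assignments)
    if missing:
        raise ValueError(f"no type assignment for leaves: {sorted(missing)}")
    keep = [lab for lab in leaves if assignments[lab] != "unclassified"]
    pruned = tree.extract_tree_with_taxa_labels(keep)
    report = {}
    for type_label in sorted(set(assignments.values()) - {"unclassified"}):
        members = {lab for lab in keep if assignments[lab] == type_label}
        report[type_label] = is_monophyletic(pruned, members)
    return report


def bootstrap_support(
    records: Sequence[GeneRecord],
    n_replicates: int = 100,
    seed: int = 0,
) -> tuple[dendropy.Tree, dict[frozenset[str], float]]:
    """NJ tree plus bipartition support from resampled alignment columns.

    Each replicate resamples, per gene pair, the aligned columns of the
    stored pairwise alignment with replacement and recomputes the identity
    (hence distance) before rebuilding the tree.
    """
    rng = np.random.default_rng(seed)
    n = len(records)
    aligned_cols: dict[tuple[int, int], list[bool]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(records[i].protein_seq, records[j].protein_seq)
            cols = [
                x == y and x != "X"
                for x, y in zip(aln.aligned_a, aln.aligned_b)
                if x != "-" and y != "-"
            ]
            aligned_cols[(i, j)] = cols
    labels = [r.gene_id for r in records]
    main = neighbor_joining(pdistance_matrix(records))
    all_leaves = frozenset(labels)

    def _bips(tree: dendropy.Tree) -> set[frozenset[str]]:
        out = set()
        for s in _leafsets(tree):
            if 1 < len(s) < len(all_leaves):
                out.add(min(s, all_leaves - s, key=sorted))
        return out

    main_bips = _bips(main)
    hits = {b: 0 for b in main_bips}
    for _ in range(n_replicates):
        d = np.zeros((n, n))
        for (i, j), cols in aligned_cols.items():
            m = len(cols)
            draw = rng.integers(0, m, size=m)
            ident = sum(cols[k] for k in draw) / m
            d[i, j] = d[j, i] = 1.0 - ident
        rep = neighbor_joining(DistanceMatrix(labels=list(labels), d=d))
        rep_bips = _bips(rep)
        for b in main_bips:
            if b in rep_bips:
                hits[b] += 1
    support = {b: hits[b] / n_replicates for b in main_bips}
    return main, support
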