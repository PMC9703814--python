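"""Expression-matrix processing and qPCR fold-change calculation.

RNA-seq expression enters as a gene x sample FPKM table with a replicate
grouping; processing follows the usual heatmap pipeline: log2(FPKM + 1)
transform, per-group replicate medians, then average-linkage hierarchical
clustering (1 - Pearson correlation on genes by default, Euclidean
available).  qPCR quantification uses the 2^-ddCt method against a
reference gene (Actin) and a control condition.

The matrix carries an explicit transform state (raw -> log2p1 ->
median-collapsed) so a transform cannot be applied twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix plus replicate grouping and transform state."""

    values: pd.DataFrame  # genes as index, samples as columns
    replicate_groups: dict[str, str]  # sample -> group label
    state: str = "raw"  # raw | log2p1 | median-collapsed

    def __post_init__(self) -> None:
        if self.state == "raw" and (self.values.values < 0).any():
            raise ValueError("raw FPKM values must be non-negative")
        unknown = set(self.values.columns) - set(self.replicate_groups)
        if unknown:
            raise ValueError(f"samples without replicate group: {sorted(unknown)}")


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read a TSV with a two-row header: sample names, replicate groups."""
    df = pd.read_csv(path, sep="\t", header=[0, 1], index_col=0, comment="#")
    groups = {sample: group for sample, group in df.columns}
    df.columns = [sample for sample, _ in df.columns]
    return ExpressionMatrix(values=df, replicate_groups=groups)


def log2p1(m: ExpressionMatrix) -> ExpressionMatrix:
    """Entry-wise log2(x + 1); only valid on a raw matrix."""
    if m.state != "raw":
        raise ValueError(f"log2p1 requires a raw matrix, got state {m.state!r}")
    if (m.values.values < 0).any():
        raise ValueError("negative expression value")
    return ExpressionMatrix(
        values=np.log2(m.values + 1.0),
        replicate_groups=dict(m.replicate_groups),
        state="log2p1",
    )


def collapse_replicates(m: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene median within each replicate group; one column per group."""
    if m.state == "median-collapsed":
        raise ValueError("matrix already median-collapsed")
    groups: dict[str, list[str]] = {}
    for sample in m.values.columns:
        groups.setdefault(m.replicate_groups[sample], []).append(sample)
    for g, samples in groups.items():
        if not samples:
            raise ValueError(f"replicate group {g!r} has no samples")
    collapsed = pd.DataFrame(
        {g: m.values[samples].median(axis=1) for g, samples in groups.items()}
    )
    return ExpressionMatrix(
        values=collapsed,
        replicate_groups={g: g for g in collapsed.columns},
        state="median-collapsed",
    )


def hierarchical_cluster(
    m: ExpressionMatrix,
    axis: str = "genes",
    metric: str = "correlation",  # 1 - Pearson; or "euclidean"
) -> tuple[np.ndarray, list[str]]:
    """Average-linkage agglomerative clustering of genes or samples.

    Returns the scipy linkage matrix and the ordered leaf labels.  With the
    correlation metric a constant row has no defined correlation and is an
    error naming the gene/sample.
    """
    data = m.values if axis == "genes" else m.values.T
    labels = list(data.index)
    if len(labels) < 2:
        raise ValueError("need at least 2 items to cluster")
    X = data.to_numpy(dtype=float)
    if metric == "correlation":
        sd = X.std(axis=1)
        flat = [labels[i] for i in np.nonzero(sd == 0)[0]]
        if flat:
            raise ValueError(
                f"constant profile(s) under correlation distance: {flat}"
            )
    dist = pdist(X, metric=metric)
    Z = hierarchy.linkage(dist, method="average")
    order = hierarchy.leaves_list(Z)
    return Z, [labels[i] for i in order]


@dataclass(frozen=True)
class QpcrMeasurement:
    gene: str
    condition: str
    replicate: int
    ct_target: float
    ct_reference: float


def read_qpcr_tsv(path) -> list[QpcrMeasurement]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        QpcrMeasurement(
            gene=str(r.gene),
            condition=str(r.condition),
            replicate=int(r.replicate),
            ct_target=float(r.ct_target),
            ct_reference=float(r.ct_reference),
        )
        for r in df.itertuples()
    ]


def ddct(
    measurements: Sequence[QpcrMeasurement], control_condition: str
) -> pd.DataFrame:
    """Relative quantification by 2^-ddCt.

    Per replicate dCt = Ct_target - Ct_reference; per (gene, condition)
    ddCt = mean dCt(condition) - mean dCt(control); fold = 2^-ddCt.  The
    control condition's fold is exactly 1 for every gene by construction.
    Returns a DataFrame with columns gene, condition, dct_mean, ddct, fold.
    """
    dct: dict[tuple[str, str], list[float]] = {}
    for q in measurements:
        dct.setdefault((q.gene, q.condition), []).append(q.ct_target - q.ct_reference)
    genes = sorted({g for g, _ in dct})
    rows = []
    for gene in genes:
        if (gene, control_condition) not in dct:
            raise ValueError(f"gene {gene!r} has no control condition measurements")
        control_mean = float(np.mean(dct[(gene, control_condition)]))
        for (g, cond), values in dct.items():
            if g != gene:
                continue
            dd = float(np.mean(values)) - control_mean
            rows.append(
                {
                    "gene": gene,
                    "condition": cond,
                    "dct_mean": float(np.mean(values)),
                    "ddct": dd,
                    "fold": 2.0 ** (-dd),
                }
            )
    return pd.DataFrame(rows).sort_values(["gene", "condition"]).reset_index(drop=True)


def plot_heatmap(m: ExpressionMatrix, path) -> None:
    """Clustered heatmap of the matrix (thin convenience wrapper)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, max(3, 0.2 * len(m.values))))
    im = ax.imshow(m.values.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(m.values.columns)), m.values.columns, rotation=90)
    ax.set_yticks(range(len(m.values)), m.values.index, fontsize=5)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
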